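"""Named study designs for the simulation experiments.

Each function returns the fixed conditions of one in-silico experiment —
chosen once, on biological grounds, and shared by the analysis drivers, the
test suite and the acceptance script so that every consumer runs the same
study.  One simulator generation represents a ~4-year breeding cycle (a
cross followed by selfing to near-fixation), so the cycle-level "selfing
rate" (the probability a line is carried forward without a new cross) is far
below the per-meiosis selfing rate of rice, and the per-cycle recombination
rate folds in the map expansion of the within-cycle selfing generations.
"""

from __future__ import annotations

import numpy as np

from .synthdata.config import SimConfig

#: loci simulated per SV class in the selection experiments
SV_COUNTS = {"exonic_SV": 80, "intronic_SV": 80, "intergenic_SV": 80}


def rate_ordering_config(seed: int) -> SimConfig:
    """Cohort design for the class-ordering and LSD experiments.

    Selection strengths are ordered exonic > intronic > intergenic = 0 with
    magnitudes that spread the purge over the whole 1905-2013 course (a
    stronger s exhausts the decline within a few cycles and leaves nothing
    for the year regression to see).
    """
    return SimConfig(
        seed=seed,
        n_varieties=101,
        pop_size=300,
        snp_count=60,
        selfing_rate=0.4,
        recomb_rate=2e-4,
        founder_ld_window_bp=0,
        selection_coeffs={"exonic_SV": 0.12, "intronic_SV": 0.03},
    )


def neutral_config(seed: int) -> SimConfig:
    """Same design with all selection off (the martingale / null case)."""
    cfg = rate_ordering_config(seed)
    cfg.selection_coeffs = {}
    return cfg


def sweep_config(seed: int) -> SimConfig:
    """Cohort design for the haplotype-block sweep scan.

    Tight linkage (few crossovers per cycle, high carryover) preserves the
    block structure the scan relies on; the planted sweep allele starts on a
    single founder background with a strong advantage, mirroring the
    semi-dwarf introduction.
    """
    return SimConfig(
        seed=seed,
        n_varieties=101,
        pop_size=500,
        snp_count=150,
        selfing_rate=0.95,
        recomb_rate=1e-5,
        sweep_s=0.5,
    )


def genotyping_config(seed: int, hemizygous_rate: float = 0.0) -> SimConfig:
    """Read-evidence design: 40x short reads over SV loci."""
    return SimConfig(
        seed=seed,
        depth=40.0,
        read_length=100,
        hemizygous_rate=hemizygous_rate,
    )


def genotyping_loci(
    n: int, rng: np.random.Generator, min_gap: int = 2_000, chrom: str = "chr1"
):
    """Spaced reference intervals for read-evidence experiments.

    Intervals mix tiny (insertion-in-derived, reference span 0-10 bp) and
    longer deletion-type spans; a minimum gap keeps read pools of adjacent
    loci independent, as pre-ascertained SV events are after merging.
    """
    import pandas as pd

    sizes = [0, 10, 80, 200, 400, 1_500]
    rows = []
    pos = 2_000
    for i in range(n):
        L = int(rng.choice(sizes))
        pos += int(rng.integers(min_gap, 2 * min_gap))
        rows.append({"locus_id": f"sv{i:04d}", "chrom": chrom, "start": pos, "end": pos + L})
        pos += L
    return pd.DataFrame(rows)


def default_event_spec(rng: np.random.Generator, n_events: int = 50):
    """Planted-event roster for the indel-inference round trip.

    An even rotation over mechanisms and ingroup lineages, lengths 60-400 bp
    (mixed events 60/40 insertion-biased), plus outgroup-private events that
    downstream inference must discard.
    """
    from .synthdata.config import EventSpec

    mechs = ["tandem_dup", "ectopic_ins", "deletion", "mixed"]
    spec = []
    for i in range(n_events):
        spec.append(
            EventSpec(
                lineage="A" if i % 2 else "B",
                mechanism=mechs[i % 4],
                length=int(rng.integers(60, 400)),
                insertion_fraction=0.75 if (i // 4) % 2 else 0.25,
            )
        )
    spec.append(EventSpec("outgroup", "deletion", 200))
    spec.append(EventSpec("outgroup", "ectopic_ins", 150))
    return spec
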