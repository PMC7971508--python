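"""Per-sample read evidence over SV intervals.

For a reference (ancestral) allele carrier, reads tile the SV interval at
roughly the configured depth.  For a derived-allele carrier no read is
contiguous across the ancestral interval: reads stop at the breakpoints and
are flagged soft-clipped (with configurable probability; otherwise split).
Optional "hemizygous-like" noise makes a configurable fraction of
sample-locus pairs show the reference pattern on top of the derived one,
emulating the tandem-duplication-driven reference bias seen in real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig

_PAD = 60  # bp of flank tiled on each side of the interval

READ_COLUMNS = ["chrom", "start", "end", "is_split", "is_softclipped"]


@dataclass
class ReadEvidence:
    """Filtered-alignment surrogate: one row per read over SV loci."""

    sample_id: str
    reads: pd.DataFrame  # READ_COLUMNS
    mean_depth: float

    def __post_init__(self):
        if len(self.reads) and not (self.reads["start"] < self.reads["end"]).all():
            raise ValueError("read start must be < end")


def _ref_reads(start, end, depth, rl, rng, chrom):
    lo, hi = start - _PAD - rl, end + _PAD
    n = rng.poisson(depth * (hi - lo) / rl)
    starts = rng.integers(lo, hi, size=n)
    return [(chrom, int(s), int(s) + rl, False, False) for s in starts]


def _derived_reads(start, end, depth, rl, softclip_prob, rng, chrom):
    out = []
    # left of the breakpoint at `start`
    n = rng.poisson(depth * (_PAD + rl) / rl)
    for s in rng.integers(start - _PAD - rl, start, size=n):
        s = int(s)
        if s + rl <= start:
            out.append((chrom, s, s + rl, False, False))
        elif s < start:  # truncated at the junction
            clipped = rng.random() < softclip_prob
            out.append((chrom, s, start, not clipped, clipped))
    # right of the breakpoint at `end`
    n = rng.poisson(depth * (_PAD + rl) / rl)
    for e in rng.integers(end + 1, end + _PAD + rl + 1, size=n):
        e = int(e)
        if e - rl >= end:
            out.append((chrom, e - rl, e, False, False))
        else:
            clipped = rng.random() < softclip_prob
            out.append((chrom, end, e, not clipped, clipped))
    return out


def simulate_read_evidence(
    genotypes: pd.DataFrame,
    sv_loci: pd.DataFrame,
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> dict[str, ReadEvidence]:
    """Simulate read evidence for every sample over every SV locus.

    Parameters
    ----------
    genotypes : samples x loci frame over {0 ancestral, 1 derived}; columns
        must match ``sv_loci["locus_id"]``.
    sv_loci : locus_id, chrom, start, end — reference-genome intervals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    depth, rl = cfg.depth, cfg.read_length
    out: dict[str, ReadEvidence] = {}
    loci = sv_loci.set_index("locus_id")
    for sample in genotypes.index:
        rows: list[tuple] = []
        if depth > 0:
            for locus_id, allele in genotypes.loc[sample].items():
                rec = loci.loc[locus_id]
                chrom, start, end = rec["chrom"], int(rec["start"]), int(rec["end"])
                if allele == 0:
                    rows += _ref_reads(start, end, depth, rl, rng, chrom)
                else:
                    rows += _derived_reads(start, end, depth, rl, cfg.softclip_prob, rng, chrom)
                    if rng.random() < cfg.hemizygous_rate:
                        rows += _ref_reads(start, end, depth, rl, rng, chrom)
        reads = pd.DataFrame(rows, columns=READ_COLUMNS)
        out[sample] = ReadEvidence(sample_id=str(sample), reads=reads, mean_depth=depth)
    return out
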