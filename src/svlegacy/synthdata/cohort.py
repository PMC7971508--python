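"""Selfing Wright-Fisher breeding cohort under class-specific selection.

The model mimics inbred-line development: a population of fully inbred
(haploid-coded) lines; each generation, parents are sampled with probability
proportional to fitness w = prod over derived alleles of (1 - s_class), times
(1 + sweep_s) for the planted sweep allele; offspring arise by selfing
(cloning, probability `selfing_rate`) or by an outcross with Poisson-breakpoint
recombination.  Generations map linearly onto release years.

Founders are drawn from a small set of distinct founder haplotypes, which
creates the strong LD-block structure downstream haplotype analyses expect;
the sweep allele is planted on a single founder haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .events import SimTruth

_SNP_CLASSES = ("syn_SNP", "nonsyn_SNP", "stop_gain_SNP")
_SNP_CLASS_P = (0.5, 0.4, 0.1)


@dataclass
class Cohort:
    """Sampled varieties with metadata, genotypes and the loci they segregate."""

    metadata: pd.DataFrame          # variety_id, release_year, grain_type, parent1, parent2
    genotypes: pd.DataFrame         # varieties x loci, int8 in {0, 1}
    loci: pd.DataFrame              # locus_id, position, kind, class_, s, fitness_mult
    freq_history: np.ndarray        # generations x loci derived-allele frequency
    populations: list[np.ndarray] = field(repr=False, default_factory=list)
    sweep_locus_id: str | None = None

    @property
    def years(self) -> pd.Series:
        return self.metadata.set_index("variety_id")["release_year"]


def assign_sv_classes(truth: SimTruth, gene_models: pd.DataFrame) -> list[str]:
    """Genic class of each non-ambiguous planted event (ancestor coordinates)."""
    exons = gene_models[gene_models.feature == "exon"][["start", "end"]].to_numpy()
    genes = gene_models[gene_models.feature == "gene"][["start", "end"]].to_numpy()

    def _ctx(iv):
        s, e = iv
        if e == s:
            e = s + 1
        if any(s < ge and gs < e for gs, ge in exons):
            return "exonic_SV"
        if any(s < ge and gs < e for gs, ge in genes):
            return "intronic_SV"
        return "intergenic_SV"

    return [_ctx(ev.anc_interval) for ev in truth.ingroup_events]


def build_loci_table(
    truth: SimTruth | None,
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_models: pd.DataFrame | None = None,
    sv_classes: list[str] | None = None,
    sv_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Loci segregating in the cohort: planted SVs, random SNPs, the sweep site.

    Each locus carries its variant class, the class selection coefficient from
    ``cfg.selection_coeffs`` and the per-derived-allele fitness multiplier.
    """
    rows = []
    if sv_counts:
        i = 0
        for cls, n in sv_counts.items():
            for _ in range(n):
                rows.append(
                    {
                        "locus_id": f"sv{i:04d}",
                        "position": int(rng.integers(0, cfg.genome_length)),
                        "kind": "SV",
                        "class_": cls,
                        "derived_lineage": "B",
                    }
                )
                i += 1
    if truth is not None:
        events = truth.ingroup_events
        if sv_classes is None:
            if gene_models is not None:
                sv_classes = assign_sv_classes(truth, gene_models)
            else:
                sv_classes = list(
                    rng.choice(["exonic_SV", "intronic_SV", "intergenic_SV"], size=len(events))
                )
        for i, (ev, cls) in enumerate(zip(events, sv_classes)):
            rows.append(
                {
                    "locus_id": f"sv{i:04d}",
                    "position": ev.anc_interval[0],
                    "kind": "SV",
                    "class_": cls,
                    "derived_lineage": ev.lineage,
                }
            )
    positions = rng.integers(0, cfg.genome_length, size=cfg.snp_count)
    classes = rng.choice(_SNP_CLASSES, size=cfg.snp_count, p=_SNP_CLASS_P)
    for i, (pos, cls) in enumerate(zip(positions, classes)):
        rows.append(
            {
                "locus_id": f"snp{i:04d}",
                "position": int(pos),
                "kind": "SNP",
                "class_": cls,
                "derived_lineage": "B",
            }
        )
    if cfg.sweep_s > 0:
        rows.append(
            {
                "locus_id": "sweep",
                "position": int(rng.integers(0, cfg.genome_length)),
                "kind": "sweep",
                "class_": "sweep",
                "derived_lineage": "B",
            }
        )
    loci = pd.DataFrame(rows).sort_values("position", kind="stable").reset_index(drop=True)
    s = loci["class_"].map(cfg.selection_coeffs).fillna(0.0)
    loci["s"] = np.where(loci["kind"] == "sweep", 0.0, s)
    loci["fitness_mult"] = np.where(
        loci["kind"] == "sweep", 1.0 + cfg.sweep_s, 1.0 - loci["s"]
    )
    if (loci["fitness_mult"] <= 0).any():
        raise ValueError("selection coefficient >= 1 gives non-positive fitness")
    return loci


def _recombine(
    h1: np.ndarray, h2: np.ndarray, positions: np.ndarray, genome_length: int,
    recomb_rate: float, rng: np.random.Generator,
) -> np.ndarray:
    n_break = rng.poisson(recomb_rate * genome_length)
    if n_break == 0:
        return (h1 if rng.random() < 0.5 else h2).copy()
    breaks = np.sort(rng.integers(0, genome_length, size=n_break))
    seg = np.searchsorted(breaks, positions, side="right")
    first = int(rng.random() < 0.5)
    use_h1 = (seg + first) % 2 == 0
    return np.where(use_h1, h1, h2)


def simulate_cohort(
    loci: pd.DataFrame | SimTruth,
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
    founder_freqs: np.ndarray | None = None,
) -> Cohort:
    """Run the breeding simulation and sample varieties across release years.

    Parameters
    ----------
    loci : loci table from :func:`build_loci_table` (a SimTruth is accepted and
        converted with random SV classes).
    founder_freqs : optional per-locus starting derived frequency targets
        (default: Uniform(0.15, 0.5); the sweep allele always starts on one
        founder haplotype).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    if isinstance(loci, SimTruth):
        loci = build_loci_table(loci, cfg, rng)
    if cfg.n_varieties < 2:
        raise ValueError("need at least 2 varieties")
    n_loci = len(loci)
    positions = loci["position"].to_numpy()
    log_mult = np.log(loci["fitness_mult"].to_numpy())

    K = cfg.n_founder_haplotypes
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.15, 0.5, size=n_loci)
    # Base haplotypes: with founder LD enabled, sites within each window
    # share one random ranking of the K bases, giving nested carrier sets
    # (high pairwise r^2) and genuine LD-block structure; with the window
    # disabled every locus draws its carriers independently, which keeps
    # neutral loci free of hitchhiking with selected neighbours.
    seg_len = cfg.founder_ld_window_bp if cfg.founder_ld_window_bp > 0 else 10_000
    base = np.zeros((K, n_loci), dtype=np.int8)
    if cfg.founder_ld_window_bp > 0:
        win_id = (positions // seg_len).astype(int)
        for w in np.unique(win_id):
            perm = rng.permutation(K)
            for j in np.flatnonzero(win_id == w):
                k = int(np.clip(round(founder_freqs[j] * K), 1, K - 1))
                base[perm[:k], j] = 1
    else:
        for j in range(n_loci):
            k = int(np.clip(round(founder_freqs[j] * K), 1, K - 1))
            base[rng.choice(K, size=k, replace=False), j] = 1
    # founders are mosaics of the base haplotypes so that linkage is local:
    # a sweep drags its own block, not a whole founder genome
    n_founders = 3 * K
    founders = np.empty((n_founders, n_loci), dtype=np.int8)
    for f in range(n_founders):
        n_break = rng.poisson(cfg.genome_length / seg_len)
        breaks = np.sort(rng.integers(0, cfg.genome_length, size=n_break))
        seg = np.searchsorted(breaks, positions, side="right")
        choice = rng.integers(0, K, size=n_break + 1)
        founders[f] = base[choice[seg], np.arange(n_loci)]
    # the sweep allele is not present at founding; it is introgressed on a
    # novel local haplotype mid-course (cf. the late-1960s semi-dwarf entry)
    sweep_idx = loci.index[loci["kind"] == "sweep"]
    if len(sweep_idx):
        founders[:, sweep_idx[0]] = 0

    N, G = cfg.pop_size, cfg.n_generations
    pop = founders[rng.integers(0, n_founders, size=N)]
    populations = [pop]
    parent_ids = [np.full((N, 2), -1)]
    freq_history = np.empty((G, n_loci))
    freq_history[0] = pop.mean(axis=0)

    intro_gen = cfg.sweep_intro_generation
    if intro_gen is None:
        intro_gen = G // 2
    sweep_pattern = None
    if len(sweep_idx):
        j = sweep_idx[0]
        window = np.abs(positions - positions[j]) <= seg_len // 2
        # introgressed lines carry the minor allele at every window site: a
        # haplotype rare in the founding population
        sweep_pattern = (founder_freqs < 0.5).astype(np.int8)[window]

    for g in range(1, G):
        if len(sweep_idx) and g == intro_gen:
            m = max(3, N // 20)
            lines = rng.choice(N, size=m, replace=False)
            pop = pop.copy()
            pop[np.ix_(lines, np.flatnonzero(window))] = sweep_pattern
            pop[lines, sweep_idx[0]] = 1
        logw = pop @ log_mult
        w = np.exp(logw - logw.max())
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("degenerate population: all fitness zero")
        p = w / total
        p1 = rng.choice(N, size=N, p=p)
        p2 = rng.choice(N, size=N, p=p)
        selfed = rng.random(N) < cfg.selfing_rate
        nxt = np.empty_like(pop)
        for i in range(N):
            if selfed[i]:
                nxt[i] = pop[p1[i]]
                p2[i] = p1[i]
            else:
                nxt[i] = _recombine(
                    pop[p1[i]], pop[p2[i]], positions, cfg.genome_length,
                    cfg.recomb_rate, rng,
                )
        parent_ids.append(np.column_stack([p1, p2]))
        pop = nxt
        populations.append(pop)
        freq_history[g] = pop.mean(axis=0)

    # sample varieties evenly across generations; release year maps linearly
    y0, y1 = cfg.year_range
    gens = np.linspace(0, G - 1, cfg.n_varieties).round().astype(int)
    meta_rows, geno_rows = [], []
    for v, g in enumerate(gens):
        i = int(rng.integers(0, N))
        year = int(round(y0 + g * (y1 - y0) / (G - 1)))
        pa, pb = parent_ids[g][i]
        meta_rows.append(
            {
                "variety_id": f"var{v:03d}",
                "release_year": year,
                "grain_type": "long" if rng.random() < 0.6 else "medium",
                "parent1": f"g{g - 1:02d}i{pa:03d}" if pa >= 0 else "",
                "parent2": f"g{g - 1:02d}i{pb:03d}" if pb >= 0 else "",
            }
        )
        geno_rows.append(populations[g][i])
    metadata = pd.DataFrame(meta_rows)
    genotypes = pd.DataFrame(
        np.array(geno_rows, dtype=np.int8),
        index=metadata["variety_id"],
        columns=loci["locus_id"],
    )
    return Cohort(
        metadata=metadata,
        genotypes=genotypes,
        loci=loci.copy(),
        freq_history=freq_history,
        populations=populations,
        sweep_locus_id="sweep" if len(sweep_idx) else None,
    )
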