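"""Random genomes, the bundled toy TE library, and synthetic gene models."""

from __future__ import annotations

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def gen_ancestor(length: int, gc: float = 0.43, seed: int | np.random.Generator = 0) -> str:
    """i.i.d. nucleotide sequence of exactly `length` bases with expected GC = gc."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _random_seq(length, gc, rng)


#: (family name, consensus length in bp) of the 8 bundled synthetic TE families,
#: spanning the 1-12 kb range of full-length plant retro- and DNA elements.
TOY_TE_FAMILIES = (
    ("TOY_MITE1", 1_000),
    ("TOY_MITE2", 1_800),
    ("TOY_DNA1", 2_500),
    ("TOY_COPIA1", 3_200),
    ("TOY_COPIA2", 4_000),
    ("TOY_COPIA3", 6_000),
    ("TOY_GYPSY1", 9_000),
    ("TOY_GYPSY2", 12_000),
)

_TE_LIBRARY_SEED = 715_019  # fixed: the library is a bundled constant


def toy_te_library() -> dict[str, str]:
    """The bundled synthetic TE library: 8 families, 1-12 kb.

    Generated deterministically in code (no data file); two calls return
    identical sequences.  Families carry 50 bp terminal repeats so that
    planted copies look element-like but are otherwise random sequence.
    """
    rng = np.random.default_rng(_TE_LIBRARY_SEED)
    lib: dict[str, str] = {}
    for name, length in TOY_TE_FAMILIES:
        tr = _random_seq(50, 0.5, rng)
        body = _random_seq(length - 100, 0.5, rng)
        lib[name] = tr + body + tr
    return lib


def nearest_te_family(length: int) -> tuple[str, str]:
    """Family whose consensus length is closest to the requested insert length."""
    lib = toy_te_library()
    name = min(lib, key=lambda k: abs(len(lib[k]) - length))
    return name, lib[name]


def gen_gene_models(
    genome_length: int,
    n_genes: int = 20,
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Synthetic gene models as a tidy table (GFF3-like, 0-based half-open).

    Each gene has 2-5 exons of 150-400 bp separated by 100-800 bp introns.
    Genes never overlap.  Columns: chrom, feature ("gene"/"exon"), start, end,
    strand, gene_id.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    cursor = int(rng.integers(200, 2_000))
    for i in range(n_genes):
        n_ex = int(rng.integers(2, 6))
        parts = []
        pos = cursor
        for j in range(n_ex):
            ex_len = int(rng.integers(150, 401))
            parts.append((pos, pos + ex_len))
            pos += ex_len
            if j < n_ex - 1:
                pos += int(rng.integers(100, 801))
        if pos >= genome_length - 200:
            break
        gid = f"gene{i:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, "gene", parts[0][0], parts[-1][1], strand, gid))
        for s, e in parts:
            rows.append((chrom, "exon", s, e, strand, gid))
        cursor = pos + int(rng.integers(500, 3_000))
    return pd.DataFrame(rows, columns=["chrom", "feature", "start", "end", "strand", "gene_id"])
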