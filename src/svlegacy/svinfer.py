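"""Structural-event inference from three-genome alignments.

Extracts >50 bp gap events, validates flanking alignment quality, polarizes
each event against the outgroup (the ingroup matching the outgroup carries the
ancestral state; the other ingroup mutated), computes the gap-coverage value
g = derived bases / (derived + ancestral bases) over the event region, and
classifies each event as insertion (g > 0.95), deletion (g < 0.05), balanced
artifact (0.49 <= g <= 0.51, dropped) or mixed.

Events private to the outgroup cannot be polarized and are never emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment import GAP, TripleAlignment

logger = logging.getLogger(__name__)

LINEAGE_ROW = {"A": 0, "B": 1}


@dataclass
class GapCandidate:
    """A maximal gap-containing column region plus its two flanks."""

    aln: TripleAlignment = field(repr=False)
    col_start: int
    col_end: int
    flank: int = 50

    @property
    def flank_left(self) -> tuple[int, int]:
        return self.col_start - self.flank, self.col_start

    @property
    def flank_right(self) -> tuple[int, int]:
        return self.col_end, self.col_end + self.flank

    def region(self) -> np.ndarray:
        return self.aln.array[:, self.col_start : self.col_end]


@dataclass
class PolarizedSV:
    """One polarized >50 bp event."""

    chrom: str
    lineage: str                     # "A" or "B": the lineage that mutated
    col_interval: tuple[int, int]
    intervals: dict[str, tuple[int, int]]  # per-genome half-open intervals
    ancestral_seq: str
    derived_seq: str
    gap_coverage: float
    indel_class: str                 # insertion | deletion | mixed | dropped_balanced
    length: int                      # net |derived - ancestral| bp
    genic_context: str | None = None
    d: float | None = None           # filled by the mechanism classifier
    mechanism: str | None = None

    @property
    def net_gain(self) -> int:
        return len(self.derived_seq) - len(self.ancestral_seq)


def _max_gap_run(mask_row: np.ndarray) -> int:
    """Longest run of True in a 1-D boolean array."""
    if not mask_row.any():
        return 0
    padded = np.concatenate([[False], mask_row, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[0::2]).max())


def extract_candidates(
    aln: TripleAlignment, min_gap: int = 50, flank: int = 50
) -> list[GapCandidate]:
    """One candidate per maximal region of gap-containing columns that holds a
    gap run strictly longer than `min_gap` in at least one row.

    Candidates whose flank would run off the chromosome are discarded (logged).
    """
    mask = aln.gap_mask()
    any_gap = mask.any(axis=0)
    if not any_gap.any():
        return []
    padded = np.concatenate([[False], any_gap, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out = []
    for s, e in zip(edges[0::2], edges[1::2]):
        if max(_max_gap_run(mask[r, s:e]) for r in range(3)) <= min_gap:
            continue
        if s - flank < 0 or e + flank > aln.ncols:
            logger.info("candidate [%d, %d) discarded: flank off chromosome", s, e)
            continue
        out.append(GapCandidate(aln=aln, col_start=int(s), col_end=int(e), flank=flank))
    return out


def flank_pass(c: GapCandidate, min_ident: float = 0.90) -> bool:
    """True iff in each flank separately, strictly more than `min_ident` of
    columns carry the same non-gap base in all three rows."""
    arr = c.aln.array
    for s, e in (c.flank_left, c.flank_right):
        cols = arr[:, s:e]
        ident = (
            (cols[0] == cols[1]) & (cols[1] == cols[2]) & (cols[0] != GAP)
        ).mean()
        if not ident > min_ident:
            return False
    return True


def _pair_identity(region: np.ndarray, r1: int, r2: int) -> float:
    """Matching non-gap columns / max ungapped length of the pair.

    Two rows that are both entirely gapped over the region are identical by
    convention (identity 1): they share the ancestral absence of sequence.
    """
    a, b = region[r1], region[r2]
    len_a = int((a != GAP).sum())
    len_b = int((b != GAP).sum())
    denom = max(len_a, len_b)
    if denom == 0:
        return 1.0
    matches = int(((a == b) & (a != GAP)).sum())
    return matches / denom


def polarize(c: GapCandidate, min_ident: float = 0.95) -> str:
    """Assign the event's lineage of origin, or discard.

    Returns "A" or "B" (the mutated ingroup), "discard_same" when the two
    ingroups share >= `min_ident` identity over the region (no ingroup event),
    or "discard_ambiguous" when neither or both ingroups match the outgroup —
    which covers outgroup-private events.
    """
    region = c.region()
    if _pair_identity(region, 0, 1) >= min_ident:
        return "discard_same"
    a_match = _pair_identity(region, 0, 2) > min_ident
    b_match = _pair_identity(region, 1, 2) > min_ident
    if a_match and not b_match:
        return "B"
    if b_match and not a_match:
        return "A"
    return "discard_ambiguous"


def gap_coverage(c: GapCandidate, lineage: str) -> float:
    """g = derived bases / (derived + ancestral bases) over the event region.

    g -> 1 is a pure insertion, g -> 0 a pure deletion.  The ancestral length
    is measured on the non-mutated ingroup (the one matching the outgroup).
    """
    region = c.region()
    derived_row = LINEAGE_ROW[lineage]
    ancestral_row = 1 - derived_row
    l_der = int((region[derived_row] != GAP).sum())
    l_anc = int((region[ancestral_row] != GAP).sum())
    if l_der + l_anc == 0:
        raise ValueError("empty event region")
    return l_der / (l_der + l_anc)


def classify_indel(g: float) -> str:
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must be in [0, 1]")
    if 0.49 <= g <= 0.51:
        return "dropped_balanced"
    if g > 0.95:
        return "insertion"
    if g < 0.05:
        return "deletion"
    return "mixed"


def infer_all(
    aln: TripleAlignment,
    min_gap: int = 50,
    flank: int = 50,
    flank_min_ident: float = 0.90,
    region_min_ident: float = 0.95,
    gene_models: pd.DataFrame | None = None,
) -> list[PolarizedSV]:
    """Full inference chain: extract, flank-check, polarize, classify."""
    svs: list[PolarizedSV] = []
    for c in extract_candidates(aln, min_gap=min_gap, flank=flank):
        if not flank_pass(c, min_ident=flank_min_ident):
            continue
        lineage = polarize(c, min_ident=region_min_ident)
        if lineage.startswith("discard"):
            continue
        g = gap_coverage(c, lineage)
        derived_row = LINEAGE_ROW[lineage]
        region = c.region()
        derived_seq = region[derived_row][region[derived_row] != GAP].tobytes().decode()
        anc_row = 1 - derived_row
        ancestral_seq = region[anc_row][region[anc_row] != GAP].tobytes().decode()
        intervals = {
            name: aln.seq_interval(r, c.col_start, c.col_end)
            for r, name in enumerate(("A", "B", "outgroup"))
        }
        svs.append(
            PolarizedSV(
                chrom=aln.chrom,
                lineage=lineage,
                col_interval=(c.col_start, c.col_end),
                intervals=intervals,
                ancestral_seq=ancestral_seq,
                derived_seq=derived_seq,
                gap_coverage=g,
                indel_class=classify_indel(g),
                length=abs(len(derived_seq) - len(ancestral_seq)),
            )
        )
    if gene_models is not None:
        annotate_context(svs, gene_models)
    return svs


def net_gain_summary(svs: list[PolarizedSV]) -> dict[str, int]:
    """Per-lineage sum of (derived - ancestral) bp, balanced events excluded."""
    out = {"A": 0, "B": 0}
    for sv in svs:
        if sv.indel_class == "dropped_balanced":
            continue
        out[sv.lineage] += sv.net_gain
    return out


def annotate_context(
    svs: list[PolarizedSV],
    gene_models: pd.DataFrame,
    reference: str = "A",
) -> list[PolarizedSV]:
    """Genic context by overlap of the reference-genome interval.

    Precedence exon > intron > intergenic: any >= 1 bp exon overlap is exonic;
    otherwise an overlap with a gene body is intronic.  Zero-length intervals
    (pure insertions into the reference) are treated as 1 bp points.
    """
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for _, r in gene_models.iterrows():
        tree = (exon_trees if r.feature == "exon" else gene_trees).setdefault(
            r.chrom, IntervalTree()
        )
        if r.end > r.start:
            tree[int(r.start) : int(r.end)] = r.gene_id
    for sv in svs:
        if sv.chrom not in exon_trees and sv.chrom not in gene_trees:
            logger.warning("unknown chromosome %s: context left missing", sv.chrom)
            sv.genic_context = None
            continue
        s, e = sv.intervals[reference]
        if e == s:
            e = s + 1
        if sv.chrom in exon_trees and exon_trees[sv.chrom].overlap(s, e):
            sv.genic_context = "exonic"
        elif sv.chrom in gene_trees and gene_trees[sv.chrom].overlap(s, e):
            sv.genic_context = "intronic"
        else:
            sv.genic_context = "intergenic"
    return svs


def sv_table(svs: list[PolarizedSV]) -> pd.DataFrame:
    """Tabular SV summary (mirrors the published per-event table)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in svs],
            "ancestral_start": [s.intervals["A" if s.lineage == "B" else "B"][0] for s in svs],
            "ancestral_end": [s.intervals["A" if s.lineage == "B" else "B"][1] for s in svs],
            "lineage": [s.lineage for s in svs],
            "g": [s.gap_coverage for s in svs],
            "class": [s.indel_class for s in svs],
            "length": [s.length for s in svs],
            "context": [s.genic_context for s in svs],
            "d": [s.d for s in svs],
            "mechanism": [s.mechanism for s in svs],
        }
    )
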