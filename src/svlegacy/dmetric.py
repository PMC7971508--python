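"""Mechanism classification of indels via the d statistic.

For each polarized indel of length L, the ancestral and derived contexts
(allele plus L bp of flank on each side) are locally aligned under
match +1 / mismatch -2 with affine gap penalties open 2 / extend 4.  The two
major local alignments are found (the second after masking the first's
footprint on the longer context), ordered along the longer context, and d is
the signed overlap of their projections onto the shorter context:

* d = 0   — direct integration of ectopic DNA (the two flank alignments abut),
* d = L   — perfect tandem duplication,
* d > L   — slippage-like events that re-use an annealing site beyond the flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import beta

MECHANISMS = ("tandem", "ectopic", "slippage_like", "unclassified")


@dataclass(frozen=True)
class Segment:
    """A local alignment footprint on the two contexts (0-based half-open)."""

    s1_start: int
    s1_end: int
    s2_start: int
    s2_end: int
    score: float


@dataclass
class MechanismCall:
    d: float | None
    indel_length: int
    mechanism: str
    segments: tuple[Segment, ...] = ()


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    # blastn-style cost: a gap of length k costs open + k*extend = 2 + 4k
    al.open_gap_score = -6
    al.extend_gap_score = -4
    return al


def build_contexts(
    sv, genomes: dict[str, str]
) -> tuple[str, str, int]:
    """(ancestral context, derived context, L) for a polarized SV.

    Contexts are left flank (L bp) + allele + right flank (L bp); for a pure
    insertion the ancestral allele is empty.  Raises ValueError when a flank
    would run off a chromosome end.
    """
    derived = sv.lineage
    ancestral = "A" if derived == "B" else "B"
    L = max(len(sv.derived_seq), len(sv.ancestral_seq))
    if L == 0:
        raise ValueError("zero-length event")
    out = []
    for name, allele in ((ancestral, sv.ancestral_seq), (derived, sv.derived_seq)):
        genome = genomes[name]
        s, e = sv.intervals[name]
        if s - L < 0 or e + L > len(genome):
            raise ValueError("insufficient flank near chromosome end")
        out.append(genome[s - L : s] + allele + genome[e : e + L])
    return out[0], out[1], L


def _trim_to_anchors(best, min_anchor: int = 10) -> tuple[int, int, int, int] | None:
    """Footprint of an alignment trimmed to its outermost >= min_anchor
    consecutive-match runs.

    Local alignments chance-extend a few score-positive columns past the true
    homology boundary; requiring the retained ends to sit on a solid run of
    matched identical bases removes those spurious edges (a random run of 10
    matches has probability 4^-10 per end).
    """
    t, q = str(best.target), str(best.query)
    coords = best.coordinates
    pos_t, pos_q, match = [], [], []
    for i in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if t1 > t0 and q1 > q0:  # aligned block (no gap)
            for j in range(t1 - t0):
                pos_t.append(t0 + j)
                pos_q.append(q0 + j)
                match.append(t[t0 + j] == q[q0 + j])
    m = np.asarray(match, dtype=bool)
    if m.size < min_anchor:
        return None
    # run length of consecutive matches ending at each column
    runs = np.zeros(m.size, dtype=np.int64)
    acc = 0
    for i, ok in enumerate(m):
        acc = acc + 1 if ok else 0
        runs[i] = acc
    anchored = np.flatnonzero(runs >= min_anchor)
    if anchored.size == 0:
        return None
    first = int(anchored[0]) - min_anchor + 1
    last = int(anchored[-1])
    return pos_t[first], pos_t[last] + 1, pos_q[first], pos_q[last] + 1


def _best_alignment(al, s1: str, s2: str, min_score: float) -> Segment | None:
    if not s1 or not s2:
        return None
    try:
        alns = al.align(s1, s2)
        best = alns[0]
    except (IndexError, ValueError):
        return None
    if best.score < min_score:
        return None
    fp = _trim_to_anchors(best)
    if fp is None:
        return None
    return Segment(
        s1_start=fp[0], s1_end=fp[1], s2_start=fp[2], s2_end=fp[3],
        score=float(best.score),
    )


def _mask(seq: str, start: int, end: int) -> str:
    return seq[:start] + "N" * (end - start) + seq[end:]


def two_major_alignments(
    s1: str, s2: str, min_score: float = 20.0, anneal_margin: int = 25
) -> tuple[Segment, Segment] | None:
    """The two major local alignments of the two contexts.

    The second alignment is found after masking the first's footprint on the
    longer of the two sequences.  The mask is shrunk by `anneal_margin` bp at
    each edge: slippage-like events re-use a short annealing site, so the two
    major alignments legitimately overlap by a few bases at the anneal, and a
    hard full-footprint mask would erase that signal (collapsing slippage onto
    tandem).  A second alignment that still falls entirely inside the first's
    footprint is rejected and recomputed under the full mask.  Returns the
    pair ordered by start position on the longer sequence, or None when fewer
    than two segments reach `min_score`.
    """
    al = _aligner()
    m1 = _best_alignment(al, s1, s2, min_score)
    if m1 is None:
        return None
    s1_longer = len(s1) >= len(s2)
    fp = (m1.s1_start, m1.s1_end) if s1_longer else (m1.s2_start, m1.s2_end)
    # annealing sites scale with event size; so does the unmasked edge
    margin = max(anneal_margin, round(0.1 * (fp[1] - fp[0])))
    lo = fp[0] + margin
    hi = max(lo, fp[1] - margin)

    def _second(a: int, b: int) -> Segment | None:
        if s1_longer:
            return _best_alignment(al, _mask(s1, a, b), s2, min_score)
        return _best_alignment(al, s1, _mask(s2, a, b), min_score)

    m2 = _second(lo, hi)
    if m2 is not None:
        m2_fp = (m2.s1_start, m2.s1_end) if s1_longer else (m2.s2_start, m2.s2_end)
        if fp[0] <= m2_fp[0] and m2_fp[1] <= fp[1]:  # echo of m1's own edges
            m2 = _second(*fp)
    if m2 is None:
        return None
    key = (lambda m: m.s1_start) if s1_longer else (lambda m: m.s2_start)
    top, bottom = sorted((m1, m2), key=key)
    return top, bottom


def compute_d(top: Segment, bottom: Segment, shorter: str) -> int:
    """Signed overlap of the two segments' projections on the shorter context.

    `shorter` is "s1" or "s2" — which of the two aligned sequences is the
    shorter one.  Segments must already be ordered along the longer sequence.
    """
    if shorter == "s1":
        return top.s1_end - bottom.s1_start
    return top.s2_end - bottom.s2_start


def classify_mechanism(
    d: float | None, L: int, tol_bp: float = 2.0, tol_frac: float = 0.05
) -> str:
    if d is None:
        return "unclassified"
    tol = max(tol_bp, tol_frac * L)
    if abs(d - L) <= tol:
        return "tandem"
    if abs(d) <= tol:
        return "ectopic"
    if d > L + tol:
        return "slippage_like"
    return "unclassified"


def call_mechanism(
    anc_ctx: str, der_ctx: str, L: int, min_score: float = 20.0,
    tol_bp: float = 2.0, tol_frac: float = 0.05,
) -> MechanismCall:
    """d and mechanism for one pair of contexts."""
    pair = two_major_alignments(anc_ctx, der_ctx, min_score)
    if pair is None:
        return MechanismCall(d=None, indel_length=L, mechanism="unclassified")
    top, bottom = pair
    shorter = "s1" if len(anc_ctx) < len(der_ctx) else "s2"
    d = compute_d(top, bottom, shorter)
    return MechanismCall(
        d=d,
        indel_length=L,
        mechanism=classify_mechanism(d, L, tol_bp, tol_frac),
        segments=(top, bottom),
    )


def classify_svs(svs, genomes: dict[str, str]) -> list[MechanismCall]:
    """Annotate each PolarizedSV in place with d and mechanism."""
    calls = []
    for sv in svs:
        try:
            anc_ctx, der_ctx, L = build_contexts(sv, genomes)
        except ValueError:
            call = MechanismCall(d=None, indel_length=sv.length, mechanism="unclassified")
        else:
            call = call_mechanism(anc_ctx, der_ctx, L)
        sv.d = call.d
        sv.mechanism = call.mechanism
        calls.append(call)
    return calls


def tandem_curve(
    calls: list[MechanismCall], length_bins: list[int], conf: float = 0.95
) -> pd.DataFrame:
    """Proportion of tandem calls per indel-length bin with a binomial CI.

    Bins are right-open intervals over `length_bins` edges; empty bins are
    omitted.  The CI is the equal-tailed Jeffreys interval.
    """
    edges = np.asarray(length_bins)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = [c for c in calls if lo <= c.indel_length < hi]
        if not sub:
            continue
        n = len(sub)
        k = sum(c.mechanism == "tandem" for c in sub)
        a = (1 - conf) / 2
        lo_ci = beta.ppf(a, k + 0.5, n - k + 0.5) if k > 0 else 0.0
        hi_ci = beta.ppf(1 - a, k + 0.5, n - k + 0.5) if k < n else 1.0
        rows.append(
            {
                "bin_lo": int(lo),
                "bin_hi": int(hi),
                "n": n,
                "prop_tandem": k / n,
                "ci_lo": float(lo_ci),
                "ci_hi": float(hi_ci),
            }
        )
    return pd.DataFrame(rows)
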