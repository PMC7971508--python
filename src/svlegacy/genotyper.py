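"""Read-contiguity genotyping of pre-ascertained SV loci.

Split and soft-clipped reads are removed (multiply-mapped reads are kept to
preserve contiguity).  A locus is called for the reference (ancestral) allele
when >98% of the reference interval is covered by at least one read — or, for
intervals shorter than 20 bp, when at least one read spans the interval plus
5 bp on each side.  The derived call requires the reference support to fail
while both 50 bp flanks carry at least one read (so that missing data is not
mistaken for a derived allele); anything else is missing (NA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata.reads import ReadEvidence

REF_COVER_MIN = 0.98
SHORT_INTERVAL = 20
SHORT_SPAN_PAD = 5
FLANK = 50


def filter_reads(ev: ReadEvidence) -> ReadEvidence:
    """Drop split and soft-clipped reads; everything else is kept."""
    keep = ~(ev.reads["is_split"] | ev.reads["is_softclipped"])
    return ReadEvidence(
        sample_id=ev.sample_id,
        reads=ev.reads[keep].reset_index(drop=True),
        mean_depth=ev.mean_depth,
    )


def _covered_fraction(starts: np.ndarray, ends: np.ndarray, lo: int, hi: int) -> float:
    if hi <= lo:
        return 1.0
    s = np.clip(starts, lo, hi)
    e = np.clip(ends, lo, hi)
    order = np.argsort(s)
    covered = 0
    cursor = lo
    for i in order:
        a, b = int(s[i]), int(e[i])
        if b <= cursor:
            continue
        covered += b - max(a, cursor)
        cursor = b
    return covered / (hi - lo)


def _any_read(starts, ends, lo, hi) -> bool:
    return bool(((starts < hi) & (ends > lo)).any())


def call_allele(
    ev: ReadEvidence, locus: tuple[str, int, int], filtered: bool = False
):
    """Allele call {0, 1, NA} for one reference-genome interval.

    `locus` is (chrom, start, end) on the genome carrying the ancestral
    (reference) allele.  Pass ``filtered=True`` when split/soft-clipped reads
    were already removed.
    """
    chrom, start, end = locus
    if end < start:
        raise ValueError("locus end before start")
    if not filtered:
        ev = filter_reads(ev)
    reads = ev.reads
    reads = reads[reads["chrom"] == chrom]
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    length = end - start
    if length < SHORT_INTERVAL:
        spanning = (
            (starts <= start - SHORT_SPAN_PAD) & (ends >= end + SHORT_SPAN_PAD)
        ).any()
        if spanning:
            return 0
    elif _covered_fraction(starts, ends, start, end) > REF_COVER_MIN:
        return 0
    left_ok = _any_read(starts, ends, start - FLANK, start)
    right_ok = _any_read(starts, ends, end, end + FLANK)
    if left_ok and right_ok:
        return 1
    return pd.NA


def genotype_cohort(
    evidence: dict[str, ReadEvidence], loci: pd.DataFrame
) -> pd.DataFrame:
    """Loci x samples matrix over {0, 1, NA} (pandas Int8, NA = missing).

    `loci` needs columns locus_id, chrom, start, end.
    """
    out = {}
    for sample, ev in evidence.items():
        fev = filter_reads(ev)
        out[sample] = [
            call_allele(fev, (r.chrom, int(r.start), int(r.end)), filtered=True)
            for r in loci.itertuples()
        ]
    return pd.DataFrame(out, index=loci["locus_id"], dtype="Int8")


def downsample_assessment(
    ev: ReadEvidence,
    loci: pd.DataFrame,
    targets: tuple[float, ...] = (22, 31, 40),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """False-negative rate of derived calls after downsampling to target depths.

    The sample is assumed all-derived at every locus (the truth), so any
    reference call is a false negative.  Reads are subsampled uniformly
    (seeded) to each target depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ev.mean_depth is None or not np.isfinite(ev.mean_depth):
        raise ValueError("evidence must carry its mean depth")
    rows = []
    for target in targets:
        if target > ev.mean_depth:
            raise ValueError(f"target depth {target} above available {ev.mean_depth}")
        p = target / ev.mean_depth
        keep = rng.random(len(ev.reads)) < p
        sub = ReadEvidence(
            sample_id=ev.sample_id,
            reads=ev.reads[keep].reset_index(drop=True),
            mean_depth=target,
        )
        calls = genotype_cohort({ev.sample_id: sub}, loci)[ev.sample_id]
        fn = float((calls == 0).sum() / len(calls)) if len(calls) else float("nan")
        rows.append({"target_depth": target, "false_negative_rate": fn, "n_loci": len(calls)})
    return pd.DataFrame(rows)


def coverage_bias_check(
    matrix: pd.DataFrame, coverage: pd.Series
) -> dict[str, float]:
    """Regress per-sample reference-call fraction on sequencing coverage.

    Returns r, the p-value and R^2; a constant-coverage input has an undefined
    slope and is flagged with NaNs.
    """
    ref_frac = (matrix == 0).sum(axis=0) / matrix.notna().sum(axis=0)
    cov = coverage.loc[ref_frac.index].astype(float)
    if cov.nunique() < 2:
        return {"r": float("nan"), "p_value": float("nan"), "r_squared": float("nan"),
                "flagged_constant_coverage": True}
    res = stats.linregress(cov.to_numpy(), ref_frac.to_numpy())
    return {
        "r": float(res.rvalue),
        "p_value": float(res.pvalue),
        "r_squared": float(res.rvalue**2),
        "flagged_constant_coverage": False,
    }
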