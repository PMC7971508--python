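"""Allele-frequency change through breeding time, by mutational class.

Every variant (SV or SNP) is coded 0 = ancestral / 1 = derived per variety;
the per-variant rate of change is the OLS slope of allelic state on
year-of-release.  Rates are compared across six mutational classes (exonic /
intronic / intergenic SVs; stop-gain / non-synonymous / synonymous SNPs)
with a least-significant-difference test under FDR adjustment, per-variety
exonic burden is regressed on release year by grain type, per-LD-block
haplotype scores are regressed on year, and parent/progeny trios provide an
inheritance-bias check that is immune to population structure.
"""

from __future__ import annotations

import itertools
import string

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata.config import VARIANT_CLASSES
from .synthdata.trios import Trio


# ---------------------------------------------------------------- preparation

def encode_and_filter(
    matrix: pd.DataFrame,
    classes: pd.Series,
    derived_lineage: pd.Series | None = None,
    reference_lineage: str = "A",
    maf_min: float = 0.1,
) -> pd.DataFrame:
    """Derived-coded variant records passing the frequency and lineage filters.

    `matrix` is loci x varieties over {0, 1, NA} (derived coding).  Variants
    whose derived allele arose in the reference lineage are excluded (rates
    are interpretable only when the reference carries the ancestral state),
    as are variants with minor allele frequency <= `maf_min` among non-missing
    calls (fixed variants fall out of the same rule).
    """
    keep = pd.Series(True, index=matrix.index)
    if derived_lineage is not None:
        keep &= derived_lineage.reindex(matrix.index) != reference_lineage
    freq = matrix.mean(axis=1, skipna=True).astype(float)
    maf = np.minimum(freq, 1.0 - freq)
    keep &= pd.Series(maf > maf_min, index=matrix.index)
    out = matrix[keep].copy()
    out.insert(0, "class_", classes.reindex(out.index))
    return out


# --------------------------------------------------------------- rate-of-change

def rate_of_change(records: pd.DataFrame, release_years: pd.Series) -> pd.DataFrame:
    """Per-variant OLS slope of allelic state (0/1) on year of release.

    Missing genotypes are excluded per variant.  Returns variant_id, class_,
    slope (frequency units per year) and n_used.
    """
    has_class = "class_" in records.columns
    geno = records.drop(columns=["class_"]) if has_class else records
    years = release_years.reindex(geno.columns).to_numpy(dtype=float)
    rows = []
    for vid, row in geno.iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < 3 or np.ptp(years[ok]) == 0:
            slope = np.nan
        else:
            xc = years[ok] - years[ok].mean()
            yc = y[ok] - y[ok].mean()
            slope = float((xc * yc).sum() / (xc * xc).sum())
        rows.append(
            {
                "variant_id": vid,
                "class_": records.loc[vid, "class_"] if has_class else None,
                "slope": slope,
                "n_used": n,
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


# ------------------------------------------------------------------- LSD test

def lsd_grouping(rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Least-significant-difference letters over classes, FDR-adjusted.

    One-way ANOVA supplies the pooled error variance; every pair of classes is
    compared with a t statistic on the pooled SE; p-values are
    Benjamini-Hochberg adjusted; classes not separated by any significant
    difference share a letter.
    """
    df = rates.dropna(subset=["slope", "class_"])
    groups = {c: g["slope"].to_numpy() for c, g in df.groupby("class_")}
    names = sorted(groups, key=lambda c: np.mean(groups[c]))
    k = len(names)
    if k < 2:
        raise ValueError("need at least two classes")
    n_total = sum(len(v) for v in groups.values())
    dof = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / dof
    pairs = list(itertools.combinations(names, 2))
    pvals = []
    for a, b in pairs:
        se = np.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])))
        t = (np.mean(groups[a]) - np.mean(groups[b])) / se
        pvals.append(2 * stats.t.sf(abs(t), dof))
    adj = multipletests(pvals, method="fdr_bh")[1]
    sig = {pair: p < alpha for pair, p in zip(pairs, adj)}

    # insert-and-absorb letter assignment on mean-ordered classes
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all(not sig.get(tuple(sorted((name, o))), False) for o in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb redundant sets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    letters = {name: "" for name in names}
    for s, ch in zip(letter_sets, string.ascii_lowercase):
        for name in s:
            letters[name] += ch
    out = pd.DataFrame(
        {
            "class_": names,
            "mean_slope": [float(np.mean(groups[c])) for c in names],
            "median_slope": [float(np.median(groups[c])) for c in names],
            "n": [len(groups[c]) for c in names],
            "letters": [letters[c] for c in names],
        }
    ).set_index("class_")
    pair_df = pd.DataFrame(
        {
            "class_a": [a for a, _ in pairs],
            "class_b": [b for _, b in pairs],
            "p_raw": pvals,
            "p_adj": adj,
        }
    )
    out.attrs["pairwise"] = pair_df
    return out


# ------------------------------------------------------------------ burden fit

def burden_regression(
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    class_: str = "exonic_SV",
    na_mode: str = "zero",
) -> pd.DataFrame:
    """Per-variety derived burden of one class regressed on release year.

    Separate OLS fits per grain type plus a combined fit.  `na_mode` "zero"
    counts missing genotypes as 0 (reporting the informative-call count);
    "drop" scales the burden to the per-variety informative fraction.
    """
    sub = records[records["class_"] == class_].drop(columns=["class_"])
    meta = metadata.set_index("variety_id")
    if na_mode == "zero":
        burden = sub.fillna(0).sum(axis=0)
    elif na_mode == "drop":
        informative = sub.notna().sum(axis=0).replace(0, np.nan)
        burden = sub.sum(axis=0, skipna=True) * len(sub) / informative
    else:
        raise ValueError("na_mode must be 'zero' or 'drop'")
    rows = []
    frames = [("combined", meta.index)]
    frames += [(gt, meta.index[meta["grain_type"] == gt]) for gt in sorted(meta["grain_type"].unique())]
    for label, idx in frames:
        y = burden.reindex(idx).to_numpy(dtype=float)
        x = meta.loc[idx, "release_year"].to_numpy(dtype=float)
        if len(idx) < 3 or np.ptp(x) == 0:
            continue
        if np.ptp(y) == 0:  # constant burden: no trend by definition
            slope, r2, p = 0.0, 0.0, 1.0
        else:
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            slope, r2, p = float(fit.params[1]), float(fit.rsquared), float(fit.pvalues[1])
        rows.append(
            {
                "grain_type": label,
                "slope": slope,
                "r_squared": r2,
                "p_value": p,
                "n": len(idx),
                "informative_loci": int(sub.notna().sum(axis=0).reindex(idx).min()),
            }
        )
    return pd.DataFrame(rows).set_index("grain_type")


# --------------------------------------------------------------- block scores

def block_score_regression(
    blocks: list[pd.Index] | list[list[str]],
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    class_: str = "exonic_SV",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-block haplotype-score trend and its relation to score variance.

    A block's haplotype score per variety is the count of derived `class_`
    variants it carries among the block's loci; the per-block coefficient is
    the OLS slope of score on release year.  Blocks with zero score variance
    are excluded.  The summary is a class-level OLS of coefficients on score
    variances with a 95% CI on the slope.
    """
    sub = records[records["class_"] == class_].drop(columns=["class_"])
    years = metadata.set_index("variety_id")["release_year"]
    rows = []
    for i, loci in enumerate(blocks):
        loci = [l for l in loci if l in sub.index]
        if not loci:
            continue
        score = sub.loc[loci].fillna(0).sum(axis=0)
        var = float(score.var(ddof=1))
        if var == 0 or np.isnan(var):
            continue
        x = years.reindex(score.index).to_numpy(dtype=float)
        xc = x - x.mean()
        coef = float((xc * (score - score.mean())).sum() / (xc * xc).sum())
        rows.append({"block": i, "coefficient": coef, "score_variance": var})
    per_block = pd.DataFrame(rows)
    if len(per_block) < 3:
        return per_block, {"slope": float("nan"), "ci_low": float("nan"),
                           "ci_high": float("nan"), "p_value": float("nan")}
    fit = sm.OLS(
        per_block["coefficient"].to_numpy(),
        sm.add_constant(per_block["score_variance"].to_numpy()),
    ).fit()
    lo, hi = fit.conf_int()[1]
    summary = {
        "slope": float(fit.params[1]),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_value": float(fit.pvalues[1]),
    }
    return per_block, summary


# ----------------------------------------------------------------------- trios

def trio_analysis(
    trios: list[Trio],
    classes: pd.Series,
    locus_ids: list[str] | None = None,
    min_segregating: int = 10,
    max_miscall_ratio: float = 0.35,
) -> pd.DataFrame:
    """Derived-allele inheritance bias per SV across trios.

    A trio segregates for a variant when its parents differ; a miscall is a
    progeny call matching neither parent (detectable only at non-segregating
    loci in biallelic coding).  Trios whose miscall/segregating ratio exceeds
    `max_miscall_ratio` are dropped, then variants segregating in fewer than
    `min_segregating` trios and variants with one allele never inherited
    (suggesting a common-parent miscall) are removed.  Bias is the fraction of
    segregating trios in which the derived allele was inherited.
    """
    if locus_ids is None:
        locus_ids = list(classes.index)
    cls = classes.reindex(locus_ids)
    kept = []
    for trio in trios:
        seg = trio.parent1 != trio.parent2
        miscall = (~seg) & (trio.progeny != trio.parent1)
        n_seg = int(seg.sum())
        if n_seg == 0:
            continue
        if miscall.sum() / n_seg > max_miscall_ratio:
            continue
        kept.append(trio)
    rows = []
    for j, vid in enumerate(locus_ids):
        seg_trios = [t for t in kept if t.parent1[j] != t.parent2[j]]
        n_seg = len(seg_trios)
        if n_seg < min_segregating:
            continue
        derived_inherited = sum(int(t.progeny[j] == 1) for t in seg_trios)
        if derived_inherited == 0 or derived_inherited == n_seg:
            continue  # one allele never inherited: likely common-parent miscall
        rows.append(
            {
                "variant_id": vid,
                "class_": cls.get(vid),
                "n_segregating": n_seg,
                "derived_inherited": derived_inherited,
                "bias": derived_inherited / n_seg,
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "class_", "n_segregating",
                                       "derived_inherited", "bias"]).set_index("variant_id")


__all__ = [
    "VARIANT_CLASSES",
    "encode_and_filter",
    "rate_of_change",
    "lsd_grouping",
    "burden_regression",
    "block_score_regression",
    "trio_analysis",
]
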