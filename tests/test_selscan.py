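"""Rates of change, LSD grouping, burden and block-score regressions, trios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from svlegacy.selscan import (
    block_score_regression,
    burden_regression,
    encode_and_filter,
    lsd_grouping,
    rate_of_change,
    trio_analysis,
)
from svlegacy.synthdata.trios import Trio


def _records(matrix, classes=None):
    out = matrix.copy()
    out.insert(0, "class_", classes if classes is not None else "exonic_SV")
    return out


class TestEncodeAndFilter:
    def _matrix(self, freqs, n=20):
        rows = {}
        rng = np.random.default_rng(0)
        for i, f in enumerate(freqs):
            k = int(round(f * n))
            row = np.zeros(n)
            row[rng.choice(n, size=k, replace=False)] = 1
            rows[f"v{i}"] = row
        return pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T

    def test_low_frequency_excluded(self):
        m = self._matrix([0.05, 0.3])
        classes = pd.Series(["exonic_SV", "exonic_SV"], index=m.index)
        rec = encode_and_filter(m, classes)
        assert list(rec.index) == ["v1"]

    def test_fixed_variant_excluded(self):
        m = self._matrix([1.0, 0.0, 0.5])
        classes = pd.Series("syn_SNP", index=m.index)
        rec = encode_and_filter(m, classes)
        assert list(rec.index) == ["v2"]

    def test_reference_lineage_derived_excluded(self):
        m = self._matrix([0.3, 0.3])
        classes = pd.Series("exonic_SV", index=m.index)
        lineage = pd.Series(["A", "B"], index=m.index)
        rec = encode_and_filter(m, classes, derived_lineage=lineage)
        assert list(rec.index) == ["v1"]


class TestRateOfChange:
    def test_constant_alleles_zero_slope(self):
        years = pd.Series([1900, 1950, 2000], index=["a", "b", "c"])
        m = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["v"])
        r = rate_of_change(_records(m), years)
        assert r.loc["v", "slope"] == 0.0

    def test_four_point_hand_case(self):
        # OLS on years (1900, 1940, 1980, 2020) vs alleles (1, 1, 0, 0):
        # slope = sum(xc*yc)/sum(xc^2) = -80/8000 = -0.01 per year
        years = pd.Series([1900, 1940, 1980, 2020], index=list("abcd"))
        m = pd.DataFrame({"a": [1], "b": [1], "c": [0], "d": [0]}, index=["v"])
        r = rate_of_change(_records(m), years)
        assert r.loc["v", "slope"] == pytest.approx(-0.01)
        assert r.loc["v", "slope"] == pytest.approx(
            np.polyfit(years.to_numpy(float), [1, 1, 0, 0], 1)[0]
        )

    def test_permutation_null_centered(self, rng):
        years = pd.Series(np.linspace(1905, 2013, 40), index=[f"s{i}" for i in range(40)])
        alleles = rng.integers(0, 2, size=40)
        slopes = []
        for _ in range(1000):
            perm = rng.permutation(years.to_numpy())
            m = pd.DataFrame([alleles], index=["v"], columns=years.index)
            slopes.append(
                rate_of_change(_records(m), pd.Series(perm, index=years.index)).loc[
                    "v", "slope"
                ]
            )
        s = np.asarray(slopes)
        assert abs(s.mean()) < 3 * s.std(ddof=1) / np.sqrt(s.size)

    def test_missing_calls_excluded(self):
        years = pd.Series([1900, 1950, 2000, 2010], index=list("abcd"))
        m = pd.DataFrame({"a": [1.0], "b": [np.nan], "c": [0.0], "d": [0.0]}, index=["v"])
        r = rate_of_change(_records(m), years)
        assert r.loc["v", "n_used"] == 3

    @given(st.integers(0, 2**31 - 1))
    def test_slope_antisymmetric_under_allele_flip(self, seed):
        rng = np.random.default_rng(seed)
        years = pd.Series(
            rng.integers(1900, 2014, size=12), index=[f"s{i}" for i in range(12)]
        )
        alleles = rng.integers(0, 2, size=12)
        m = pd.DataFrame([alleles], index=["v"], columns=years.index, dtype=float)
        f = pd.DataFrame([1 - alleles], index=["v"], columns=years.index, dtype=float)
        s1 = rate_of_change(_records(m), years).loc["v", "slope"]
        s2 = rate_of_change(_records(f), years).loc["v", "slope"]
        if not (np.isnan(s1) or np.isnan(s2)):
            assert s1 == pytest.approx(-s2)


class TestLSD:
    def test_null_single_letter_group(self, rng):
        single = 0
        for _ in range(20):
            r = pd.DataFrame(
                {
                    "class_": np.repeat(["a", "b", "c", "d"], 30),
                    "slope": rng.normal(0, 1, 120),
                },
                index=[f"v{i}" for i in range(120)],
            )
            if lsd_grouping(r)["letters"].nunique() == 1:
                single += 1
        assert single >= 18

    def test_separated_classes_get_distinct_letters(self, rng):
        r = pd.DataFrame(
            {
                "class_": np.repeat(["a", "b"], 30),
                "slope": np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]),
            },
            index=[f"v{i}" for i in range(60)],
        )
        g = lsd_grouping(r)
        assert not set(g.loc["a", "letters"]) & set(g.loc["b", "letters"])

    def test_pairwise_p_equals_pooled_t_oracle(self, rng):
        r = pd.DataFrame(
            {
                "class_": np.repeat(["a", "b", "c"], 15),
                "slope": rng.normal(0, 1, 45),
            },
            index=[f"v{i}" for i in range(45)],
        )
        g = lsd_grouping(r)
        pair = g.attrs["pairwise"].set_index(["class_a", "class_b"])
        groups = {c: sub["slope"].to_numpy() for c, sub in r.groupby("class_")}
        mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (45 - 3)
        for (a, b), row in pair.iterrows():
            se = np.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])))
            t = (groups[a].mean() - groups[b].mean()) / se
            p = 2 * stats.t.sf(abs(t), 42)
            assert row["p_raw"] == pytest.approx(p)


class TestBurden:
    def _meta(self, n=40):
        return pd.DataFrame(
            {
                "variety_id": [f"v{i}" for i in range(n)],
                "release_year": np.linspace(1905, 2013, n).round().astype(int),
                "grain_type": ["long", "medium"] * (n // 2),
            }
        )

    def test_constant_burden_zero_r2(self):
        meta = self._meta()
        m = pd.DataFrame(
            np.ones((10, 40)), index=[f"l{i}" for i in range(10)],
            columns=meta.variety_id,
        )
        br = burden_regression(_records(m), meta)
        assert (br["r_squared"] == 0).all()

    def test_exact_linear_burden_r2_one(self):
        meta = self._meta()
        years = meta.set_index("variety_id")["release_year"]
        m = pd.DataFrame(
            0, index=[f"l{i}" for i in range(40)], columns=meta.variety_id, dtype=float
        )
        for v in meta.variety_id:
            k = int(round(30 - 0.2 * (years[v] - 1905)))
            m.loc[m.index[:k], v] = 1
        br = burden_regression(_records(m), meta)
        assert (br["r_squared"] > 0.99).all()

    def test_simulated_decline_recovered_within_2_se(self, rng):
        meta = self._meta(60)
        years = meta.set_index("variety_id")["release_year"]
        true_slope = -0.1
        m = pd.DataFrame(
            0, index=[f"l{i}" for i in range(60)], columns=meta.variety_id, dtype=float
        )
        for v in meta.variety_id:
            lam = max(0.5, 25 + true_slope * (years[v] - 1905))
            k = min(60, rng.poisson(lam))
            m.loc[m.index[:k], v] = 1
        br = burden_regression(_records(m), meta)
        fit_slope = br.loc["combined", "slope"]
        # standard error of an OLS slope with Poisson noise around the line
        x = years.to_numpy(float)
        se = np.sqrt(25 / ((x - x.mean()) ** 2).sum())
        assert abs(fit_slope - true_slope) < 2 * se


class TestBlockScores:
    def test_zero_variance_blocks_excluded(self):
        meta = pd.DataFrame(
            {
                "variety_id": ["a", "b", "c", "d"],
                "release_year": [1910, 1950, 1990, 2010],
                "grain_type": ["long"] * 4,
            }
        )
        m = pd.DataFrame(
            {"a": [1, 1], "b": [1, 0], "c": [1, 1], "d": [1, 0]},
            index=["l0", "l1"], dtype=float,
        )
        per_block, _ = block_score_regression([["l0"], ["l1"]], _records(m), meta)
        assert per_block["block"].tolist() == [1]

    def test_high_variance_deleterious_blocks_more_negative(self, rng):
        n = 60
        meta = pd.DataFrame(
            {
                "variety_id": [f"v{i}" for i in range(n)],
                "release_year": np.linspace(1905, 2013, n).round().astype(int),
                "grain_type": ["long"] * n,
            }
        )
        years = meta.set_index("variety_id")["release_year"]
        blocks, frames = [], []
        # high-variance blocks decline with year; low-variance blocks are flat
        for b in range(12):
            high = b < 6
            loci = [f"b{b}l{j}" for j in range(3 if high else 1)]
            blocks.append(loci)
            for l in loci:
                if high:
                    p = np.clip(0.8 - 0.006 * (years - 1905), 0.05, 0.95)
                    frames.append(pd.Series(rng.random(n) < p, index=years.index, name=l))
                else:
                    frames.append(
                        pd.Series(rng.random(n) < 0.2, index=years.index, name=l)
                    )
        m = pd.DataFrame(frames).astype(float)
        per_block, _ = block_score_regression(blocks, _records(m), meta)
        hv = per_block[per_block["score_variance"] > per_block["score_variance"].median()]
        lv = per_block[per_block["score_variance"] <= per_block["score_variance"].median()]
        assert hv["coefficient"].mean() < lv["coefficient"].mean()

    def test_neutral_summary_ci_covers_zero(self, rng):
        n = 80
        meta = pd.DataFrame(
            {
                "variety_id": [f"v{i}" for i in range(n)],
                "release_year": np.linspace(1905, 2013, n).round().astype(int),
                "grain_type": ["long"] * n,
            }
        )
        blocks, frames = [], []
        for b in range(20):
            loci = [f"b{b}l{j}" for j in range(2)]
            blocks.append(loci)
            for l in loci:
                frames.append(
                    pd.Series(
                        rng.random(n) < rng.uniform(0.2, 0.6), index=meta.variety_id,
                        name=l,
                    )
                )
        m = pd.DataFrame(frames).astype(float)
        rec = m.copy()
        rec.insert(0, "class_", "intronic_SV")
        _, summary = block_score_regression(blocks, rec, meta, class_="intronic_SV")
        assert summary["ci_low"] <= 0 <= summary["ci_high"]


class TestTrios:
    def _trio(self, p1, p2, child, i=0):
        return Trio(
            progeny_id=f"t{i}", parent1_id="a", parent2_id="b",
            parent1=np.asarray(p1, dtype=np.int8),
            parent2=np.asarray(p2, dtype=np.int8),
            progeny=np.asarray(child, dtype=np.int8),
        )

    def test_neutral_bias_near_half(self, rng):
        n_loci, n_trios = 30, 40
        classes = pd.Series("exonic_SV", index=[f"l{j}" for j in range(n_loci)])
        trios = []
        for i in range(n_trios):
            p1 = rng.integers(0, 2, n_loci)
            p2 = rng.integers(0, 2, n_loci)
            pick = rng.random(n_loci) < 0.5
            trios.append(self._trio(p1, p2, np.where(pick, p1, p2), i))
        out = trio_analysis(trios, classes, min_segregating=10)
        assert len(out) > 0
        se = np.sqrt(0.25 / out["n_segregating"]).mean() / np.sqrt(len(out))
        assert abs(out["bias"].mean() - 0.5) < 4 * se

    def test_derived_inheritance_counted(self):
        classes = pd.Series("exonic_SV", index=["l0"])
        trios = [
            self._trio([1], [0], [1], i) for i in range(8)
        ] + [self._trio([1], [0], [0], i + 8) for i in range(4)]
        out = trio_analysis(trios, classes, min_segregating=10)
        assert out.loc["l0", "derived_inherited"] == 8
        assert out.loc["l0", "bias"] == pytest.approx(8 / 12)

    def test_single_allele_always_inherited_removed(self):
        classes = pd.Series("exonic_SV", index=["l0"])
        trios = [self._trio([1], [0], [0], i) for i in range(12)]
        assert len(trio_analysis(trios, classes, min_segregating=10)) == 0

    def test_under_segregated_variant_removed(self):
        classes = pd.Series("exonic_SV", index=["l0"])
        trios = [self._trio([1], [0], [1], 0), self._trio([1], [0], [0], 1)]
        assert len(trio_analysis(trios, classes, min_segregating=10)) == 0

    def test_high_miscall_trio_dropped(self):
        classes = pd.Series("exonic_SV", index=[f"l{j}" for j in range(20)])
        # parents agree at 10 loci; progeny contradicts both at 5 of them
        p = np.zeros(20, dtype=np.int8)
        q = np.concatenate([np.ones(10), np.zeros(10)]).astype(np.int8)
        child = np.concatenate([np.ones(10), np.ones(5), np.zeros(5)]).astype(np.int8)
        bad = self._trio(p, q, child)
        good = [self._trio(q, p, q, i + 1) for i in range(12)]
        out = trio_analysis([bad] + good, classes, min_segregating=10)
        # the bad trio (miscall ratio 5/10 > 0.35) must not contribute
        assert (out["n_segregating"] <= 12).all()
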