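"""Panel preparation, LD pruning, block building, era frequencies, the
sweep threshold, H-scan tracts and Centered-IBS kinship."""

import numpy as np
import pandas as pd
import pytest

from _oracles import tract_length_oracle
from svlegacy import haploscan as H


def _panel(data, positions):
    m = pd.DataFrame(
        data, index=[f"v{i}" for i in range(len(data))],
        columns=[f"s{j}" for j in range(len(positions))], dtype=float,
    )
    return m, pd.Series(positions, index=m.columns, dtype=float)


class TestPreparePanel:
    def test_heterozygous_site_dropped(self):
        m, pos = _panel([[0.5, 0], [0.5, 1], [0.5, 0], [0, 1], [1, 0], [0, 1],
                         [1, 0], [0, 1], [1, 0], [0, 1]], [100, 5000])
        out, _ = H.prepare_panel(m, pos, het_max=0.10)
        assert list(out.columns) == ["s1"]

    def test_missingness_threshold(self):
        rows = [[np.nan, 0]] * 20 + [[0, 1]] * 10
        m, pos = _panel(rows, [100, 5000])
        out, _ = H.prepare_panel(m, pos, max_missing=20)
        assert list(out.columns) == ["s1"]

    def test_thinning_keeps_first_of_each_window(self):
        m, pos = _panel([[0, 1, 0, 1]] * 4, [0, 1_000, 2_000, 3_000])
        out, _ = H.prepare_panel(m, pos, min_dist=3_000)
        assert list(out.columns) == ["s0", "s3"]

    def test_spaced_sites_untouched(self):
        m, pos = _panel([[0, 1, 0]] * 4, [0, 3_000, 6_000])
        out, _ = H.prepare_panel(m, pos)
        assert list(out.columns) == ["s0", "s1", "s2"]

    def test_residual_hets_become_missing(self):
        rows = [[0.5, 1]] + [[0, 1]] * 19
        m, pos = _panel(rows, [0, 5_000])
        out, _ = H.prepare_panel(m, pos, het_max=0.10)
        assert np.isnan(out.iloc[0, 0])


class TestLDPrune:
    def test_duplicated_site_pair_keeps_one(self, rng):
        col = rng.integers(0, 2, 30).astype(float)
        m = pd.DataFrame({"s0": col, "s1": col, "s2": rng.integers(0, 2, 30)})
        kept = H.ld_prune(m)
        assert kept[0] == "s0" and "s1" not in kept

    def test_independent_sites_mostly_retained(self, rng):
        m = pd.DataFrame(
            rng.integers(0, 2, size=(200, 30)).astype(float),
            columns=[f"s{j}" for j in range(30)],
        )
        kept = H.ld_prune(m)
        assert len(kept) >= 28

    def test_r2_matches_brute_force_on_hand_matrix(self):
        a = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        b = np.array([0, 1, 1, 1, 0, 0], dtype=float)
        r = np.corrcoef(a, b)[0, 1] ** 2
        assert H._r2(a, b) == pytest.approx(r)

    def test_output_within_window_r2_bounded(self, rng):
        base = rng.integers(0, 2, size=(100, 1)).astype(float)
        noisy = np.repeat(base, 12, axis=1)
        flips = rng.random(noisy.shape) < 0.2
        noisy = np.where(flips, 1 - noisy, noisy)
        m = pd.DataFrame(noisy, columns=[f"s{j}" for j in range(12)])
        kept = H.ld_prune(m, r2_max=0.1)
        vals = m[kept].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert H._r2(vals[:, i], vals[:, j]) <= 0.1


class TestBlocks:
    def test_two_linked_clusters_give_two_blocks(self, rng):
        left = rng.integers(0, 2, size=(60, 1)).astype(float)
        right = rng.integers(0, 2, size=(60, 1)).astype(float)
        data = np.hstack([np.repeat(left, 3, axis=1), np.repeat(right, 3, axis=1)])
        m = pd.DataFrame(data, columns=[f"s{j}" for j in range(6)])
        pos = pd.Series([0, 1e3, 2e3, 10e3, 11e3, 12e3], index=m.columns)
        blocks = H.define_blocks(m, pos)
        assert len(blocks) == 2
        assert [b.sites for b in blocks] == [["s0", "s1", "s2"], ["s3", "s4", "s5"]]

    def test_single_site_is_singleton_block(self, rng):
        m = pd.DataFrame({"s0": rng.integers(0, 2, 20).astype(float)})
        blocks = H.define_blocks(m, pd.Series([500.0], index=["s0"]))
        assert len(blocks) == 1 and blocks[0].sites == ["s0"]

    def test_span_never_exceeds_cap(self, rng):
        col = rng.integers(0, 2, size=(40, 1)).astype(float)
        data = np.repeat(col, 12, axis=1)
        m = pd.DataFrame(data, columns=[f"s{j}" for j in range(12)])
        pos = pd.Series(np.arange(12) * 100_000.0, index=m.columns)
        blocks = H.define_blocks(m, pos, max_span=800_000)
        assert all(b.span_bp <= 800_001 for b in blocks)
        assert len(blocks) >= 2

    def test_partition_covers_every_site_once(self, rng):
        m = pd.DataFrame(
            rng.integers(0, 2, size=(30, 15)).astype(float),
            columns=[f"s{j}" for j in range(15)],
        )
        pos = pd.Series(np.sort(rng.choice(50_000, 15, replace=False)).astype(float),
                        index=m.columns)
        blocks = H.define_blocks(m, pos)
        covered = [s for b in blocks for s in b.sites]
        assert sorted(covered) == sorted(m.columns)
        assert len(covered) == len(set(covered))


class TestEraFrequencies:
    def _years(self):
        ids = [f"v{i}" for i in range(30)]
        return pd.Series([1930] * 10 + [1975] * 10 + [2000] * 10, index=ids)

    def test_single_haplotype_everywhere(self):
        years = self._years()
        m = pd.DataFrame({"s0": np.zeros(30)}, index=years.index)
        eras = H.era_partition(years)
        blocks = H.define_blocks(m, pd.Series([100.0], index=["s0"]))
        tab = H.era_frequencies(blocks[0], m, eras)
        assert (tab.loc["0"] == 1.0).all()

    def test_columns_sum_to_one(self, rng):
        years = self._years()
        m = pd.DataFrame(
            rng.integers(0, 2, size=(30, 3)).astype(float), index=years.index,
            columns=["s0", "s1", "s2"],
        )
        eras = H.era_partition(years)
        blocks = H.define_blocks(m, pd.Series([0.0, 500.0, 900.0], index=m.columns),
                                 min_adjacent_r2=0.0)
        tab = H.era_frequencies(blocks[0], m, eras)
        assert np.allclose(tab.sum(axis=0), 1.0)

    def test_hand_counted_table(self):
        years = pd.Series([1930] * 5 + [2000] * 5, index=[f"v{i}" for i in range(10)])
        m = pd.DataFrame(
            {"s0": [0, 0, 0, 1, 1, 1, 1, 1, 1, 0]}, index=years.index, dtype=float
        )
        eras = H.era_partition(years)
        blocks = H.define_blocks(m, pd.Series([100.0], index=["s0"]))
        tab = H.era_frequencies(blocks[0], m, eras)
        assert tab.loc["0", "early"] == pytest.approx(0.6)
        assert tab.loc["1", "late"] == pytest.approx(0.8)


class TestSweepScan:
    def test_threshold_is_inclusive_at_023(self):
        years = pd.Series(
            [1930] * 10 + [1975] * 10 + [2000] * 12,
            index=[f"v{i}" for i in range(32)],
        )
        # haplotype "1" goes 0.10 -> 0.10 -> 0.33...: gain about 0.233
        col = np.array([0] * 9 + [1] + [0] * 9 + [1] + [0] * 8 + [1] * 4, dtype=float)
        m = pd.DataFrame({"s0": col}, index=years.index)
        eras = H.era_partition(years)
        blocks = H.define_blocks(m, pd.Series([100.0], index=["s0"]))
        flags = H.sweep_scan(blocks, m, eras, delta=0.23)
        assert bool(flags["flagged"].iloc[0])

    def test_stable_frequencies_not_flagged(self):
        years = pd.Series(
            [1930] * 10 + [1975] * 10 + [2000] * 10,
            index=[f"v{i}" for i in range(30)],
        )
        col = np.array(([0] * 5 + [1] * 5) * 3, dtype=float)
        m = pd.DataFrame({"s0": col}, index=years.index)
        eras = H.era_partition(years)
        blocks = H.define_blocks(m, pd.Series([100.0], index=["s0"]))
        flags = H.sweep_scan(blocks, m, eras, delta=0.23)
        assert not flags["flagged"].any()

    def test_planted_sweep_block_flagged(self):
        from svlegacy.experiments import sweep_config
        from svlegacy.synthdata.cohort import build_loci_table, simulate_cohort

        hits = 0
        reps = 10
        for rep in range(reps):
            cfg = sweep_config(rep)
            rng = np.random.default_rng(500 + rep)
            c = simulate_cohort(build_loci_table(None, cfg, rng), cfg, rng)
            snp_ids = c.loci.locus_id[c.loci.kind == "SNP"]
            panel = c.genotypes[snp_ids].astype(float)
            pos = c.loci.set_index("locus_id")["position"].reindex(snp_ids)
            panel, pos = H.prepare_panel(panel, pos, min_dist=1_000)
            eras = H.era_partition(c.years)
            blocks = H.define_blocks(panel, pos)
            flags = H.sweep_scan(blocks, panel, eras)
            sweep_pos = c.loci.loc[c.loci.kind == "sweep", "position"].iloc[0]
            d = [
                0 if b.span[0] <= sweep_pos < b.span[1]
                else min(abs(b.span[0] - sweep_pos), abs(b.span[1] - sweep_pos))
                for b in blocks
            ]
            if flags.loc[int(np.argmin(d)), "flagged"]:
                hits += 1
        assert hits >= 0.8 * reps


class TestHScan:
    def test_identical_varieties_span_chromosome(self):
        m = pd.DataFrame(np.zeros((4, 5)), columns=[f"s{j}" for j in range(5)])
        pos = pd.Series([0.0, 10, 20, 30, 40], index=m.columns)
        h = H.hscan_index(m, pos)
        assert (h == 41).all()

    def test_all_different_gives_minimum(self):
        m = pd.DataFrame([[0, 0, 0], [1, 1, 1]], columns=["s0", "s1", "s2"])
        pos = pd.Series([0.0, 100, 200], index=m.columns)
        assert H.hscan_index(m.astype(float), pos).isna().all()
        m2 = pd.DataFrame([[0, 0, 0], [1, 0, 1]], columns=m.columns).astype(float)
        h = H.hscan_index(m2, pos)
        assert h["s1"] == 1.0

    def test_matches_brute_force_enumeration(self, rng):
        n_var, n_sites = 5, 12
        data = rng.integers(0, 2, size=(n_var, n_sites)).astype(float)
        data[rng.random(data.shape) < 0.1] = np.nan
        m = pd.DataFrame(data, columns=[f"s{j}" for j in range(n_sites)])
        pos = np.sort(rng.choice(10_000, n_sites, replace=False)).astype(float)
        h = H.hscan_index(m, pd.Series(pos, index=m.columns))
        listed = [
            [None if np.isnan(x) else int(x) for x in row] for row in data
        ]
        for focal in range(n_sites):
            expected = tract_length_oracle(listed, list(pos), focal)
            got = h.iloc[focal]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


class TestKinship:
    def test_matches_brute_force_formula(self, rng):
        g = rng.integers(0, 2, size=(4, 6)).astype(float)
        m = pd.DataFrame(g, index=list("abcd"), columns=[f"s{j}" for j in range(6)])
        k = H.centered_ibs_kinship(m)
        p = g.mean(axis=0)
        w = g - p
        expected = w @ w.T / (p * (1 - p)).sum()
        assert np.allclose(k.to_numpy(), expected)

    def test_symmetric_and_identical_pair_maximal(self, rng):
        g = rng.integers(0, 2, size=(5, 30)).astype(float)
        g[1] = g[0]
        m = pd.DataFrame(g, index=list("abcde"), columns=[f"s{j}" for j in range(30)])
        k = H.centered_ibs_kinship(m)
        assert np.allclose(k, k.T)
        assert k.loc["a", "b"] == pytest.approx(k.loc["a", "a"])

    def test_monomorphic_panel_rejected(self):
        m = pd.DataFrame(np.zeros((3, 4)), columns=[f"s{j}" for j in range(4)])
        with pytest.raises(ValueError):
            H.centered_ibs_kinship(m)
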