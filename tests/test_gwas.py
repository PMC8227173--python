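"""Backsolving, window variances, region selection and pleiotropy."""

import numpy as np
import pandas as pd
import pytest

from ssgwas.gwas import (backsolve_snp_effects, per_snp_variance,
                         pleiotropy_table, select_regions, window_variances)


def snp_map(bps, chroms=None):
    return pd.DataFrame({
        "chrom": chroms if chroms is not None else ["1"] * len(bps),
        "snp_id": [f"s{i}" for i in range(len(bps))],
        "cm": 0,
        "bp": bps,
    })


def windows_from(pcts, chrom="1", start=0):
    return pd.DataFrame({
        "chrom": chrom, "window": np.arange(start, start + len(pcts)),
        "window_start_bp": np.arange(start, start + len(pcts)) * 10**6 + 1,
        "window_end_bp": (np.arange(start, start + len(pcts)) + 1) * 10**6,
        "n_snps": 1, "pct_var": pcts,
    })


class TestBacksolve:
    def test_zero_gebv_zero_effects(self, rng):
        Z = rng.normal(size=(5, 8))
        p = np.full(8, 0.3)
        G = Z @ Z.T / np.sum(2 * p * (1 - p))
        eff = backsolve_snp_effects(np.zeros(5), Z, G, p)
        np.testing.assert_allclose(eff.g_hat, 0.0)

    def test_projection_reconstructs_gebv(self, rng):
        """With the raw marker G, Z g-hat scaled back reproduces u-hat:
        the GBLUP <-> SNP-BLUP equivalence."""
        n, N = 6, 20
        Z = rng.normal(size=(n, N))
        p = rng.uniform(0.1, 0.5, size=N)
        denom = np.sum(2 * p * (1 - p))
        G = Z @ Z.T / denom
        u = rng.normal(size=n)
        eff = backsolve_snp_effects(u, Z, G, p)
        np.testing.assert_allclose(Z @ eff.g_hat, u, atol=1e-8)

    def test_hand_dense_oracle(self, rng):
        n, N = 5, 3
        Z = rng.normal(size=(n, N))
        p = np.array([0.2, 0.4, 0.5])
        denom = float(np.sum(2 * p * (1 - p)))
        G = Z @ Z.T / denom + 0.01 * np.eye(n)  # ensure invertible
        u = rng.normal(size=n)
        expected = Z.T @ np.linalg.inv(G) @ u / denom
        eff = backsolve_snp_effects(u, Z, G, p)
        np.testing.assert_allclose(eff.g_hat, expected, atol=1e-10)

    def test_order_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            backsolve_snp_effects(np.zeros(3), rng.normal(size=(4, 2)),
                                  np.eye(4), np.array([0.5, 0.5]))


class TestPerSnpVariance:
    def test_hand_values_and_elementwise_oracle(self, rng):
        assert per_snp_variance(np.array([1.0]), np.array([0.5]))[0] == 0.5
        assert per_snp_variance(np.array([0.0]), np.array([0.3]))[0] == 0.0
        g = rng.normal(size=30)
        p = rng.uniform(0.01, 0.99, size=30)
        np.testing.assert_allclose(per_snp_variance(g, p),
                                   [2 * pi * (1 - pi) * gi ** 2
                                    for gi, pi in zip(g, p)])


class TestWindowVariances:
    def test_single_window_is_hundred(self):
        t = window_variances(np.array([1.0, 2.0, 3.0]),
                             snp_map([100, 5000, 999_999]))
        assert len(t) == 1
        assert t.pct_var.iloc[0] == pytest.approx(100.0)
        assert t.window_start_bp.iloc[0] == 1
        assert t.window_end_bp.iloc[0] == 1_000_000

    def test_equal_windows_fifty_fifty(self):
        t = window_variances(np.array([2.0, 1.0, 1.0]),
                             snp_map([10, 1_000_010, 1_500_000]))
        np.testing.assert_allclose(sorted(t.pct_var), [50.0, 50.0])

    def test_window_indexing_boundary(self):
        # bp = 1_000_000 belongs to window 0; 1_000_001 to window 1
        t = window_variances(np.array([1.0, 1.0]),
                             snp_map([1_000_000, 1_000_001]))
        assert t.window.tolist() == [0, 1]

    def test_percentages_sum_to_hundred(self, rng):
        n = 500
        bps = np.sort(rng.integers(1, 50_000_000, size=n))
        chroms = np.sort(rng.choice(["1", "2", "3"], size=n))
        t = window_variances(rng.random(n), snp_map(bps, chroms))
        assert t.pct_var.sum() == pytest.approx(100.0, abs=1e-6)

    def test_unsorted_map_warns_and_sorts(self, rng):
        with pytest.warns(UserWarning, match="sorted"):
            t = window_variances(np.array([1.0, 1.0]), snp_map([2_000_001, 10]))
        assert t.window.tolist() == [0, 2]

    def test_chromosome_relabeling_invariance(self, rng):
        n = 200
        bps = np.sort(rng.integers(1, 20_000_000, size=n))
        chroms = np.sort(rng.choice(["1", "2"], size=n))
        v = rng.random(n)
        t1 = window_variances(v, snp_map(bps, chroms))
        relabel = {"1": "9", "2": "7"}
        t2 = window_variances(v, snp_map(bps, [relabel[c] for c in chroms]))
        m1 = {(relabel[r.chrom], r.window): r.pct_var for r in t1.itertuples()}
        m2 = {(r.chrom, r.window): r.pct_var for r in t2.itertuples()}
        assert m1.keys() == m2.keys()
        for k in m1:
            assert m1[k] == pytest.approx(m2[k])


class TestRegions:
    def test_consecutive_windows_merge(self):
        w = windows_from([1.0, 2.0], start=1)
        r = select_regions(w, threshold_pct=0.5)
        assert len(r) == 1
        assert r.start_bp.iloc[0] == 1_000_001 and r.end_bp.iloc[0] == 3_000_000

    def test_gap_splits_regions(self):
        w = pd.concat([windows_from([1.0], start=1), windows_from([1.0], start=5)])
        assert len(select_regions(w, 0.5)) == 2

    def test_threshold_is_inclusive_on_raw_value(self):
        w = windows_from([0.5, 0.4999])
        r = select_regions(w, 0.5)
        assert len(r) == 1 and r.start_window.iloc[0] == 0

    def test_coarsening_never_increases_regions(self, rng):
        """Doubling the window size cannot yield more merged regions than
        the finer partition produced."""
        n = 400
        bps = np.sort(rng.integers(1, 40_000_000, size=n))
        v = rng.random(n) ** 4  # heavy tail: some windows dominate
        fine = select_regions(window_variances(v, snp_map(bps)), 0.8)
        coarse = select_regions(
            window_variances(v, snp_map(bps), window_size_bp=2_000_000), 0.8)
        assert len(coarse) <= max(len(fine), 1)


class TestPleiotropy:
    def test_shared_and_private_planted_regions(self):
        """Two traits with one shared significant window and one private
        window each: exactly one pleiotropic region."""
        t1 = pd.concat([windows_from([2.0], "1", start=5),   # shared
                        windows_from([1.0], "2", start=3),   # private to t1
                        windows_from([0.1], "3", start=8)])
        t2 = pd.concat([windows_from([1.5], "1", start=5),   # shared
                        windows_from([0.1], "2", start=3),
                        windows_from([0.9], "3", start=8)])  # private to t2
        tab = pleiotropy_table({"bw": t1, "ww": t2}, threshold_pct=0.5)
        assert len(tab) == 3
        shared = tab[tab.pleiotropic]
        assert len(shared) == 1 and shared.chrom.iloc[0] == "1"
        assert shared.n_traits.iloc[0] == 2

    def test_single_trait_region_marked_once(self):
        t1 = windows_from([1.0], "4", start=2)
        t2 = windows_from([0.2], "4", start=2)
        tab = pleiotropy_table({"a": t1, "b": t2})
        assert tab[["a", "b"]].values.tolist() == [["X", "-"]]

    def test_union_region_spans_per_trait_merges(self):
        # trait a significant in windows 1-2, trait b in windows 2-3:
        # one union region 1-3 marked for both
        a = windows_from([1.0, 1.0], "1", start=1)
        b = windows_from([1.0, 1.0], "1", start=2)
        tab = pleiotropy_table({"a": a, "b": b})
        assert len(tab) == 1
        assert tab.start_Mb.iloc[0] == 1 and tab.end_Mb.iloc[0] == 4
        assert tab.pleiotropic.iloc[0]

    def test_empty_input(self):
        tab = pleiotropy_table({"a": windows_from([0.1]), "b": windows_from([0.2])})
        assert len(tab) == 0
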