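import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bsaqtl import bsa_statistics as bs
from bsaqtl._loess import loess_fit

from conftest import make_null_snp_table


def brute_force_tricube(values, positions, window_bp):
    """O(n^2) reference for the windowed tricube weighted mean."""
    values = np.asarray(values, float)
    positions = np.asarray(positions, float)
    out = np.empty(len(values))
    half = window_bp / 2.0
    for i in range(len(values)):
        num = den = 0.0
        for j in range(len(values)):
            d = abs(positions[j] - positions[i])
            if d <= half:
                w = (1 - (2 * d / window_bp) ** 3) ** 3
                num += w * values[j]
                den += w
        out[i] = num / den
    return out


class TestIndices:
    def test_snp_index_symmetry(self):
        assert bs.snp_index(10, 10) == pytest.approx(0.5)

    def test_snp_index_zero(self):
        assert bs.snp_index(0, 25) == pytest.approx(0.0)

    def test_snp_index_ratio(self):
        assert bs.snp_index(7, 3) == pytest.approx(0.7)

    def test_snp_index_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            bs.snp_index(0, 0)

    def test_delta(self):
        assert bs.delta_snp_index(0.5, 0.0) == pytest.approx(0.5)
        assert bs.delta_snp_index(0.3, 0.3) == pytest.approx(0.0)
        assert bs.delta_snp_index(0.0, 0.5) == pytest.approx(-0.5)

    def test_euclidean_closed_form(self):
        assert bs.euclidean_distance(1.0, 0.0) == pytest.approx(np.sqrt(2))
        assert bs.ed_power(bs.euclidean_distance(1.0, 0.0), 5) == pytest.approx(
            4 * np.sqrt(2)
        )
        assert bs.euclidean_distance(0.4, 0.4) == pytest.approx(0.0)
        assert bs.euclidean_distance(0.5, 0.0) == pytest.approx(0.5 * np.sqrt(2))

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_ed_is_sqrt2_delta_property(self, f, s):
        ed = bs.euclidean_distance(f, s)
        assert ed == pytest.approx(np.sqrt(2) * abs(f - s), abs=1e-12)


class TestGStatistic:
    def test_balanced_table_is_zero(self):
        assert bs.g_statistic(10, 10, 10, 10) == pytest.approx(0.0)

    def test_perfect_separation_closed_form(self):
        # all four expected cells equal 10; G = 2*(20 ln2 + 20 ln2) = 80 ln2
        assert bs.g_statistic(20, 0, 0, 20) == pytest.approx(80 * np.log(2))

    def test_hand_computed_table(self):
        # frozen from the cell-expectation formula:
        # 2*(12 ln(12/9) + 8 ln(8/11) + 6 ln(6/9) + 14 ln(14/11))
        assert bs.g_statistic(12, 8, 6, 14) == pytest.approx(3.6960663345, abs=1e-6)

    def test_matches_scipy_log_likelihood_ratio(self):
        # dual route: scipy's G-test on the same 2x2 table
        rng = np.random.default_rng(5)
        for _ in range(20):
            cells = rng.integers(1, 60, size=4)
            g, _, _, _ = sps.chi2_contingency(
                cells.reshape(2, 2), correction=False, lambda_="log-likelihood"
            )
            assert bs.g_statistic(*cells) == pytest.approx(g, abs=1e-10)

    def test_zero_row_or_column_is_zero(self):
        assert bs.g_statistic(0, 0, 5, 7) == 0.0
        assert bs.g_statistic(0, 5, 0, 7) == 0.0

    def test_bulk_swap_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, r, c, d = rng.integers(0, 50, size=4)
            assert bs.g_statistic(a, r, c, d) == pytest.approx(
                bs.g_statistic(c, d, a, r), abs=1e-10
            )


class TestTricubeSmooth:
    def test_single_snp_is_identity(self):
        np.testing.assert_allclose(bs.tricube_smooth([3.7], [100], 1e6), [3.7])

    def test_constant_track(self):
        pos = np.sort(np.random.default_rng(0).integers(1, 10**6, 200))
        out = bs.tricube_smooth(np.full(200, 2.5), pos, 1e6)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_brute_force_oracle_1000_snps(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(10**7, size=1000, replace=False))
        vals = rng.normal(size=1000)
        fast = bs.tricube_smooth(vals, pos, 1e6)
        slow = brute_force_tricube(vals, pos, 1e6)
        np.testing.assert_allclose(fast, slow, atol=1e-12, rtol=0)

    def test_gprime_equals_smoothed_g(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(10**7, size=500, replace=False))
        g = rng.gamma(2.0, size=500)
        np.testing.assert_allclose(
            bs.gprime(g, pos, 1e6), brute_force_tricube(g, pos, 1e6), atol=1e-12
        )

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            bs.tricube_smooth([1.0, 2.0], [200, 100], 1e6)

    def test_empty(self):
        assert len(bs.tricube_smooth([], [], 1e6)) == 0

    def test_nan_values_excluded(self):
        out = bs.tricube_smooth([1.0, np.nan, 1.0], [100, 200, 300], 1e6)
        np.testing.assert_allclose(out, 1.0)


class TestGprimePQ:
    def test_lognormal_null_recovery(self):
        # Monte-Carlo oracle: a pure log-normal track should be refit with
        # the stated trimmed estimators and yield ~no BH rejections
        rng = np.random.default_rng(3)
        gp = rng.lognormal(mean=1.0, sigma=0.5, size=10_000)
        p, q, mask = bs.gprime_pq(gp, fdr_q=0.01)
        ln_g = np.log(gp)
        med = np.median(ln_g)
        mad = np.median(np.abs(ln_g - med))
        retained = ln_g[ln_g <= med + 5.2 * mad]
        assert np.median(retained) == pytest.approx(1.0, abs=0.05)
        assert 1.4826 * np.median(np.abs(retained - np.median(retained))) == pytest.approx(
            0.5, abs=0.05
        )
        assert mask.mean() <= 0.02

    def test_constant_track_no_rejections(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p, q, mask = bs.gprime_pq(np.full(100, 3.0), fdr_q=0.01)
        assert not mask.any()
        np.testing.assert_allclose(p, 1.0)

    def test_bh_hand_computation(self):
        # p=(0.001, 0.02, 0.9) at q=0.05: BH thresholds 0.0167/0.0333/0.05,
        # step-up rejects the first two
        from statsmodels.stats.multitest import multipletests

        reject, qvals = multipletests([0.001, 0.02, 0.9], alpha=0.05,
                                      method="fdr_bh")[:2]
        assert list(reject) == [True, True, False]
        # q-values monotone nondecreasing in p-rank
        assert qvals[0] <= qvals[1] <= qvals[2]

    def test_signal_is_detected(self):
        rng = np.random.default_rng(4)
        gp = rng.lognormal(mean=0.0, sigma=0.3, size=5000)
        gp[:50] = np.exp(4.0)  # strong outliers
        _, q, mask = bs.gprime_pq(gp, fdr_q=0.01)
        assert mask[:50].all()
        assert mask[50:].mean() <= 0.02


class TestDeltaCI:
    cfg = bs.ScanConfig(ci_reps=10_000, bulk_size=30, seed=0)

    def test_nested_and_symmetric(self):
        null = bs.DeltaCINull(self.cfg)
        for depth in (10, 40, 100):
            lo95, hi95, lo99, hi99 = null.bounds(depth)
            assert lo99 <= lo95 < 0 < hi95 <= hi99
            assert abs(lo95 + hi95) <= 0.05
            assert abs(lo99 + hi99) <= 0.08

    def test_narrower_at_higher_depth(self):
        null = bs.DeltaCINull(self.cfg)
        lo10, hi10, *_ = null.bounds(10)
        lo100, hi100, *_ = null.bounds(100)
        assert hi100 - lo100 < hi10 - lo10

    def test_memoized_and_deterministic(self):
        a = bs.DeltaCINull(self.cfg).bounds(25)
        b = bs.DeltaCINull(self.cfg).bounds(25)
        assert a == b

    def test_refuses_tiny_reps(self):
        with pytest.raises(ValueError, match="refusing"):
            bs.DeltaCINull(bs.ScanConfig(ci_reps=50))

    def test_f2_wider_pool_variance_than_bc1(self):
        # F2 pooled donor frequency has twice the BC1 variance at the pool
        # level; at high depth that dominates, so bands must be wider
        bc1 = bs.DeltaCINull(bs.ScanConfig(ci_reps=20_000, pop_structure="BC1"))
        f2 = bs.DeltaCINull(bs.ScanConfig(ci_reps=20_000, pop_structure="F2"))
        lo_b, hi_b, *_ = bc1.bounds(1000)
        lo_f, hi_f, *_ = f2.bounds(1000)
        assert hi_f - lo_f > hi_b - lo_b


class TestLoess:
    def test_quadratic_reproduced_exactly(self):
        x = np.linspace(0, 1, 120)
        y = 2.0 + 3.0 * x - 5.0 * x**2
        fitted = loess_fit(x, y, span=0.3, degree=2)
        np.testing.assert_allclose(fitted, y, atol=1e-6)

    def test_constant_input(self):
        x = np.arange(50, dtype=float)
        np.testing.assert_allclose(loess_fit(x, np.full(50, 7.0)), 7.0, atol=1e-9)

    def test_stays_within_range_for_smooth_input(self):
        x = np.linspace(0, 10, 300)
        y = np.sin(x)
        fitted = loess_fit(x, y, span=0.2, degree=2)
        assert fitted.min() >= y.min() - 1e-6 - 0.05
        assert fitted.max() <= y.max() + 1e-6 + 0.05


class TestEdLoessThreshold:
    def test_constant_track_threshold_equals_constant(self):
        pos = np.arange(1, 101, dtype=float) * 1000
        chroms = np.array(["chr01"] * 100)
        ed5 = np.full(100, 0.3)
        fitted, thr = bs.ed_loess_threshold(ed5, pos, chroms, bs.ScanConfig())
        np.testing.assert_allclose(fitted, 0.3, atol=1e-9)
        assert thr == pytest.approx(0.3, abs=1e-9)

    def test_fitted_bounded_by_input_range(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(10**7, 400, replace=False)).astype(float)
        ed5 = np.interp(pos, [0, 5e6, 1e7], [0.0, 1.0, 0.0])  # smooth tent
        fitted, _ = bs.ed_loess_threshold(
            ed5, pos, np.array(["chr01"] * 400), bs.ScanConfig()
        )
        assert fitted.min() >= ed5.min() - 1e-6 - 0.02
        assert fitted.max() <= ed5.max() + 1e-6 + 0.02

    def test_quadratic_oracle(self):
        pos = np.linspace(0, 1e6, 200)
        ed5 = 1e-12 * (pos - 5e5) ** 2 / 1e6
        fitted, _ = bs.ed_loess_threshold(
            ed5, pos, np.array(["chr01"] * 200), bs.ScanConfig()
        )
        np.testing.assert_allclose(fitted, ed5, atol=1e-6)

    def test_small_chromosome_falls_back_to_tricube(self, caplog):
        import logging

        pos = np.array([1e3, 2e3, 3e3])
        ed5 = np.array([0.1, 0.2, 0.3])
        with caplog.at_level(logging.WARNING, logger="bsaqtl.bsa_statistics"):
            fitted, _ = bs.ed_loess_threshold(
                ed5, pos, np.array(["chr01"] * 3), bs.ScanConfig()
            )
        assert "falling back" in caplog.text
        np.testing.assert_allclose(
            fitted, bs.tricube_smooth(ed5, pos, bs.ScanConfig().window_bp)
        )

    def test_per_chromosome_scope(self):
        pos = np.concatenate([np.arange(1, 51) * 1000.0] * 2)
        chroms = np.array(["chr01"] * 50 + ["chr02"] * 50)
        ed5 = np.concatenate([np.full(50, 0.1), np.full(50, 0.4)])
        cfg = bs.ScanConfig(ed_threshold_scope="chromosome")
        _, thr = bs.ed_loess_threshold(ed5, pos, chroms, cfg)
        assert thr["chr01"] == pytest.approx(0.1, abs=1e-9)
        assert thr["chr02"] == pytest.approx(0.4, abs=1e-9)


class TestComputeTrack:
    def test_track_internal_consistency(self):
        snps = make_null_snp_table(n_chrom=2, chrom_len=2_000_000,
                                   spacing=20_000, seed=10)
        cfg = bs.ScanConfig(ci_reps=500, seed=1)
        track, thresholds = bs.compute_track(snps, cfg)
        assert list(track.columns) == bs.TRACK_COLUMNS
        np.testing.assert_allclose(track["delta"], track["idxF"] - track["idxS"],
                                   atol=1e-12)
        np.testing.assert_allclose(track["ED"], np.sqrt(2) * track["delta"].abs(),
                                   atol=1e-12)
        np.testing.assert_allclose(track["ED5"], track["ED"] ** 5, atol=1e-12)
        assert (track["G"] >= 0).all()
        assert track["p"].between(0, 1).all()
        assert track["q"].between(0, 1).all()
        assert np.isfinite(thresholds["ed_threshold"])
        # q monotone nondecreasing in p-rank
        s = track.sort_values("p")
        assert np.all(np.diff(np.maximum.accumulate(s["q"].to_numpy())) >= -1e-12)

    def test_bulk_swap_symmetry(self):
        snps = make_null_snp_table(n_chrom=1, chrom_len=1_000_000,
                                   spacing=20_000, seed=11)
        cfg = bs.ScanConfig(ci_reps=500, seed=2)
        track, _ = bs.compute_track(snps, cfg)
        swapped = snps.rename(columns={"aF": "aS", "rF": "rS",
                                       "aS": "aF", "rS": "rF"})
        track_sw, _ = bs.compute_track(swapped, cfg)
        np.testing.assert_allclose(track_sw["G"], track["G"], atol=1e-10)
        np.testing.assert_allclose(track_sw["delta"], -track["delta"], atol=1e-12)
        np.testing.assert_allclose(track_sw["ED5"], track["ED5"], atol=1e-12)

    def test_write_read_round_trip(self, tmp_path):
        snps = make_null_snp_table(n_chrom=1, chrom_len=1_000_000,
                                   spacing=50_000, seed=12)
        track, thresholds = bs.compute_track(snps, bs.ScanConfig(ci_reps=500))
        bs.write_track(track, thresholds, tmp_path / "t.tsv", tmp_path / "th.json")
        track2, thresholds2 = bs.read_track(tmp_path / "t.tsv", tmp_path / "th.json")
        np.testing.assert_allclose(track["Gprime"], track2["Gprime"], rtol=1e-9)
        assert thresholds2["fdr_q"] == thresholds["fdr_q"]
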