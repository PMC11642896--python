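"""Causal/information coupling features: independent oracles, null
behaviour, direction specificity and determinism."""

import numpy as np
import pytest
from scipy import stats

from cardioresp.coupling import (
    assemble_coupling_features,
    gc_ratio,
    kernel_gc,
    linear_gc,
    lsngc,
    max_lagged_correlation,
    ml_gc,
    select_order,
    transfer_entropy,
)
from cardioresp.features import paired_signals_25hz


def _coupled_pair(rng, n=5000, beta=0.9, noise=0.1):
    x = rng.standard_normal(n + 1)
    y = np.empty(n + 1)
    y[0] = 0.0
    y[1:] = beta * x[:-1] + noise * rng.standard_normal(n)
    return x[1:], y[1:]


def _normal_equations_gc(source, target, p):
    """Independent brute-force oracle: explicit normal equations."""
    n = len(target) - p
    Xr = np.ones((n, p + 1))
    Xf = np.ones((n, 2 * p + 1))
    for k in range(1, p + 1):
        Xr[:, k] = target[p - k: len(target) - k]
        Xf[:, k] = target[p - k: len(target) - k]
        Xf[:, p + k] = source[p - k: len(source) - k]
    y = target[p:]
    br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
    bf = np.linalg.solve(Xf.T @ Xf, Xf.T @ y)
    vr = np.sum((y - Xr @ br) ** 2) / (n - Xr.shape[1])
    vf = np.sum((y - Xf @ bf) ** 2) / (n - Xf.shape[1])
    return np.log(vr / vf)


class TestOrderSelection:
    def test_recovers_known_order(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(2000)
            y = np.zeros(2000)
            for t in range(2, 2000):
                y[t] = 0.4 * y[t - 1] + 0.3 * y[t - 2] + 0.5 * x[t - 2] \
                    + 0.5 * rng.standard_normal()
            if select_order(x, y, p_max=6) == 2:
                hits += 1
        assert hits >= 18

    def test_forced_single_lag(self, rng):
        assert select_order(rng.standard_normal(500),
                            rng.standard_normal(500), p_max=1) == 1

    def test_white_noise_prefers_smallest_model(self, rng):
        assert select_order(rng.standard_normal(3000),
                            rng.standard_normal(3000), p_max=10) == 1


class TestLinearGC:
    def test_matches_normal_equations_oracle(self):
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            p = [1, 2, 3][i % 3]
            x, y = _coupled_pair(rng, n=500, beta=0.5, noise=0.7)
            ours = linear_gc(x, y, p).gc
            oracle = _normal_equations_gc(x, y, p)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_analytic_variance_ratio(self, rng):
        """y_t = 0.9 x_{t-1} + N(0, 0.01): GC = ln(0.82/0.01) = ln 82."""
        x, y = _coupled_pair(rng, n=5000, beta=0.9, noise=0.1)
        assert linear_gc(x, y, 1).gc == pytest.approx(np.log(82.0), abs=0.15)

    def test_reverse_direction_negligible(self, rng):
        x, y = _coupled_pair(rng, n=5000, beta=0.9, noise=0.1)
        assert linear_gc(y, x, 1).gc <= 0.01

    def test_constant_target_masked(self, rng):
        res = linear_gc(rng.standard_normal(500), np.full(500, 1.0), 2)
        assert res.masked and np.isnan(res.gc)

    def test_nesting_nonnegative_up_to_tolerance(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(800)
            y = rng.standard_normal(800)
            assert linear_gc(x, y, 3).gc >= -0.05


class TestGCRatio:
    def test_symmetric_coupling_ratio_near_one(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 4000
            x = np.zeros(n)
            y = np.zeros(n)
            ex = rng.standard_normal(n)
            ey = rng.standard_normal(n)
            for t in range(1, n):
                x[t] = 0.4 * y[t - 1] + ex[t]
                y[t] = 0.4 * x[t - 1] + ey[t]
            vals.append(gc_ratio(x, y, 1))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_dominant_direction_ratio_large(self, rng):
        n = 5000
        x = np.zeros(n)
        y = np.zeros(n)
        ex = rng.standard_normal(n)
        ey = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.05 * y[t - 1] + ex[t]      # faint feedback
            y[t] = 0.9 * x[t - 1] + 0.3 * ey[t]  # strong forward path
        assert gc_ratio(x, y, 1) > 10.0

    def test_exactly_zero_reverse_gc_masked(self, rng):
        x, y = _coupled_pair(rng, n=5000, beta=0.9, noise=0.3)
        # reverse GC clips to zero -> ratio undefined
        assert np.isnan(gc_ratio(x, y, 1)) or gc_ratio(x, y, 1) > 10.0

    def test_zero_denominator_masked(self, rng):
        x = rng.standard_normal(500)
        y = np.full(500, 2.0)  # constant: both directions masked
        assert np.isnan(gc_ratio(x, y, 1))


class TestKernelGC:
    def test_independent_pair_near_zero(self, rng):
        v = kernel_gc(rng.standard_normal(2000), rng.standard_normal(2000), p=2)
        assert v <= 0.02

    def test_nonlinear_coupling_exceeds_linear(self, rng):
        x = rng.standard_normal(3000)
        y = np.zeros(3000)
        y[1:] = x[:-1] ** 2 + 0.2 * rng.standard_normal(2999)
        kv = kernel_gc(x, y, p=2)
        lv = max(linear_gc(x, y, 2).gc, 0.0)
        assert kv > lv + 0.5

    def test_wide_kernel_approaches_linear_gc(self, rng):
        x = rng.standard_normal(3000)
        y = np.zeros(3000)
        y[1:] = 0.7 * x[:-1] + 0.5 * rng.standard_normal(2999)
        wide = kernel_gc(x, y, p=2, kernel_width=20.0)
        lin = linear_gc(x, y, 2).gc
        assert wide == pytest.approx(lin, rel=0.2)

    def test_nonpositive_width_rejected(self, rng):
        with pytest.raises(ValueError):
            kernel_gc(rng.standard_normal(500), rng.standard_normal(500),
                      p=1, kernel_width=0.0)


class TestLsNGC:
    def test_null_f_statistic_calibrated(self):
        n, p, c = 2000, 3, 8
        d2 = n - (p + c + 1)
        crit95 = stats.f.ppf(0.95, c, d2)
        below = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f, _ = lsngc(rng.standard_normal(n), rng.standard_normal(n),
                         n_centers=c, p=p, seed=seed)
            if f < crit95:
                below += 1
        assert below >= 18

    def test_strong_coupling_exceeds_99th_percentile(self):
        n, p, c = 2000, 3, 8
        crit99 = stats.f.ppf(0.99, c, n - (p + c + 1))
        above = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(n)
            y = np.zeros(n)
            y[1:] = np.tanh(2.0 * x[:-1]) + 0.3 * rng.standard_normal(n - 1)
            f, _ = lsngc(x, y, n_centers=c, p=p, seed=seed)
            if f > crit99:
                above += 1
        assert above >= 9

    def test_single_center_gives_no_information(self, rng):
        f, aff = lsngc(rng.standard_normal(1500), rng.standard_normal(1500),
                       n_centers=1, p=2, seed=0)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert aff == pytest.approx(0.0, abs=1e-9)


class TestMlGC:
    def test_independent_pair_near_zero_on_average(self):
        vals = [
            ml_gc(np.random.default_rng(s).standard_normal(2000),
                  np.random.default_rng(1000 + s).standard_normal(2000),
                  "mlp", p=2, seed=s)
            for s in range(10)
        ]
        assert abs(np.mean(vals)) <= 0.05

    def test_linear_coupling_comparable_to_linear_gc(self, rng):
        x = rng.standard_normal(3000)
        y = np.zeros(3000)
        y[1:] = 0.8 * x[:-1] + 0.6 * rng.standard_normal(2999)
        mlp = ml_gc(x, y, "mlp", p=2, seed=0)
        lin = linear_gc(x, y, 2).gc
        assert mlp == pytest.approx(lin, rel=0.3)

    def test_seed_determinism(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert ml_gc(x, y, "mlp", p=2, seed=5) == ml_gc(x, y, "mlp", p=2, seed=5)

    def test_unknown_model_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            ml_gc(rng.standard_normal(500), rng.standard_normal(500), "forest")


class TestTransferEntropy:
    def test_independent_binary_sequences_near_zero(self, rng):
        x = rng.integers(0, 2, 5000).astype(float)
        y = rng.integers(0, 2, 5000).astype(float)
        assert transfer_entropy(x, y, lag=1, n_bins=2, seed=0) <= 0.02

    def test_deterministic_copy_carries_one_bit(self, rng):
        x = rng.integers(0, 2, 5000).astype(float)
        y = np.zeros(5000)
        y[1:] = x[:-1]
        te = transfer_entropy(x, y, lag=1, n_bins=2, seed=0)
        assert te == pytest.approx(1.0, abs=0.05)

    def test_shifted_copy_dominates_independent_target(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(4000)
            shifted = np.roll(x, 1)
            indep = rng.standard_normal(4000)
            te_self = transfer_entropy(x, shifted, lag=1, seed=seed)
            te_ind = transfer_entropy(x, indep, lag=1, seed=seed)
            assert te_self >= te_ind


class TestMaxLaggedCorrelation:
    def test_delayed_copy_recovered(self, rng):
        fs = 25.0
        n = 7500
        x = np.sin(2 * np.pi * 0.3 * np.arange(n) / fs) \
            + 0.01 * rng.standard_normal(n)
        y = np.roll(x, int(0.5 * fs))
        r, lag = max_lagged_correlation(x[50:-50], y[50:-50], fs)
        assert r == pytest.approx(1.0, abs=0.01)
        assert lag == pytest.approx(0.5, abs=1 / fs)

    def test_independent_noise_stays_small(self, rng):
        r, _ = max_lagged_correlation(rng.standard_normal(7500),
                                      rng.standard_normal(7500), 25.0)
        assert abs(r) <= 0.08

    def test_anticorrelated_signals_return_signed_extreme(self, rng):
        x = np.sin(2 * np.pi * 0.3 * np.arange(7500) / 25.0) \
            + 0.01 * rng.standard_normal(7500)
        r, lag = max_lagged_correlation(x, -x, 25.0)
        assert r == pytest.approx(-1.0, abs=0.01)
        assert lag == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_masked(self, rng):
        r, lag = max_lagged_correlation(np.full(1000, 1.0),
                                        rng.standard_normal(1000), 25.0)
        assert np.isnan(r) and np.isnan(lag)


class TestAssembleCouplingFeatures:
    def test_exactly_32_features(self, healthy_recording):
        resp25, rr25 = paired_signals_25hz(healthy_recording)
        feats, log = assemble_coupling_features(resp25, rr25, seed=0)
        assert len(feats) == 32
        assert log["p_resp_to_rr"] >= 1

    def test_seed_determinism_byte_identical(self, healthy_recording):
        resp25, rr25 = paired_signals_25hz(healthy_recording)
        a, _ = assemble_coupling_features(resp25, rr25, seed=3)
        b, _ = assemble_coupling_features(resp25, rr25, seed=3)
        assert a == b

    def test_uncoupled_recordings_show_null_causality(self, uncoupled_recordings):
        """Directional Resp->RR values collapse without planted coupling."""
        small = 0
        for i, rec in enumerate(uncoupled_recordings):
            resp25, rr25 = paired_signals_25hz(rec)
            feats, _ = assemble_coupling_features(resp25, rr25, seed=i)
            if feats["GC_RespToRR"] < 0.05 and feats["TE_RespToRR"] < 0.01:
                small += 1
        assert small >= 4  # >= 80% of the null cohort

    def test_direction_specificity_on_one_way_coupling(self, healthy_recording):
        resp25, rr25 = paired_signals_25hz(healthy_recording)
        feats, _ = assemble_coupling_features(resp25, rr25, seed=0)
        assert feats["GC_RespToRR"] > feats["GC_RRToResp"]
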