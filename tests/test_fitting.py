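"""Aggregation, truncation and weighted-NLS fitting, against brute-force oracles."""

import warnings

import numpy as np
import pytest

from ppase_kinetics import (
    HillParams,
    KineticDataset,
    MWCParams,
    UnderdeterminedError,
    aggregate_replicates,
    fit_model,
    hill_rate,
    mm_rate,
    mwc_rate,
    truncate_for_substrate_inhibition,
)

S_GRID = np.array([0.025, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.8])


def noiseless_dataset(model, params, s=S_GRID):
    rate = {"hill": hill_rate, "mwc": mwc_rate}[model](s, params)
    return KineticDataset(s, rate, np.zeros_like(s), np.full(s.size, 3))


class TestAggregateReplicates:
    def test_hand_arithmetic(self):
        ds = aggregate_replicates([0.1, 0.1, 0.1], [0.4, 0.5, 0.6])
        assert ds.mean_rate[0] == pytest.approx(0.5)
        assert ds.rate_variance[0] == pytest.approx(0.01)
        assert ds.n_replicates[0] == 3

    def test_levels_sorted_by_substrate(self):
        ds = aggregate_replicates([0.2, 0.1, 0.2, 0.1], [0.3, 0.1, 0.3, 0.1])
        assert list(ds.s) == [0.1, 0.2]

    def test_zero_variance_survives_aggregation(self):
        ds = aggregate_replicates([0.1] * 3 + [0.2] * 3, [0.3] * 3 + [0.5, 0.6, 0.55])
        assert ds.rate_variance[0] == 0.0  # fallback happens at fit time

    def test_single_replicate_errors_by_default(self):
        with pytest.raises(ValueError, match="single replicate"):
            aggregate_replicates([0.1, 0.2, 0.2], [0.1, 0.3, 0.4])

    def test_single_replicate_pooled_substitution_warns(self):
        with pytest.warns(UserWarning, match="pooled"):
            ds = aggregate_replicates(
                [0.1, 0.2, 0.2], [0.1, 0.3, 0.4], single_replicate="pooled"
            )
        assert ds.rate_variance[0] == pytest.approx(ds.rate_variance[1])

    def test_non_finite_rates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            aggregate_replicates([0.1, 0.1], [0.3, np.nan])


class TestTruncation:
    def test_noop_below_threshold(self):
        ds = aggregate_replicates([0.05] * 3 + [0.1] * 3, list(range(3)) + list(range(3)))
        out = truncate_for_substrate_inhibition(ds, 0.2, min_points=2)
        assert list(out.s) == list(ds.s)

    def test_counts_by_inspection(self):
        s = np.array([0.05, 0.1, 0.2, 0.25, 0.5])
        ds = KineticDataset(s, s, np.full(5, 0.01), np.full(5, 3))
        out = truncate_for_substrate_inhibition(ds, 0.2, min_points=3)
        assert len(out) == 3
        assert out.s.max() == 0.2

    def test_underdetermined_error(self):
        s = np.array([0.05, 0.1, 0.2, 0.25, 0.5])
        ds = KineticDataset(s, s, np.full(5, 0.01), np.full(5, 3))
        with pytest.raises(UnderdeterminedError):
            truncate_for_substrate_inhibition(ds, 0.01, min_points=4)


def grid_oracle_sse(dataset, model, n=20):
    """Exhaustive SSE over an n^3 grid spanning the optimisation bounds."""
    s = dataset.s
    y = dataset.mean_rate
    var = dataset.rate_variance.copy()
    var[var <= 0] = var[var > 0].min() if np.any(var > 0) else 1.0
    w = 1.0 / var
    vmax, smax = y.max(), s.max()
    vms = np.linspace(0.05 * vmax, 10 * vmax, n)
    best = np.inf
    if model == "hill":
        ks = np.geomspace(1e-3 * smax, 10 * smax, n)
        ns = np.linspace(0.5, 8.0, n)
        for vm in vms:
            for k in ks:
                for nh in ns:
                    sse = np.sum(w * (y - hill_rate(s, HillParams(vm, k, nh))) ** 2)
                    best = min(best, sse)
    else:
        krs = np.geomspace(1e-3 * smax * 1000, 10 * smax * 1000, n)
        ls = np.geomspace(1e-2, 1e7, n)
        for vm in vms:
            for kr in krs:
                for l in ls:
                    sse = np.sum(w * (y - mwc_rate(s, MWCParams(vm, l, kr))) ** 2)
                    best = min(best, sse)
    return best


class TestFitModel:
    def test_noiseless_hill_recovery(self):
        ds = noiseless_dataset("hill", HillParams(1.0, 0.10, 2.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(ds, "hill", weights="unit")
        assert fit.params["vm"] == pytest.approx(1.0, rel=1e-6)
        assert fit.params["k_half"] == pytest.approx(0.10, rel=1e-6)
        assert fit.params["n_h"] == pytest.approx(2.0, rel=1e-6)
        assert fit.wrss < 1e-12

    def test_noiseless_mwc_recovery_tabulated_truth(self):
        s = np.geomspace(0.010, 0.500, 10)
        truth = MWCParams(vm=0.51, l=17.0, k_r=84.0)
        ds = KineticDataset(s, mwc_rate(s, truth), np.zeros_like(s), np.full(10, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(ds, "mwc", weights="unit")
        assert fit.params["vm"] == pytest.approx(0.51, rel=1e-4)
        assert fit.params["l"] == pytest.approx(17.0, rel=1e-4)
        assert fit.params["k_r"] == pytest.approx(84.0, rel=1e-4)

    @pytest.mark.parametrize("model", ["hill", "mwc", "mm"])
    def test_exact_recovery_randomized(self, model, rng):
        """Noiseless generating parameters are recovered to 1e-6 relative."""
        for _ in range(20):
            vm = float(rng.uniform(0.2, 2.0))
            if model == "hill":
                truth = HillParams(vm, float(rng.uniform(0.05, 0.3)), float(rng.uniform(1.0, 5.0)))
                y = hill_rate(S_GRID, truth)
                expect = (truth.vm, truth.k_half, truth.n_h)
            elif model == "mwc":
                truth = MWCParams(vm, float(10 ** rng.uniform(0.5, 3.0)), float(rng.uniform(30, 200)))
                y = mwc_rate(S_GRID, truth)
                expect = (truth.vm, truth.l, truth.k_r)
            else:
                km = float(rng.uniform(0.05, 0.3))
                y = mm_rate(S_GRID, vm, km)
                expect = (vm, km)
            ds = KineticDataset(S_GRID, y, np.zeros_like(S_GRID), np.full(S_GRID.size, 3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_model(ds, model, weights="unit")
            for got, want in zip(fit.theta, expect):
                assert got == pytest.approx(want, rel=1e-6)

    @pytest.mark.parametrize("model", ["hill", "mwc"])
    def test_dominates_grid_oracle_on_noisy_data(self, model, rng):
        """Fitted weighted SSE never exceeds the exhaustive grid-search SSE."""
        for _ in range(3):
            truth_rate = hill_rate(S_GRID, HillParams(0.5, 0.12, 2.5))
            reps = truth_rate[None, :] * (1 + 0.08 * rng.standard_normal((4, S_GRID.size)))
            ds = aggregate_replicates(
                np.tile(S_GRID, 4), np.abs(reps).ravel()
            )
            fit = fit_model(ds, model)
            assert fit.wrss <= grid_oracle_sse(ds, model) + 1e-9

    def test_weight_scale_invariance(self, rng):
        """Multiplying all variances by a constant leaves estimates unchanged."""
        truth_rate = mwc_rate(S_GRID, MWCParams(0.5, 30.0, 90.0))
        reps = truth_rate[None, :] * (1 + 0.08 * rng.standard_normal((4, S_GRID.size)))
        ds = aggregate_replicates(np.tile(S_GRID, 4), np.abs(reps).ravel())
        scaled = KineticDataset(
            ds.s, ds.mean_rate, 100.0 * ds.rate_variance, ds.n_replicates
        )
        f1 = fit_model(ds, "mwc")
        f2 = fit_model(scaled, "mwc")
        for name in f1.params:
            assert f1.params[name] == pytest.approx(f2.params[name], rel=1e-6)
        # SEs follow the stated convention: s^2 = wSSE/(N-p) absorbs the scale
        for name in f1.se:
            assert f1.se[name] == pytest.approx(f2.se[name], rel=1e-4)

    def test_zero_variance_fallback_warns(self):
        y = hill_rate(S_GRID, HillParams(1.0, 0.1, 2.0))
        var = np.full(S_GRID.size, 0.001)
        var[0] = 0.0
        ds = KineticDataset(S_GRID, y, var, np.full(S_GRID.size, 3))
        with pytest.warns(UserWarning, match="smallest positive variance"):
            fit = fit_model(ds, "hill")
        assert fit.converged

    def test_underdetermined_errors(self):
        s = np.array([0.1, 0.2, 0.3])
        ds = KineticDataset(s, s, np.full(3, 0.01), np.full(3, 3))
        with pytest.raises(UnderdeterminedError):
            fit_model(ds, "hill")

    def test_truncation_recorded_in_result(self):
        s = np.array([0.05, 0.1, 0.15, 0.2, 0.3, 0.5])
        y = hill_rate(s, HillParams(1.0, 0.1, 2.0))
        ds = KineticDataset(s, y, np.full(s.size, 1e-4), np.full(s.size, 4))
        fit = fit_model(ds, "hill", truncate_max_s=0.2)
        assert fit.truncation_max_s == 0.2
        assert fit.points_used == 4

    def test_deterministic(self, rng):
        truth_rate = hill_rate(S_GRID, HillParams(0.5, 0.12, 2.5))
        reps = truth_rate[None, :] * (1 + 0.08 * rng.standard_normal((4, S_GRID.size)))
        ds = aggregate_replicates(np.tile(S_GRID, 4), np.abs(reps).ravel())
        f1 = fit_model(ds, "hill")
        f2 = fit_model(ds, "hill")
        assert f1.params == f2.params and f1.se == f2.se
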