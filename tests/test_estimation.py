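"""Weighted least-squares fit: objective correctness and optimizer quality.

The independent oracle for the optimizer is an exhaustive grid search over
(beta, gamma) followed by derivative-free local refinement — a brute-force
route that shares no code with the fit's own grid-seeded L-BFGS-B path.
"""

import numpy as np
import pytest
from scipy.optimize import fmin
from scipy.special import expit

from cdlr import (
    CDLRParams,
    bin_observations,
    fit_cdlr,
    ntcp,
    simulate_cohort,
    weighted_sse,
)
from cdlr.binning import BinnedSeries, DoseBin
from cdlr.estimation import InsufficientDataError
from cdlr.simulate import SimConfig


def series_from(dose_reps, incidences, weights, metric="mean", width=5.0):
    """Assemble a BinnedSeries directly from (dose, incidence, weight) triples."""
    bins = tuple(
        DoseBin(
            lower=d - width / 2,
            upper=d + width / 2,
            n_total=int(w),
            n_events=int(round(w * p)),
            incidence=p,
            dose_rep=d,
        )
        for d, p, w in zip(dose_reps, incidences, weights)
    )
    return BinnedSeries(metric=metric, bin_width=width, bins=bins)


def grid_refine_oracle(series, n_grid=200):
    """Brute-force WLS optimum: dense grid then Nelder-Mead polish."""
    d = np.array([b.dose_rep for b in series.bins])
    p = np.array([b.incidence for b in series.bins])
    w = np.array([b.n_total for b in series.bins], dtype=float)

    def sse(theta):
        return float(np.sum(w * (p - expit(d * theta[0] - theta[1])) ** 2))

    betas = np.linspace(0.001, 0.5, n_grid)
    gammas = np.linspace(0.0, 20.0, n_grid)
    mu = expit(d[None, None, :] * betas[:, None, None] - gammas[None, :, None])
    grid = np.einsum("k,ijk->ij", w, (p[None, None, :] - mu) ** 2)
    i, j = np.unravel_index(np.argmin(grid), grid.shape)
    best = fmin(sse, [betas[i], gammas[j]], xtol=1e-12, ftol=1e-14, disp=False)
    return min(sse(best), float(grid[i, j]))


def random_small_series(rng):
    n_bins = rng.integers(3, 7)
    dose_reps = np.sort(rng.uniform(10, 75, n_bins))
    incidences = np.sort(rng.uniform(0, 1, n_bins))  # roughly monotone data
    weights = rng.integers(1, 20, n_bins)
    return series_from(dose_reps, incidences, weights)


class TestWeightedSse:
    def test_zero_when_curve_interpolates(self, mean_params):
        d = np.arange(15.0, 61.0, 5.0)
        series = series_from(d, ntcp(d, mean_params), np.full(len(d), 10))
        assert weighted_sse(series, mean_params) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_arithmetic_on_two_bins(self):
        params = CDLRParams(beta=0.1, gamma=4.0)
        series = series_from([30.0, 50.0], [0.2, 0.8], [3, 7])
        expected = 3 * (0.2 - ntcp(30.0, params)) ** 2 + 7 * (0.8 - ntcp(50.0, params)) ** 2
        assert weighted_sse(series, params) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_weights(self, mean_params):
        rng = np.random.default_rng(3)
        series = random_small_series(rng)
        doubled = series_from(
            [b.dose_rep for b in series.bins],
            [b.incidence for b in series.bins],
            [2 * b.n_total for b in series.bins],
        )
        assert weighted_sse(doubled, mean_params) == pytest.approx(
            2 * weighted_sse(series, mean_params), rel=1e-12
        )


class TestFitCdlr:
    def test_recovers_noise_free_curve(self, mean_params):
        d = np.arange(15.0, 61.0, 5.0)
        series = series_from(d, ntcp(d, mean_params), np.full(len(d), 10))
        result = fit_cdlr(series)
        assert result.converged
        assert result.params.beta == pytest.approx(mean_params.beta, rel=1e-4)
        assert result.params.gamma == pytest.approx(mean_params.gamma, rel=1e-4)
        assert result.weighted_sse == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_never_worse_than_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        series = random_small_series(rng)
        assert fit_cdlr(series).weighted_sse <= grid_refine_oracle(series) + 1e-8

    def test_replicated_observations_equal_scaled_weights(self, mean_params):
        # fitting raw data replicated k-fold == fitting with k-scaled weights
        rng = np.random.default_rng(11)
        cfg = SimConfig(n_patients=40, true_params=mean_params, seed=5,
                        dose_low=15.0, dose_high=60.0)
        obs = simulate_cohort(cfg)
        series = bin_observations(obs, "mean")
        k = 3
        scaled = series_from(
            [b.dose_rep for b in series.bins],
            [b.incidence for b in series.bins],
            [k * b.n_total for b in series.bins],
        )
        fit_a, fit_b = fit_cdlr(series), fit_cdlr(scaled)
        assert fit_a.params.beta == pytest.approx(fit_b.params.beta, rel=1e-6)
        assert fit_a.params.gamma == pytest.approx(fit_b.params.gamma, rel=1e-6)
        del rng

    def test_independent_of_bin_order(self, mean_params):
        series = random_small_series(np.random.default_rng(21))
        reversed_series = BinnedSeries(
            metric=series.metric, bin_width=series.bin_width,
            bins=tuple(reversed(series.bins)),
        )
        fit_a, fit_b = fit_cdlr(series), fit_cdlr(reversed_series)
        # summation order perturbs the objective at machine precision
        assert fit_a.params.beta == pytest.approx(fit_b.params.beta, rel=1e-6)
        assert fit_a.params.gamma == pytest.approx(fit_b.params.gamma, rel=1e-6)

    def test_deterministic_across_calls(self):
        series = random_small_series(np.random.default_rng(8))
        assert fit_cdlr(series) == fit_cdlr(series)

    def test_accepts_explicit_init(self, mean_params):
        d = np.arange(15.0, 61.0, 5.0)
        series = series_from(d, ntcp(d, mean_params), np.full(len(d), 10))
        result = fit_cdlr(series, init=CDLRParams(beta=0.05, gamma=3.0))
        assert result.params.beta == pytest.approx(mean_params.beta, rel=1e-4)

    @pytest.mark.parametrize(
        "series",
        [
            series_from([30.0], [0.5], [5]),
            series_from([30.0, 30.0], [0.2, 0.8], [5, 5]),
        ],
        ids=["one_bin", "identical_doses"],
    )
    def test_insufficient_data_raises(self, series):
        with pytest.raises(InsufficientDataError):
            fit_cdlr(series)

    def test_consistency_bias_shrinks_with_cohort_size(self, mean_params):
        # fitted parameters approach the generating truth as n grows
        true_td50 = mean_params.td50

        def td50_err(n, seed):
            cfg = SimConfig(n_patients=n, true_params=mean_params, seed=seed,
                            dose_low=15.0, dose_high=75.0)
            series = bin_observations(simulate_cohort(cfg), "mean")
            return fit_cdlr(series).report.td50 - true_td50

        small = np.mean([abs(td50_err(250, s)) for s in range(5)])
        large = np.mean([abs(td50_err(10000, s)) for s in range(5)])
        assert large < small
        assert large < 1.0

    def test_artifact_dict_schema(self, study_cohort):
        result = fit_cdlr(bin_observations(study_cohort, "mean"))
        d = result.to_dict()
        assert set(d) == {
            "metric", "bin_width", "beta", "gamma", "m",
            "td25", "td50", "weighted_sse", "n_bins", "converged",
        }
        assert d["weighted_sse"] >= 0
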