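"""Goodness-of-fit, local CIs, sensitivity and contribution matrices."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from emuflux.estimate import (FitResults, FluxMeasurement, MDVMeasurement,
                              make_fit_problem, solve)
from emuflux.fixtures import generate_synthetic_dataset
from emuflux.network import read_network
from emuflux.stats import (chi2_test, contribution_matrix,
                           local_confidence_intervals, residual_normality,
                           sensitivity_matrix)


class _LinearProblem:
    """Minimal duck-typed problem: one parameter, direct measurements.

    r_k = (theta - m_k) / sd_k, so every statistic has a closed form.
    """

    def __init__(self, means, sds):
        self.stacked_means = np.asarray(means, dtype=float)
        self.stacked_sd = np.asarray(sds, dtype=float)
        self.n_residuals = self.stacked_means.size
        self.n_params = 1
        self.report_names = ["x"]
        self.residual_labels = [f"m{k}" for k in range(self.n_residuals)]

    def report_values(self, theta):
        return np.array([theta[0]])

    def report_jacobian(self, theta):
        return np.array([[1.0]])

    def fit(self):
        w = 1.0 / self.stacked_sd ** 2
        xhat = float(np.sum(w * self.stacked_means) / np.sum(w))
        theta = np.array([xhat])
        r = (xhat - self.stacked_means) / self.stacked_sd
        J = (1.0 / self.stacked_sd)[:, None]
        return FitResults(problem=self, theta=theta, phi=float(r @ r),
                          residuals=r, jacobian=J, converged=True,
                          n_starts=1, seed=None)


class TestChi2:
    def test_dof_arithmetic(self):
        fit = _LinearProblem(np.zeros(20), np.ones(20)).fit()
        fit.problem.n_params = 6
        assert fit.dof == 14

    def test_noise_free_fit_flagged_too_good(self, ss_fit_clean):
        stats = chi2_test(ss_fit_clean)
        assert stats.chi2 < stats.chi2_lo
        assert not stats.accepted  # suspiciously small residuals

    def test_correctly_specified_noise_accepted(self, ss_fit_noisy):
        stats = chi2_test(ss_fit_noisy)
        assert stats.chi2_lo <= stats.chi2 <= stats.chi2_hi

    def test_nonpositive_dof_rejected(self):
        fit = _LinearProblem([0.0], [1.0]).fit()
        with pytest.raises(ValueError, match="dof"):
            chi2_test(fit)


class TestResidualNormality:
    def test_gaussian_residuals_pass(self, rng):
        passes = sum(residual_normality(rng.standard_normal(40))[1] > 0.05
                     for _ in range(100))
        assert passes >= 90

    def test_heavy_tails_detected(self, rng):
        rejections = sum(residual_normality(rng.standard_t(2, 50))[1] < 0.05
                         for _ in range(100))
        assert rejections > 50

    def test_constant_residuals_degenerate(self):
        with pytest.raises(ValueError):
            residual_normality(np.ones(20))

    def test_too_few_residuals(self):
        with pytest.raises(ValueError):
            residual_normality(np.zeros(5))

    def test_quantile_pairs_shape(self, rng):
        _, _, pairs = residual_normality(rng.standard_normal(30))
        assert pairs.shape == (30, 2)
        assert np.all(np.diff(pairs[:, 0]) >= 0)  # ordered quantiles


class TestLocalCI:
    def test_single_linear_residual_closed_form(self):
        m, sd = 3.7, 0.25
        fit = _LinearProblem([m], [sd]).fit()
        ci = local_confidence_intervals(fit, alpha=0.05)
        z = sps.norm.ppf(0.975)
        assert ci.loc["x", "estimate"] == pytest.approx(m)
        assert ci.loc["x", "ci_lo"] == pytest.approx(m - z * sd)
        assert ci.loc["x", "ci_hi"] == pytest.approx(m + z * sd)

    def test_futile_cycle_flagged_unidentifiable(self):
        # P <-> Q cycling does not move any label: the cycle magnitude is a
        # null direction of the Jacobian and must be reported as unbounded
        net = read_network(io.StringIO(
            "id\tequation\treversible\n"
            "in\tA{a} -> P{a}\t0\n"
            "p\tP{a} -> Q{a}\t0\n"
            "q\tQ{a} -> P{a}\t0\n"
            "out\tP{a} -> F{a}\t0\n"))
        from emuflux.labeling import LabelingStrategy
        strat = LabelingStrategy({"A": [("1", 0.5, 1.0), ("0", 0.5, 1.0)]})
        from emuflux.simulate import simulate_steady_state
        v = {"in": 10, "p": 5, "q": 5, "out": 10}
        sim = simulate_steady_state(net, v, strat, ["F_1"])
        meas = [MDVMeasurement("F_1", "ss",
                               list(sim.values())[0].values, [0.01, 0.01])]
        prob = make_fit_problem(net, meas, [FluxMeasurement("in", 10.0, 0.1)],
                                strat, "ss",
                                net_flux_bounds={"p": (0, 50), "q": (0, 50)})
        fit = solve(prob, n_starts=2, seed=1)
        ci = local_confidence_intervals(fit)
        assert not ci.loc["net:p", "identifiable"]
        assert not ci.loc["net:q", "identifiable"]
        assert np.isinf(ci.loc["net:p", "ci_hi"])
        assert ci.loc["net:in", "identifiable"]

    def test_ci_halfwidth_scales_with_sd(self):
        base = _LinearProblem([1.0, 2.0, 1.5], [0.1, 0.1, 0.1]).fit()
        twice = _LinearProblem([1.0, 2.0, 1.5], [0.2, 0.2, 0.2]).fit()
        def hw(fit):
            ci = local_confidence_intervals(fit)
            return ci.loc["x", "ci_hi"] - ci.loc["x", "ci_lo"]
        assert hw(twice) == pytest.approx(2 * hw(base), rel=1e-9)

    def test_hessian_psd(self, ss_fit_noisy):
        H = ss_fit_noisy.hessian
        assert np.allclose(H, H.T)
        assert np.linalg.eigvalsh(H).min() > -1e-8 * np.abs(H).max()


class TestSensitivity:
    def test_single_measurement_unit_sensitivity(self):
        fit = _LinearProblem([2.0], [0.5]).fit()
        S = sensitivity_matrix(fit)
        assert S.iloc[0, 0] == pytest.approx(1.0)

    def test_duplicated_measurement_halves_influence(self):
        single = _LinearProblem([2.0], [0.5]).fit()
        double = _LinearProblem([2.0, 2.0], [0.5, 0.5]).fit()
        S1 = sensitivity_matrix(single).to_numpy()
        S2 = sensitivity_matrix(double).to_numpy()
        assert np.allclose(S2, 0.5 * S1[0, 0])

    def test_finite_difference_oracle(self, toyspec, ss_fit_noisy):
        # perturb the most influential measurement entry, refit from the
        # optimum, compare the estimate shift against the analytic
        # sensitivity; refit termination noise bounds the achievable
        # absolute accuracy on the flux scale of 100
        fit = ss_fit_noisy
        prob = fit.problem
        S = sensitivity_matrix(fit)
        net_rows = [i for i, n in enumerate(prob.report_names)
                    if n.startswith("net:")]
        absS = np.abs(S.to_numpy()[net_rows, :])
        j = int(absS.max(axis=0).argmax())
        delta = 1e-3
        means = prob.stacked_means.copy()
        means[j] += delta
        refit = solve(prob, n_starts=1, seed=0, x0=fit.theta, means=means,
                      tol=1e-13, max_iter=1000)
        numeric = (prob.report_values(refit.theta)
                   - prob.report_values(fit.theta)) / delta
        for i in net_rows:
            analytic = S.iloc[i, j]
            if abs(analytic) >= 1.0:
                assert numeric[i] == pytest.approx(analytic, rel=0.02)
            else:
                assert numeric[i] == pytest.approx(analytic, abs=0.5)


class TestContribution:
    def test_rows_sum_to_one(self, ss_fit_noisy):
        C = contribution_matrix(ss_fit_noisy)
        sums = C.sum(axis=1).to_numpy()
        assert np.allclose(sums[np.isfinite(sums)], 1.0, atol=1e-9)
        assert (C.to_numpy()[np.isfinite(C.to_numpy())] >= -1e-12).all()

    def test_one_measurement_gives_unit_row(self):
        fit = _LinearProblem([2.0], [0.5]).fit()
        C = contribution_matrix(fit)
        assert np.allclose(C.to_numpy(), [[1.0]])

    def test_inst_kinetic_information_is_early(self, toyspec,
                                                inst_fit_clean):
        # kinetic (pool-size) information lives in the early transient: the
        # fastest-turnover pool draws its variance mostly from the earliest
        # samples, while plateau-determined fluxes draw on later ones
        fit = inst_fit_clean
        C = contribution_matrix(fit)
        labels = fit.problem.residual_labels
        times = np.array([float(l.split("@")[1].split("[")[0])
                          if "@" in l else np.nan for l in labels])
        # fastest-turnover pool (smallest c/outflux) at the fitted fluxes
        net = toyspec.network
        v = fit.total_fluxes
        pools = fit.pool_estimates
        tau = {m: pools[m] / sum(w * v[f]
                                 for f, w in net.consumption_weights(m))
               for m in pools}
        fastest = min(tau, key=tau.get)

        def row_stats(name):
            row = C.loc[name].to_numpy().copy()
            row[~np.isfinite(times)] = 0.0  # drop the flux-anchor column
            argmax_t = times[int(np.argmax(row))]
            wmean_t = float(np.nansum(row * np.nan_to_num(times))
                            / max(row.sum(), 1e-12))
            return argmax_t, wmean_t

        argmax_t, pool_wmean = row_stats(f"pool:{fastest}")
        assert argmax_t <= np.nanmedian(times)
        for rid in toyspec.identifiable_fluxes:
            _, flux_wmean = row_stats(f"net:{rid}")
            assert flux_wmean >= pool_wmean
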