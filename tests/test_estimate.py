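"""Flux estimation: problem assembly, recovery, dilution, Monte Carlo."""

import numpy as np
import pytest

from emuflux.estimate import (DilutionSpec, EstimationError, FluxMeasurement,
                              MDVMeasurement, make_fit_problem, solve,
                              solve_inst, solve_with_confidence_intervals)
from emuflux.fixtures import generate_synthetic_dataset
from emuflux.mdv import get_natural_MDV
from emuflux.emu import parse_emu


class TestMakeFitProblem:
    def test_free_parameter_count_is_nullity(self, toyspec, ss_dataset_clean):
        ds = ss_dataset_clean
        prob = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                ds.flux_measurements, toyspec.strategy, "ss")
        S = toyspec.network.net_stoichiometric_matrix().to_numpy()
        nullity = S.shape[1] - np.linalg.matrix_rank(S)
        assert prob.n_free == nullity == 2
        # + one exchange parameter for the reversible reaction
        assert prob.n_params == nullity + 1

    def test_dilution_adds_one_parameter(self, toyspec, ss_dataset_clean):
        ds = ss_dataset_clean
        base = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                ds.flux_measurements, toyspec.strategy, "ss")
        dil = make_fit_problem(toyspec.network, ds.mdv_measurements,
                               ds.flux_measurements, toyspec.strategy, "ss",
                               dilution=[DilutionSpec("F")])
        assert dil.n_params == base.n_params + 1

    def test_unknown_emu_rejected(self, toyspec, ss_dataset_clean):
        ds = ss_dataset_clean
        bad = MDVMeasurement(parse_emu("Zz_1"), "ss", [0.5, 0.5], [0.01, 0.01])
        with pytest.raises(EstimationError, match="not in network"):
            make_fit_problem(toyspec.network,
                             list(ds.mdv_measurements) + [bad],
                             ds.flux_measurements, toyspec.strategy, "ss")

    def test_scale_anchor_required(self, toyspec, ss_dataset_clean):
        with pytest.raises(EstimationError, match="anchor"):
            make_fit_problem(toyspec.network,
                             ss_dataset_clean.mdv_measurements, [],
                             toyspec.strategy, "ss")

    def test_sd_floor_applied(self, toyspec, ss_dataset_clean):
        ds = ss_dataset_clean
        tiny = MDVMeasurement(parse_emu("F_123"), "ss",
                              ds.mdv_measurements[0].mean,
                              np.full(4, 1e-9))
        prob = make_fit_problem(toyspec.network, [tiny],
                                ds.flux_measurements, toyspec.strategy, "ss")
        assert prob.measurements[0].sd.min() >= 1e-3

    def test_every_theta_is_mass_balanced(self, ss_problem_clean, rng):
        S = ss_problem_clean._Snet
        for _ in range(20):
            theta = ss_problem_clean.sample_start(rng)
            v = ss_problem_clean.net_fluxes(theta)
            assert np.abs(S @ v).max() <= 1e-9 * max(1.0, np.abs(v).max())

    def test_objective_invariant_to_measurement_order(self, toyspec,
                                                      ss_dataset_clean, rng):
        ds = ss_dataset_clean
        prob1 = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                 ds.flux_measurements, toyspec.strategy, "ss")
        shuffled = list(ds.mdv_measurements)[::-1]
        prob2 = make_fit_problem(toyspec.network, shuffled,
                                 ds.flux_measurements, toyspec.strategy, "ss")
        theta = prob1.sample_start(rng)
        assert prob1.objective(theta) == pytest.approx(prob2.objective(theta),
                                                       rel=1e-12)


class TestSteadyStateRecovery:
    def test_noise_free_recovery(self, toyspec, ss_dataset_clean,
                                 ss_fit_clean):
        ds, fit = ss_dataset_clean, ss_fit_clean
        assert fit.phi < 1e-3
        for rid in toyspec.identifiable_fluxes:
            assert fit.net_fluxes[rid] == pytest.approx(
                ds.true_net_fluxes[rid], abs=0.1)

    def test_duplicated_measurements_double_phi(self, toyspec,
                                                ss_dataset_noisy):
        ds = ss_dataset_noisy
        prob1 = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                 ds.flux_measurements, toyspec.strategy, "ss",
                                 net_flux_bounds=toyspec.fit_net_flux_bounds())
        prob2 = make_fit_problem(toyspec.network,
                                 list(ds.mdv_measurements) * 2,
                                 ds.flux_measurements, toyspec.strategy, "ss",
                                 net_flux_bounds=toyspec.fit_net_flux_bounds())
        fit1 = solve(prob1, n_starts=2, seed=4)
        # doubling every MDV measurement doubles its Phi contribution ...
        flux_part = fit1.residuals[-1] ** 2
        assert prob2.objective(fit1.theta) == pytest.approx(
            2 * (fit1.phi - flux_part) + flux_part, rel=1e-9)
        # ... and leaves the optimum where it was
        fit2 = solve(prob2, n_starts=1, seed=4, x0=fit1.theta)
        for rid in toyspec.identifiable_fluxes:
            assert fit2.net_fluxes[rid] == pytest.approx(
                fit1.net_fluxes[rid], abs=0.05)

    def test_g_value_recovery(self, toyspec, ss_dataset_clean):
        ds = ss_dataset_clean
        G = 0.8
        nat = get_natural_MDV(3).values
        meas = []
        for m in ds.mdv_measurements:
            if m.emu.name == "F_123":
                meas.append(MDVMeasurement(m.emu, "ss",
                                           G * m.mean + (1 - G) * nat, m.sd))
            else:
                meas.append(m)
        prob = make_fit_problem(toyspec.network, meas, ds.flux_measurements,
                                toyspec.strategy, "ss",
                                net_flux_bounds=toyspec.fit_net_flux_bounds(),
                                dilution=[DilutionSpec("F")])
        fit = solve(prob, n_starts=4, seed=6)
        assert fit.g_estimates["F"] == pytest.approx(0.8, abs=0.02)


class TestInstRecovery:
    def test_noise_free_flux_and_pool_recovery(self, toyspec,
                                               inst_dataset_clean,
                                               inst_fit_clean):
        ds, fit = inst_dataset_clean, inst_fit_clean
        for rid in toyspec.identifiable_fluxes:
            scale = max(abs(ds.true_net_fluxes[rid]), 1.0)
            assert abs(fit.net_fluxes[rid]
                       - ds.true_net_fluxes[rid]) / scale <= 0.01
        for met, c in ds.true_pools.items():
            assert abs(fit.pool_estimates[met] - c) / c <= 0.01

    def test_fixed_pools_tighten_recovery(self, toyspec, inst_dataset_clean):
        ds = inst_dataset_clean
        prob = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                ds.flux_measurements, ds.strategy, "inst",
                                net_flux_bounds=toyspec.fit_net_flux_bounds(),
                                fixed_pools=dict(ds.true_pools))
        fit = solve_inst(prob, n_starts=2, seed=8, max_iter=300)
        for rid in toyspec.identifiable_fluxes:
            scale = max(abs(ds.true_net_fluxes[rid]), 1.0)
            assert abs(fit.net_fluxes[rid]
                       - ds.true_net_fluxes[rid]) / scale <= 1e-3

    def test_single_timepoint_leaves_pools_unidentifiable(self, toyspec):
        from emuflux.stats import local_confidence_intervals
        ds = generate_synthetic_dataset(toyspec, noise_molpct=0.0, seed=5,
                                        mode="inst", timegrid=(0.0, 5.0))
        with pytest.warns(UserWarning, match="timepoints"):
            prob = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                    ds.flux_measurements, ds.strategy, "inst",
                                    net_flux_bounds=toyspec.fit_net_flux_bounds(),
                                    pools_init={m: 1.0 for m in ds.true_pools})
            fit = solve_inst(prob, n_starts=2, seed=8, max_iter=200)
        ci = local_confidence_intervals(fit)
        pool_rows = ci.loc[[f"pool:{m}" for m in ds.true_pools]]
        flux_rows = ci.loc[[f"net:{r}" for r in toyspec.identifiable_fluxes]]
        # at t >> turnover the data carry steady-state information only:
        # fluxes stay bounded, pool uncertainties blow up
        assert np.isfinite(flux_rows["sd"]).all()
        assert (~np.isfinite(pool_rows["sd"])).any() or \
            (pool_rows["sd"] > 10 * flux_rows["sd"].max()).any()


class TestMonteCarlo:
    def test_seed_reproducible(self, ss_problem_clean, ss_fit_clean):
        a = solve_with_confidence_intervals(ss_problem_clean, n_runs=10,
                                            seed=42, base=ss_fit_clean)
        b = solve_with_confidence_intervals(ss_problem_clean, n_runs=10,
                                            seed=42, base=ss_fit_clean)
        assert np.array_equal(a.samples, b.samples)
        assert a.ci().equals(b.ci())

    def test_parallel_matches_serial(self, ss_problem_clean, ss_fit_clean):
        a = solve_with_confidence_intervals(ss_problem_clean, n_runs=8,
                                            seed=7, base=ss_fit_clean)
        b = solve_with_confidence_intervals(ss_problem_clean, n_runs=8,
                                            seed=7, n_jobs=2,
                                            base=ss_fit_clean)
        assert np.allclose(a.samples, b.samples)

    def test_ci_width_scales_with_noise(self, toyspec):
        widths = {}
        for noise in (1.0, 0.5):
            ds = generate_synthetic_dataset(toyspec, noise_molpct=noise,
                                            seed=33, mode="ss",
                                            renormalize=False)
            prob = make_fit_problem(toyspec.network, ds.mdv_measurements,
                                    ds.flux_measurements, toyspec.strategy,
                                    "ss",
                                    net_flux_bounds=toyspec.fit_net_flux_bounds())
            base = solve(prob, n_starts=3, seed=5)
            mc = solve_with_confidence_intervals(prob, n_runs=60, seed=13,
                                                 base=base)
            ci = mc.ci()
            widths[noise] = np.mean([
                ci.loc[f"net:{r}", "ci_hi"] - ci.loc[f"net:{r}", "ci_lo"]
                for r in toyspec.identifiable_fluxes])
        # MDV noise halves; the flux-anchor sd (1% of uptake) stays, so the
        # ratio sits between 1.3 and 2.3 rather than exactly 2
        assert 1.3 <= widths[1.0] / widths[0.5] <= 2.3

    def test_near_zero_noise_gives_tiny_cis(self, ss_problem_clean,
                                            ss_fit_clean, toyspec):
        mc = solve_with_confidence_intervals(ss_problem_clean, n_runs=30,
                                             seed=3, base=ss_fit_clean)
        ci = mc.ci()
        for r in toyspec.identifiable_fluxes:
            hw = (ci.loc[f"net:{r}", "ci_hi"] - ci.loc[f"net:{r}", "ci_lo"]) / 2
            # limited by the sd floor and the 1-unit flux anchor sd, far
            # below the flux scale of 100
            assert hw < 5.0
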