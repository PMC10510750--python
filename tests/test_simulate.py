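"""Labeling simulation: EMU engine vs exhaustive isotopomer oracle,
steady-state identities, and the first-order-hold INST integrator."""

import io

import numpy as np
import pytest

from emuflux.constraint import sample_feasible_fluxes
from emuflux.emu import parse_emu
from emuflux.fixtures import (brute_force_inst, brute_force_steady_state,
                              toynet1)
from emuflux.labeling import LabelingStrategy
from emuflux.mdv import IsotopeConstants
from emuflux.network import read_network, split_total_fluxes
from emuflux.simulate import (EMUSimulator, SimulationError, simulate_inst,
                              simulate_steady_state)

C0 = IsotopeConstants(p13=0.0)

CHAIN_TSV = ("id\tequation\treversible\n"
             "r1\tA{ab} -> B{ab}\t0\n"
             "r2\tB{ab} -> F{ab}\t0\n")


class TestSteadyState:
    def test_chain_passthrough(self):
        net = read_network(io.StringIO(CHAIN_TSV))
        strat = LabelingStrategy({"A": [("10", 1.0, 1.0)]})
        for flux in (1.0, 42.0):
            res = simulate_steady_state(net, {"r1": flux, "r2": flux}, strat,
                                        ["F_12"], C0)
            assert np.allclose(res[parse_emu("F_12")].values, [0, 1, 0])

    def test_condensation_is_convolution(self):
        net = read_network(io.StringIO(
            "id\tequation\treversible\n"
            "r1\tC{a} + D{b} -> E{ab}\t0\n"
            "r2\tE{ab} -> F{ab}\t0\n"))
        strat = LabelingStrategy({"C": [("1", 0.4, 1.0), ("0", 0.6, 1.0)],
                                  "D": [("1", 1.0, 1.0)]})
        res = simulate_steady_state(net, {"r1": 3.0, "r2": 3.0}, strat,
                                    ["E_12"], C0)
        # conv([0.6, 0.4], [0, 1]) = [0, 0.6, 0.4]
        assert np.allclose(res[parse_emu("E_12")].values, [0, 0.6, 0.4])

    def test_toynet_agrees_with_isotopomer_oracle(self, toyspec):
        net, strat = toyspec.network, toyspec.strategy
        sim = EMUSimulator(net, strat, toyspec.measured_targets)
        draws = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=20,
                                       seed=17)
        for v in draws:
            emu_res = sim.steady_state(v)
            oracle = brute_force_steady_state(net, v, strat,
                                              toyspec.measured_targets)
            for emu in emu_res:
                assert np.abs(emu_res[emu].values
                              - oracle[emu].values).max() <= 1e-9

    def test_all_outputs_normalized(self, toyspec):
        net, strat = toyspec.network, toyspec.strategy
        sim = EMUSimulator(net, strat, toyspec.measured_targets)
        for v in sample_feasible_fluxes(net, toyspec.flux_bounds(), n=10,
                                        seed=23):
            for m in sim.steady_state(v).values():
                assert abs(m.values.sum() - 1.0) <= 1e-9

    def test_all_zero_fluxes_singular(self, toyspec):
        net = toyspec.network
        v = {f: 0.0 for f in net.total_flux_ids}
        sim = EMUSimulator(net, toyspec.strategy, ["F_123"])
        with pytest.raises(SimulationError):
            sim.steady_state(v)

    def test_unbalanced_fluxes_rejected(self, toyspec):
        net = toyspec.network
        v = {f: 10.0 for f in net.total_flux_ids}  # violates S.v = 0
        sim = EMUSimulator(net, toyspec.strategy, ["F_123"])
        with pytest.raises(SimulationError, match="mass-balanced"):
            sim.steady_state(v)

    def test_chain_balance_structure(self):
        # single internal EMU: A = [[-v]], B = [[v]]
        net = read_network(io.StringIO(CHAIN_TSV))
        strat = LabelingStrategy({"A": [("10", 1.0, 1.0)]})
        sim = EMUSimulator(net, strat, ["B_12"])
        (sys,) = sim._systems
        A, B, _, _, _ = sys.assemble(np.array([7.0, 7.0]), np.zeros(0))
        assert np.allclose(A, [[-7.0]])
        assert np.allclose(B, [[7.0]])

    def test_pool_scope_dilution(self):
        net = read_network(io.StringIO(CHAIN_TSV))
        strat = LabelingStrategy({"A": [("10", 1.0, 1.0)]})
        res = simulate_steady_state(net, {"r1": 10, "r2": 10}, strat,
                                    ["F_12"], C0, dilution={"B": 0.7})
        # F sees 70% labeled B + 30% natural (here unlabeled)
        assert np.allclose(res[parse_emu("F_12")].values, [0.3, 0.7, 0.0])


class TestInst:
    def test_initial_condition_is_natural(self, toyspec):
        net = toyspec.network
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=3)[0]
        tr = simulate_inst(net, v, toyspec.default_pools, toyspec.inst_strategy,
                           toyspec.measured_targets, [0.0, 0.1])
        from emuflux.mdv import get_natural_MDV
        for t in toyspec.measured_targets:
            emu = parse_emu(t)
            nat = get_natural_MDV(emu.size).values
            assert np.abs(tr.mdvs[emu][0] - nat).max() <= 1e-12

    def test_agrees_with_isotopomer_ode_oracle(self, toyspec):
        net = toyspec.network
        strat = toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=29)[0]
        tg = toyspec.inst_timegrid
        # at a fine fixed grid the only residual is oracle/linear-solve
        # round-off; the default grid's discretization error is checked by
        # the convergence-order test below
        sim = EMUSimulator(net, strat, toyspec.measured_targets)
        tr = sim.inst(v, toyspec.default_pools, tg, n_substeps=128)
        orc = brute_force_inst(net, v, toyspec.default_pools, strat,
                               toyspec.measured_targets, tg)
        for t in toyspec.measured_targets:
            emu = parse_emu(t)
            assert np.abs(tr.mdvs[emu] - orc.mdvs[emu]).max() <= 1e-6
        tr_default = simulate_inst(net, v, toyspec.default_pools, strat,
                                   toyspec.measured_targets, tg)
        for t in toyspec.measured_targets:
            emu = parse_emu(t)
            assert np.abs(tr_default.mdvs[emu] - orc.mdvs[emu]).max() <= 2e-5

    def test_endpoint_reaches_steady_state(self, toyspec):
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=31)[0]
        # 50x the summed turnover times (network transit time)
        pools = toyspec.default_pools
        outflux = {m: sum(w * v[f] for f, w in net.consumption_weights(m))
                   for m in pools}
        t_end = 50 * sum(pools[m] / outflux[m] for m in pools)
        sim = EMUSimulator(net, strat, toyspec.measured_targets)
        tr = sim.inst(v, pools, [0.0, t_end])
        ss = sim.steady_state(v)
        for t in toyspec.measured_targets:
            emu = parse_emu(t)
            assert np.abs(tr.endpoint(emu).values
                          - ss[emu].values).max() <= 1e-6

    def test_pool_halving_rescales_time(self, toyspec):
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=37)[0]
        tg = np.array([0.0, 0.04, 0.1, 0.2])
        a = simulate_inst(net, v, toyspec.default_pools, strat,
                          toyspec.measured_targets, tg)
        half = {m: c / 2 for m, c in toyspec.default_pools.items()}
        b = simulate_inst(net, v, half, strat, toyspec.measured_targets,
                          tg / 2)
        for t in toyspec.measured_targets:
            emu = parse_emu(t)
            assert np.abs(a.mdvs[emu] - b.mdvs[emu]).max() <= 1e-8

    def test_foh_second_order_convergence(self, toyspec):
        # convolution sources vary in time under the mixture tracer, so the
        # first-order hold has genuine O(h^2) error against a fine reference
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=41)[0]
        sim = EMUSimulator(net, strat, toyspec.measured_targets)
        tg = (0.0, 0.05, 0.15, 0.4)
        ref = sim.inst(v, toyspec.default_pools, tg, n_substeps=256)

        def err(K):
            tr = sim.inst(v, toyspec.default_pools, tg, n_substeps=K)
            return max(np.abs(tr.mdvs[parse_emu(t)]
                              - ref.mdvs[parse_emu(t)]).max()
                       for t in toyspec.measured_targets)

        e1, e2, e4 = err(1), err(2), err(4)
        assert e1 / e2 >= 3.0 and e2 / e4 >= 3.0  # order >= 2

    def test_monotone_enrichment_step_input(self, toyspec):
        net = toyspec.network
        strat = LabelingStrategy({"A": [("111", 1.0, 1.0)]})
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=43)[0]
        tr = simulate_inst(net, v, toyspec.default_pools, strat,
                           toyspec.measured_targets, np.linspace(0, 0.6, 25))
        for t in toyspec.measured_targets:
            arr = tr.mdvs[parse_emu(t)]
            enr = arr @ np.arange(arr.shape[1]) / (arr.shape[1] - 1)
            assert np.all(np.diff(enr) > -1e-9)

    def test_normalized_at_every_timepoint(self, toyspec):
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=47)[0]
        tr = simulate_inst(net, v, toyspec.default_pools, strat,
                           toyspec.measured_targets, toyspec.inst_timegrid)
        for arr in tr.mdvs.values():
            assert np.abs(arr.sum(axis=1) - 1.0).max() <= 1e-9

    def test_nonpositive_pool_rejected(self, toyspec):
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=3)[0]
        pools = dict(toyspec.default_pools, B=0.0)
        with pytest.raises(SimulationError, match="pool"):
            simulate_inst(net, v, pools, strat, ["F_123"], [0.0, 0.1])

    def test_bad_timegrid_rejected(self, toyspec):
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=3)[0]
        with pytest.raises(SimulationError, match="timegrid"):
            simulate_inst(net, v, toyspec.default_pools, strat, ["F_123"],
                          [0.1, 0.2])
        with pytest.raises(SimulationError, match="timegrid"):
            simulate_inst(net, v, toyspec.default_pools, strat, ["F_123"],
                          [0.0, 0.2, 0.1])

    def test_trajectory_dataframe(self, toyspec):
        net, strat = toyspec.network, toyspec.inst_strategy
        v = sample_feasible_fluxes(net, toyspec.flux_bounds(), n=1, seed=3)[0]
        tr = simulate_inst(net, v, toyspec.default_pools, strat, ["F_123"],
                           [0.0, 0.1])
        df = tr.to_dataframe()
        assert set(df.columns) == {"emu_id", "t", "M0", "M1", "M2", "M3"}
        assert len(df) == 2
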