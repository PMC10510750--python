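"""Flux (and pool-size) estimation by weighted nonlinear least squares.

The unknown net fluxes are parameterized by null-space coordinates of the
net stoichiometric matrix, so every candidate flux vector satisfies the
mass balances S·v = 0 exactly; exchange fluxes of reversible reactions are
separate parameters mapped from [0, 1) onto [0, inf) by a tangent
transform; pool sizes (nonstationary mode) are estimated in log space; each
declared dilution adds one G-value in [0, 1].

The objective is the weighted residual sum of squares between simulated
and measured MDVs and exchange fluxes,

    Phi(theta) = sum_k ((y_k(theta) - m_k) / sd_k)^2,

minimized by multi-start sequential least squares programming (SLSQP) with
linear feasibility constraints; initial guesses are drawn from the feasible
flux polytope bounded by flux variability analysis.  Uncertainty comes from
the Gauss-Newton Hessian at convergence (see ``stats``) or from Monte-Carlo
refits of noise-perturbed data (``solve_with_confidence_intervals``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.linalg import null_space
from scipy.optimize import minimize

from .constraint import FluxBounds, InfeasibleError
from .emu import EMU, parse_emu
from .labeling import LabelingStrategy
from .mdv import DEFAULT_CONSTANTS, IsotopeConstants, get_natural_MDV
from .network import (FluxDistribution, MetabolicNetwork, NetworkError,
                      split_total_fluxes)
from .simulate import EMUSimulator, SimulationError

__all__ = [
    "MDVMeasurement", "FluxMeasurement", "DilutionSpec", "FitProblem",
    "FitResults", "MonteCarloResults", "make_fit_problem", "solve",
    "solve_inst", "solve_with_confidence_intervals", "EstimationError",
]

SD_FLOOR = 1e-3  # MDV standard deviations below this are raised to it
XCH_SCALE = 100.0  # exchange flux at transform midpoint w = 0.5
W_MAX = 0.98


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MDVMeasurement:
    """Measured MDV of one EMU at one timepoint ("ss" = isotopic steady state)."""

    emu: EMU
    timepoint: Union[str, float]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if isinstance(self.emu, str):
            object.__setattr__(self, "emu", parse_emu(self.emu))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise EstimationError(f"{self.emu}: mean/sd shape mismatch")
        if self.mean.size != self.emu.size + 1:
            raise EstimationError(
                f"{self.emu}: MDV length {self.mean.size} != size+1")
        if np.any(self.sd <= 0):
            raise EstimationError(f"{self.emu}: standard deviations must be > 0")
        if abs(self.mean.sum() - 1.0) > 0.02:
            warnings.warn(
                f"measured MDV of {self.emu} at {self.timepoint} sums to "
                f"{self.mean.sum():.4f}", stacklevel=2)
        if self.timepoint != "ss":
            object.__setattr__(self, "timepoint", float(self.timepoint))

    @property
    def label(self) -> str:
        tp = self.timepoint if self.timepoint == "ss" else f"{self.timepoint:g}"
        return f"{self.emu.name}@{tp}"


@dataclass(frozen=True)
class FluxMeasurement:
    """Measured net flux (uptake, secretion or growth) of one reaction."""

    reaction_id: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise EstimationError(f"{self.reaction_id}: sd must be > 0")

    @property
    def label(self) -> str:
        return f"flux:{self.reaction_id}"


@dataclass(frozen=True)
class DilutionSpec:
    """One diluted pool with a free G-value (labeled fraction).

    scope "measurement": the measured MDVs of this metabolite are modeled as
    ``G*simulated + (1-G)*natural`` (inactive fraction of a measured pool).
    scope "pool": the metabolite's appearances as a labeling *source* inside
    the network are diluted (unmeasured pools, e.g. intracellular CO2).
    """

    metabolite_id: str
    scope: str = "measurement"

    def __post_init__(self):
        if self.scope not in ("measurement", "pool"):
            raise EstimationError("dilution scope must be 'measurement' or 'pool'")


class FitProblem:
    """Precompiled inverse problem; build via :func:`make_fit_problem`."""

    def __init__(self, net: MetabolicNetwork, measurements: Sequence[MDVMeasurement],
                 flux_measurements: Sequence[FluxMeasurement],
                 strategy: LabelingStrategy, mode: str,
                 dilution: Sequence[DilutionSpec] = (),
                 net_flux_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
                 pools_init: Optional[Mapping[str, float]] = None,
                 fixed_pools: Optional[Mapping[str, float]] = None,
                 constants: IsotopeConstants = DEFAULT_CONSTANTS,
                 xch_scale: float = XCH_SCALE, inst_substeps: int = 8):
        if mode not in ("ss", "inst"):
            raise EstimationError("mode must be 'ss' or 'inst'")
        if not measurements:
            raise EstimationError("at least one MDV measurement is required")
        self.net = net
        self.mode = mode
        self.constants = constants
        self.strategy = strategy
        self.xch_scale = float(xch_scale)
        self.inst_substeps = int(inst_substeps)
        self.dilution = list(dilution)
        self.measurements = list(measurements)
        self.flux_measurements = list(flux_measurements)

        self.reaction_ids = list(net.reactions)
        for fm in self.flux_measurements:
            if fm.reaction_id not in net.reactions:
                raise EstimationError(f"measured flux of unknown reaction "
                                      f"{fm.reaction_id!r}")
        if not self.flux_measurements:
            raise EstimationError(
                "no measured exchange flux: the problem has no scale anchor")

        targets = sorted({m.emu for m in self.measurements})
        for t in targets:
            if t.metabolite_id not in net.metabolites:
                raise EstimationError(f"measured EMU {t.name} not in network")
        pool_scope = sorted(d.metabolite_id for d in self.dilution
                            if d.scope == "pool")
        self.simulator = EMUSimulator(net, strategy, targets, constants,
                                      diluted_pools=pool_scope)

        # floor tiny MDV sds (degenerate weights)
        self.measurements = [
            replace(m, sd=np.maximum(m.sd, SD_FLOOR)) for m in self.measurements]

        # --- null-space parameterization of net fluxes -----------------
        S_net = net.net_stoichiometric_matrix()
        self._Snet = S_net.to_numpy()
        self.N = null_space(self._Snet) if self._Snet.size else np.eye(
            len(self.reaction_ids))
        if self.N.shape[1] == 0:
            raise EstimationError("network has no degrees of freedom")
        # sign convention for determinism
        for j in range(self.N.shape[1]):
            k = np.argmax(np.abs(self.N[:, j]) > 1e-12)
            if self.N[k, j] < 0:
                self.N[:, j] = -self.N[:, j]
        self.n_free = self.N.shape[1]
        self.reversible = net.reversible_reaction_ids()
        # flux parameters are kept O(1): v_net = N @ (flux_scale * theta_u)
        self.flux_scale = max(1.0, *(abs(fm.mean) for fm in self.flux_measurements))

        # --- net-flux box: defaults, user bounds, measurement windows ---
        lo = np.full(len(self.reaction_ids), -1000.0)
        hi = np.full(len(self.reaction_ids), 1000.0)
        for i, rid in enumerate(self.reaction_ids):
            if not net.reactions[rid].reversible:
                lo[i] = 0.0
        if net_flux_bounds:
            for rid, (a, b) in net_flux_bounds.items():
                i = self.reaction_ids.index(rid)
                lo[i], hi[i] = max(lo[i], a), min(hi[i], b)
        for fm in self.flux_measurements:
            i = self.reaction_ids.index(fm.reaction_id)
            lo[i] = max(lo[i], fm.mean - 5 * fm.sd)
            hi[i] = min(hi[i], fm.mean + 5 * fm.sd)
        if np.any(lo > hi):
            raise InfeasibleError("contradictory net-flux bounds")
        self.net_lo, self.net_hi = lo, hi
        self._fva_box = self._net_fva_box()

        # --- parameter layout -------------------------------------------
        self.param_names: List[str] = [f"u{i}" for i in range(self.n_free)]
        self.param_names += [f"xch_w:{r}" for r in self.reversible]
        self.g_names = [d.metabolite_id for d in self.dilution]
        self.param_names += [f"G:{m}" for m in self.g_names]
        self.pooled_metabolites: List[str] = []
        self.fixed_pools = dict(fixed_pools or {})
        if mode == "inst":
            dyn = sorted({e.metabolite_id
                          for sys in self.simulator._systems
                          for e in sys.dynamic})
            self.pooled_metabolites = [m for m in dyn if m not in self.fixed_pools]
            self.param_names += [f"logc:{m}" for m in self.pooled_metabolites]
        self.n_params = len(self.param_names)
        self._iu = slice(0, self.n_free)
        self._iw = slice(self.n_free, self.n_free + len(self.reversible))
        gw = self.n_free + len(self.reversible)
        self._ig = slice(gw, gw + len(self.g_names))
        self._ic = slice(gw + len(self.g_names), self.n_params)
        self.pools_init = {m: float((pools_init or {}).get(m, 1.0))
                           for m in self.pooled_metabolites}

        # measurement bookkeeping
        self._meas_slices: List[slice] = []
        k = 0
        for m in self.measurements:
            self._meas_slices.append(slice(k, k + m.mean.size))
            k += m.mean.size
        self._n_mdv = k
        self.stacked_means = np.concatenate(
            [m.mean for m in self.measurements]
            + [np.array([fm.mean for fm in self.flux_measurements])])
        self.stacked_sd = np.concatenate(
            [m.sd for m in self.measurements]
            + [np.array([fm.sd for fm in self.flux_measurements])])
        self.residual_labels: List[str] = []
        for m in self.measurements:
            self.residual_labels += [f"{m.label}[M+{i}]" for i in range(m.mean.size)]
        self.residual_labels += [fm.label for fm in self.flux_measurements]
        self.n_residuals = self.stacked_means.size
        self._flux_meas_idx = [self.reaction_ids.index(fm.reaction_id)
                               for fm in self.flux_measurements]
        if mode == "inst":
            times = sorted({m.timepoint for m in self.measurements})
            if any(t == "ss" for t in times):
                raise EstimationError("inst mode requires numeric timepoints")
            self.timegrid = np.concatenate(
                [[0.0], np.array([t for t in times if t > 0], dtype=float)])
            if len(self.timegrid) < 2:
                raise EstimationError("inst mode requires at least one t > 0")
            self._time_index = {t: i for i, t in enumerate(self.timegrid)}
        else:
            if any(m.timepoint != "ss" for m in self.measurements):
                raise EstimationError("ss mode requires timepoint 'ss'")
        # natural MDVs for measurement-scope dilution
        self._nat = {m.emu: get_natural_MDV(m.emu.size, constants).values
                     for m in self.measurements}
        self._meas_dil = {}
        for d in self.dilution:
            if d.scope == "measurement":
                self._meas_dil[d.metabolite_id] = self.g_names.index(d.metabolite_id)
        self._pool_dil = {d.metabolite_id: self.g_names.index(d.metabolite_id)
                          for d in self.dilution if d.scope == "pool"}

    # -- flux mapping --------------------------------------------------------

    def _net_fva_box(self) -> Tuple[np.ndarray, np.ndarray]:
        """Feasible range of each net flux under the box + balances (the
        initial-guess sampling region)."""
        from scipy.optimize import linprog
        nr = len(self.reaction_ids)
        lov = np.empty(nr)
        hiv = np.empty(nr)
        bounds = list(zip(self.net_lo, self.net_hi))
        for i in range(nr):
            c = np.zeros(nr)
            c[i] = 1.0
            a = linprog(c, A_eq=self._Snet, b_eq=np.zeros(self._Snet.shape[0]),
                        bounds=bounds, method="highs")
            b = linprog(-c, A_eq=self._Snet, b_eq=np.zeros(self._Snet.shape[0]),
                        bounds=bounds, method="highs")
            if not (a.success and b.success):
                raise InfeasibleError(
                    f"flux polytope empty or unbounded at {self.reaction_ids[i]}")
            lov[i], hiv[i] = a.x[i], b.x[i]
        return lov, hiv

    def net_fluxes(self, theta: np.ndarray) -> np.ndarray:
        return self.N @ (self.flux_scale * theta[self._iu])

    def xch_fluxes(self, theta: np.ndarray) -> np.ndarray:
        w = np.clip(theta[self._iw], 0.0, W_MAX)
        return self.xch_scale * np.tan(0.5 * np.pi * w)

    def g_values(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta[self._ig], 0.0, 1.0)

    def pool_sizes(self, theta: np.ndarray) -> Dict[str, float]:
        out = dict(self.fixed_pools)
        out.update({m: 10.0 ** c for m, c in
                    zip(self.pooled_metabolites, theta[self._ic])})
        return out

    def total_fluxes(self, theta: np.ndarray) -> FluxDistribution:
        vn = self.net_fluxes(theta)
        xch = dict(zip(self.reversible, self.xch_fluxes(theta)))
        v_net = {rid: max(v, 0.0) if not self.net.reactions[rid].reversible else v
                 for rid, v in zip(self.reaction_ids, vn)}
        return split_total_fluxes(self.net, v_net, xch)

    # -- residuals ------------------------------------------------------------

    def simulated_measurements(self, theta: np.ndarray) -> np.ndarray:
        """Model predictions stacked in measurement order."""
        v = self.total_fluxes(theta)
        g = self.g_values(theta)
        dil = {m: g[i] for m, i in self._pool_dil.items()}
        out = np.empty(self.n_residuals)
        if self.mode == "ss":
            sim = self.simulator.steady_state(v, dil)
            for m, sl in zip(self.measurements, self._meas_slices):
                y = sim[m.emu].values
                gi = self._meas_dil.get(m.emu.metabolite_id)
                if gi is not None:
                    y = g[gi] * y + (1 - g[gi]) * self._nat[m.emu]
                out[sl] = y
        else:
            pools = self.pool_sizes(theta)
            traj = self.simulator.inst(v, pools, self.timegrid, dil,
                                       n_substeps=self.inst_substeps)
            for m, sl in zip(self.measurements, self._meas_slices):
                y = traj.mdvs[m.emu][self._time_index[m.timepoint]]
                gi = self._meas_dil.get(m.emu.metabolite_id)
                if gi is not None:
                    y = g[gi] * y + (1 - g[gi]) * self._nat[m.emu]
                out[sl] = y
        vn = self.net_fluxes(theta)
        out[self._n_mdv:] = vn[self._flux_meas_idx]
        return out

    def residuals(self, theta: np.ndarray,
                  means: Optional[np.ndarray] = None) -> np.ndarray:
        y = self.simulated_measurements(theta)
        m = self.stacked_means if means is None else means
        return (y - m) / self.stacked_sd

    def objective(self, theta: np.ndarray,
                  means: Optional[np.ndarray] = None) -> float:
        try:
            r = self.residuals(theta, means)
        except (SimulationError, NetworkError):
            # graded penalty: slope back toward the feasible polytope keeps
            # line searches recoverable (a flat cliff stalls SQP steps)
            v = self.net_fluxes(theta)
            viol = float(np.sum(np.clip(self.net_lo - v, 0, None) ** 2
                                + np.clip(v - self.net_hi, 0, None) ** 2))
            return 1e8 * (1.0 + viol / self.flux_scale ** 2)
        return float(r @ r)

    def objective_gradient(self, theta: np.ndarray,
                           means: Optional[np.ndarray] = None,
                           rel_step: float = 1e-6) -> np.ndarray:
        """Forward-difference gradient with per-parameter scaled steps."""
        f0 = self.objective(theta, means)
        g = np.empty(theta.size)
        for i in range(theta.size):
            h = rel_step * max(1.0, abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            g[i] = (self.objective(tp, means) - f0) / h
        return g

    # -- constraints, bounds, starts -------------------------------------------

    def _constraints(self):
        N, lo, hi = self.N * self.flux_scale, self.net_lo, self.net_hi
        A = np.zeros((2 * N.shape[0], self.n_params))
        A[: N.shape[0], : self.n_free] = N
        A[N.shape[0]:, : self.n_free] = -N
        b = np.concatenate([-lo, hi])

        def fun(theta):
            return A @ theta + b

        def jac(theta):
            return A

        return [{"type": "ineq", "fun": fun, "jac": jac}]

    def _bounds(self):
        b: List[Tuple] = [(None, None)] * self.n_free
        b += [(0.0, W_MAX)] * len(self.reversible)
        b += [(0.0, 1.0)] * len(self.g_names)
        b += [(np.log10(v) - 1.5, np.log10(v) + 1.5)
              for v in (self.pools_init[m] for m in self.pooled_metabolites)]
        return b

    def sample_start(self, rng: np.random.Generator,
                     hr_steps: int = 50) -> np.ndarray:
        """One random initial point: net fluxes by hit-and-run inside the
        FVA box, exchange/G/pool parameters uniform in their bounds."""
        theta = np.zeros(self.n_params)
        u = self._hit_and_run_u(rng, hr_steps)
        theta[self._iu] = u / self.flux_scale
        theta[self._iw] = rng.uniform(0.0, 0.6, len(self.reversible))
        theta[self._ig] = rng.uniform(0.3, 1.0, len(self.g_names))
        theta[self._ic] = [np.log10(self.pools_init[m]) + rng.uniform(-1.0, 1.0)
                           for m in self.pooled_metabolites]
        return theta

    def _hit_and_run_u(self, rng, steps: int) -> np.ndarray:
        N, lo, hi = self.N, self.net_lo, self.net_hi
        if not hasattr(self, "_u0"):
            from .constraint import _interior_point
            x0 = _interior_point(self._Snet, lo, hi)
            self._u0 = self.N.T @ x0
        pinned = (hi - lo) < 1e-9
        if pinned.any():
            Q = null_space(N[pinned, :])
            if Q.shape[1] == 0:
                return self._u0.copy()
        else:
            Q = np.eye(self.n_free)
        u = self._u0.copy()
        for _ in range(steps):
            du = Q @ rng.standard_normal(Q.shape[1])
            d = N @ du
            nrm = np.linalg.norm(d)
            if nrm < 1e-12:
                continue
            d /= nrm
            du /= nrm
            d[np.abs(d) < 1e-12] = 0.0
            x = N @ u
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = np.where(d != 0, (lo - x) / d, -np.inf)
                t_hi = np.where(d != 0, (hi - x) / d, np.inf)
            tmin = np.max(np.minimum(t_lo, t_hi))
            tmax = np.min(np.maximum(t_lo, t_hi))
            if tmax > tmin:
                u = u + rng.uniform(tmin, tmax) * du
        return u

    # -- reported quantities -----------------------------------------------

    @property
    def report_names(self) -> List[str]:
        names = [f"net:{r}" for r in self.reaction_ids]
        names += [f"xch:{r}" for r in self.reversible]
        names += [f"G:{m}" for m in self.g_names]
        names += [f"pool:{m}" for m in self.pooled_metabolites]
        return names

    def report_values(self, theta: np.ndarray) -> np.ndarray:
        pools = [10.0 ** c for c in theta[self._ic]]
        return np.concatenate([self.net_fluxes(theta), self.xch_fluxes(theta),
                               self.g_values(theta), pools])

    def report_jacobian(self, theta: np.ndarray) -> np.ndarray:
        """d(reported quantities)/d(theta): linear null-space map for net
        fluxes, analytic transforms for exchange fluxes and pools."""
        nr = len(self.report_names)
        D = np.zeros((nr, self.n_params))
        k = 0
        D[: len(self.reaction_ids), self._iu] = self.N * self.flux_scale
        k += len(self.reaction_ids)
        w = np.clip(theta[self._iw], 0.0, W_MAX)
        dx = self.xch_scale * 0.5 * np.pi / np.cos(0.5 * np.pi * w) ** 2
        for j, _ in enumerate(self.reversible):
            D[k + j, self.n_free + j] = dx[j]
        k += len(self.reversible)
        for j, _ in enumerate(self.g_names):
            D[k + j, self.n_free + len(self.reversible) + j] = 1.0
        k += len(self.g_names)
        logc = theta[self._ic]
        for j, _ in enumerate(self.pooled_metabolites):
            D[k + j, self._ic.start + j] = np.log(10.0) * 10.0 ** logc[j]
        return D


def make_fit_problem(net: MetabolicNetwork, measurements, flux_measurements,
                     strategy: LabelingStrategy, mode: str = "ss",
                     dilution: Sequence[DilutionSpec] = (),
                     net_flux_bounds=None, pools_init=None, fixed_pools=None,
                     constants: IsotopeConstants = DEFAULT_CONSTANTS,
                     xch_scale: float = XCH_SCALE,
                     inst_substeps: int = 8) -> FitProblem:
    """Assemble a :class:`FitProblem` (see class docs for the parameter
    layout).  ``measurements`` may give EMUs as names or :class:`EMU`."""
    meas = []
    for m in measurements:
        if not isinstance(m, MDVMeasurement):
            emu, tp, mean, sd = m
            m = MDVMeasurement(emu if isinstance(emu, EMU) else parse_emu(emu),
                               tp, mean, sd)
        meas.append(m)
    fmeas = [fm if isinstance(fm, FluxMeasurement) else FluxMeasurement(*fm)
             for fm in flux_measurements]
    return FitProblem(net, meas, fmeas, strategy, mode, dilution,
                      net_flux_bounds, pools_init, fixed_pools, constants,
                      xch_scale, inst_substeps)


@dataclass
class FitResults:
    """Best fit with residual Jacobian and everything statistics need."""

    problem: FitProblem
    theta: np.ndarray
    phi: float
    residuals: np.ndarray
    jacobian: np.ndarray           # d residuals / d theta at the optimum
    converged: bool
    n_starts: int
    seed: Optional[int]

    @property
    def hessian(self) -> np.ndarray:
        """Gauss-Newton Hessian 2 JᵀJ (symmetric PSD)."""
        return 2.0 * self.jacobian.T @ self.jacobian

    @property
    def dof(self) -> int:
        return self.problem.n_residuals - self.problem.n_params

    @property
    def net_fluxes(self) -> Dict[str, float]:
        return dict(zip(self.problem.reaction_ids,
                        self.problem.net_fluxes(self.theta)))

    @property
    def exchange_fluxes(self) -> Dict[str, float]:
        return dict(zip(self.problem.reversible,
                        self.problem.xch_fluxes(self.theta)))

    @property
    def g_estimates(self) -> Dict[str, float]:
        return dict(zip(self.problem.g_names, self.problem.g_values(self.theta)))

    @property
    def pool_estimates(self) -> Dict[str, float]:
        return {m: 10.0 ** c for m, c in zip(self.problem.pooled_metabolites,
                                             self.theta[self.problem._ic])}

    @property
    def total_fluxes(self) -> FluxDistribution:
        return self.problem.total_fluxes(self.theta)

    def report(self) -> pd.DataFrame:
        names = self.problem.report_names
        vals = self.problem.report_values(self.theta)
        kinds = [n.split(":")[0] for n in names]
        ids = [n.split(":", 1)[1] for n in names]
        return pd.DataFrame({"kind": kinds, "id": ids, "estimate": vals},
                            index=names)

    def normalized_net_fluxes(self, reference_reaction: str,
                              scale: float = 100.0) -> Dict[str, float]:
        ref = self.net_fluxes[reference_reaction]
        if ref == 0:
            raise EstimationError("reference flux is zero")
        return {r: v * scale / ref for r, v in self.net_fluxes.items()}

    def compare_measurements(self) -> pd.DataFrame:
        sim = self.problem.simulated_measurements(self.theta)
        return pd.DataFrame({
            "measurement": self.problem.residual_labels,
            "measured": self.problem.stacked_means,
            "simulated": sim,
            "sd": self.problem.stacked_sd,
            "weighted_residual": self.residuals,
        })


def _fd_jacobian(problem: FitProblem, theta: np.ndarray,
                 means: Optional[np.ndarray] = None,
                 rel_step: float = 1e-6) -> np.ndarray:
    """Forward finite-difference Jacobian of the weighted residuals."""
    r0 = problem.residuals(theta, means)
    J = np.empty((r0.size, theta.size))
    for i in range(theta.size):
        h = rel_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        J[:, i] = (problem.residuals(tp, means) - r0) / h
    return J


_LOG_EPS = 1e-15


def _minimize_once(problem: FitProblem, x0: np.ndarray,
                   means: Optional[np.ndarray], tol: float, max_iter: int):
    """One SLSQP descent on log(Phi).

    The log transform makes the objective self-scaling (raw Phi spans ~10
    orders of magnitude between a random start and a noise-free optimum,
    which stalls SQP line searches), and it turns ``ftol`` into a tolerance
    on the *relative* change of Phi.
    """
    def fun(th):
        return np.log(problem.objective(th, means) + _LOG_EPS)

    def jac(th):
        f0 = problem.objective(th, means)
        return problem.objective_gradient(th, means) / (f0 + _LOG_EPS)

    res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=problem._bounds(),
                   constraints=problem._constraints(),
                   options={"maxiter": max_iter, "ftol": tol})
    res.fun = problem.objective(res.x, means)
    return res


def solve(problem: FitProblem, n_starts: int = 10, seed: Optional[int] = None,
          tol: float = 1e-9, max_iter: int = 500,
          x0: Optional[np.ndarray] = None,
          means: Optional[np.ndarray] = None) -> FitResults:
    """Best-of-n-starts weighted least-squares fit (steady state).

    Initial points are drawn from the FVA-bounded flux polytope; pass
    ``x0`` to warm-start (it is used as the first start).
    """
    if problem.mode != "ss":
        raise EstimationError("use solve_inst for nonstationary problems")
    return _solve_impl(problem, n_starts, seed, tol, max_iter, x0, means)


def solve_inst(problem: FitProblem, n_starts: int = 5,
               seed: Optional[int] = None, tol: float = 1e-9,
               max_iter: int = 500, x0: Optional[np.ndarray] = None,
               means: Optional[np.ndarray] = None) -> FitResults:
    """Fluxes and pool sizes from time-course MDVs (nonstationary state).

    Identical contract to :func:`solve`; every objective evaluation
    integrates the labeling ODEs on the measurement time grid.
    """
    if problem.mode != "inst":
        raise EstimationError("problem is not in inst mode")
    n_times = len({m.timepoint for m in problem.measurements})
    if n_times < 2:
        warnings.warn("fewer than 2 timepoints: pool sizes are likely "
                      "unidentifiable", stacklevel=2)
    return _solve_impl(problem, n_starts, seed, tol, max_iter, x0, means)


def _solve_impl(problem, n_starts, seed, tol, max_iter, x0, means) -> FitResults:
    rng = np.random.default_rng(seed)
    starts: List[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    while len(starts) < n_starts:
        starts.append(problem.sample_start(rng))
    best = None
    n_failed = 0
    for s in starts:
        try:
            res = _minimize_once(problem, s, means, tol, max_iter)
        except (SimulationError, NetworkError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise EstimationError(f"all {len(starts)} starts failed")
    J = _fd_jacobian(problem, best.x, means)
    return FitResults(problem=problem, theta=np.asarray(best.x),
                      phi=float(best.fun),
                      residuals=problem.residuals(best.x, means),
                      jacobian=J, converged=bool(best.success),
                      n_starts=len(starts), seed=seed)


@dataclass
class MonteCarloResults:
    """Empirical parameter distribution from noise-perturbed refits."""

    names: List[str]
    samples: np.ndarray            # (n_ok, n_quantities)
    alpha: float
    n_runs: int
    n_failed: int
    seed: Optional[int]
    base: FitResults

    def ci(self) -> pd.DataFrame:
        lo = np.quantile(self.samples, self.alpha / 2, axis=0)
        hi = np.quantile(self.samples, 1 - self.alpha / 2, axis=0)
        est = self.base.problem.report_values(self.base.theta)
        return pd.DataFrame({"estimate": est, "ci_lo": lo, "ci_hi": hi,
                             "mc_mean": self.samples.mean(axis=0),
                             "mc_sd": self.samples.std(axis=0, ddof=1)},
                            index=self.names)


def _mc_run(problem: FitProblem, base_theta: np.ndarray, means: np.ndarray,
            tol: float, max_iter: int) -> Optional[np.ndarray]:
    try:
        res = _minimize_once(problem, base_theta, means, tol, max_iter)
        if not np.isfinite(res.fun):
            return None
        return problem.report_values(res.x)
    except (SimulationError, NetworkError, np.linalg.LinAlgError):
        return None


def solve_with_confidence_intervals(problem: FitProblem, n_runs: int = 100,
                                    n_jobs: int = 1, seed: Optional[int] = None,
                                    alpha: float = 0.05,
                                    base: Optional[FitResults] = None,
                                    n_starts: int = 10, tol: float = 1e-9,
                                    max_iter: int = 500) -> MonteCarloResults:
    """Monte-Carlo confidence intervals.

    ``n_runs`` refits of the problem with every measurement entry perturbed
    by Gaussian noise at its declared sd, each warm-started from the base
    estimate; CIs are the empirical [alpha/2, 1-alpha/2] quantiles.  More
    than 20% failed runs raises.  Fully reproducible under ``seed``; runs
    are parallelized with joblib when ``n_jobs > 1``.
    """
    rng = np.random.default_rng(seed)
    if base is None:
        solver = solve if problem.mode == "ss" else solve_inst
        base = solver(problem, n_starts=n_starts,
                      seed=int(rng.integers(2 ** 31 - 1)), tol=tol,
                      max_iter=max_iter)
    perturbed = [problem.stacked_means
                 + rng.standard_normal(problem.n_residuals) * problem.stacked_sd
                 for _ in range(n_runs)]
    if n_jobs > 1:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_mc_run)(problem, base.theta, m, tol, max_iter)
            for m in perturbed)
    else:
        results = [_mc_run(problem, base.theta, m, tol, max_iter)
                   for m in perturbed]
    ok = [r for r in results if r is not None]
    n_failed = n_runs - len(ok)
    if n_failed > 0.2 * n_runs:
        raise EstimationError(
            f"{n_failed}/{n_runs} Monte-Carlo runs failed; the problem is "
            "likely ill-posed at the fitted optimum")
    return MonteCarloResults(names=problem.report_names,
                             samples=np.vstack(ok), alpha=alpha,
                             n_runs=n_runs, n_failed=n_failed, seed=seed,
                             base=base)
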