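"""Linear-programming layer over the total-flux space.

Flux balance analysis (FBA) optimizes a linear objective subject to
S·v = 0 and box bounds; flux variability analysis (FVA) reports each total
flux's attainable range while holding the objective at a fraction gamma of
its optimum.  The FVA box is what flux estimation samples its initial
guesses from.  ``sample_feasible_fluxes`` draws (asymptotically) uniform
points from the flux polytope with a coordinate hit-and-run walk on the
null-space parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .network import FluxDistribution, MetabolicNetwork

__all__ = ["FluxBounds", "FBAResults", "FVAResults", "fba", "fva",
           "sample_feasible_fluxes", "InfeasibleError"]

DEFAULT_UB = 1000.0  # default cap on every total flux, normalized units


class InfeasibleError(RuntimeError):
    """The flux polytope is empty (or the objective unbounded)."""


@dataclass
class FluxBounds:
    """Per total-flux (lb, ub) bounds; fluxes not listed get [0, 1000]."""

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    default: Tuple[float, float] = (0.0, DEFAULT_UB)

    def __post_init__(self):
        for fid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise InfeasibleError(f"{fid}: lb {lb} > ub {ub}")

    def get(self, flux_id: str) -> Tuple[float, float]:
        return self.bounds.get(flux_id, self.default)

    def set(self, flux_id: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise InfeasibleError(f"{flux_id}: lb {lb} > ub {ub}")
        self.bounds[flux_id] = (float(lb), float(ub))

    def as_arrays(self, order) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.get(f)[0] for f in order])
        ub = np.array([self.get(f)[1] for f in order])
        return lb, ub


@dataclass
class FBAResults:
    objective_id: str
    sense: str
    objective_value: float
    fluxes: FluxDistribution


@dataclass
class FVAResults:
    gamma: float
    ranges: Dict[str, Tuple[float, float]]

    def __getitem__(self, flux_id):
        return self.ranges[flux_id]

    def box(self, order) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.ranges[f][0] for f in order])
        hi = np.array([self.ranges[f][1] for f in order])
        return lo, hi


def _objective_vector(net: MetabolicNetwork, objective: str,
                      flux_ids: List[str]) -> np.ndarray:
    c = np.zeros(len(flux_ids))
    idx = {f: i for i, f in enumerate(flux_ids)}
    if objective in idx:
        c[idx[objective]] = 1.0
    elif objective + "_f" in idx:  # net flux of a reversible reaction
        c[idx[objective + "_f"]] = 1.0
        c[idx[objective + "_b"]] = -1.0
    else:
        raise KeyError(f"unknown objective flux {objective!r}")
    return c


def _solve_lp(S, c, lb, ub, A_ub=None, b_ub=None):
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  A_ub=A_ub, b_ub=b_ub,
                  bounds=list(zip(lb, ub)), method="highs")
    return res


def fba(net: MetabolicNetwork, bounds: Optional[FluxBounds] = None,
        objective: str = "", sense: str = "max") -> FBAResults:
    """LP optimum of one flux subject to S·v = 0 and bounds.

    Degenerate optima are broken deterministically by a tiny secondary
    objective with lexicographic flux-order weights.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    bounds = bounds or FluxBounds()
    flux_ids = net.total_flux_ids
    S = net.stoichiometric_matrix().to_numpy()
    lb, ub = bounds.as_arrays(flux_ids)
    c = _objective_vector(net, objective, flux_ids)
    sign = -1.0 if sense == "max" else 1.0
    # lexicographic tie-break: minuscule penalty increasing along flux order
    tie = 1e-9 * (1.0 + np.arange(len(flux_ids))) / len(flux_ids)
    res = _solve_lp(S, sign * c + tie, lb, ub)
    if res.status == 3:
        raise InfeasibleError(f"FBA objective {objective} is unbounded")
    if not res.success:
        raise InfeasibleError(f"FBA infeasible: {res.message}")
    v = FluxDistribution(dict(zip(flux_ids, np.clip(res.x, 0.0, None))))
    return FBAResults(objective, sense, float(c @ res.x), v)


def fva(net: MetabolicNetwork, bounds: Optional[FluxBounds] = None,
        objective: Optional[str] = None, gamma: float = 0.0,
        sense: str = "max") -> FVAResults:
    """Attainable [min, max] of every total flux.

    With an objective and gamma > 0, the constraint ``objective >=
    gamma * FBA optimum`` (maximization; reversed for minimization) is
    added; gamma = 0 is plain feasibility analysis of the polytope.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    bounds = bounds or FluxBounds()
    flux_ids = net.total_flux_ids
    S = net.stoichiometric_matrix().to_numpy()
    lb, ub = bounds.as_arrays(flux_ids)
    A_ub = b_ub = None
    if objective is not None and gamma > 0.0:
        opt = fba(net, bounds, objective, sense)
        c_obj = _objective_vector(net, objective, flux_ids)
        if sense == "max":
            A_ub = -c_obj[None, :]
            b_ub = np.array([-gamma * opt.objective_value])
        else:
            A_ub = c_obj[None, :]
            b_ub = np.array([gamma * opt.objective_value
                             if opt.objective_value >= 0
                             else opt.objective_value / gamma])
    ranges = {}
    for i, fid in enumerate(flux_ids):
        c = np.zeros(len(flux_ids))
        c[i] = 1.0
        lo = _solve_lp(S, c, lb, ub, A_ub, b_ub)
        hi = _solve_lp(S, -c, lb, ub, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise InfeasibleError(
                f"FVA infeasible for {fid}: {lo.message or hi.message}")
        vmin, vmax = float(lo.x[i]), float(hi.x[i])
        if vmin > vmax:  # solver round-off on pinned fluxes
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[fid] = (vmin, vmax)
    return FVAResults(gamma, ranges)


def _interior_point(S, lb, ub) -> np.ndarray:
    """Chebyshev-style interior point: maximize the minimum slack to the
    box faces subject to S·v = 0.  Coordinates pinned by equal bounds are
    excluded from the slack (their slack is identically zero and would
    degenerate the LP to an arbitrary vertex)."""
    n = len(lb)
    free = (ub - lb) > 1e-9
    # variables [v, t]; maximize t with lb_i + t <= v_i <= ub_i - t (free i)
    c = np.zeros(n + 1)
    c[-1] = -1.0
    rows = []
    rhs = []
    for i in range(n):
        if not free[i]:
            continue
        row = np.zeros(n + 1)
        row[i] = -1.0
        row[-1] = 1.0
        rows.append(row)
        rhs.append(-lb[i])
        row = np.zeros(n + 1)
        row[i] = 1.0
        row[-1] = 1.0
        rows.append(row)
        rhs.append(ub[i])
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    tmax = 0.5 * float((ub[free] - lb[free]).min()) if free.any() else 0.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(S.shape[0]),
                  bounds=[(lo, hi) for lo, hi in zip(lb, ub)] + [(0, tmax)],
                  method="highs")
    if not res.success:
        raise InfeasibleError(f"no feasible flux vector: {res.message}")
    return res.x[:n]


def sample_feasible_fluxes(net: MetabolicNetwork,
                           bounds: Optional[FluxBounds] = None,
                           n: int = 1, seed: Optional[int] = None,
                           burn_in: int = 1000, thinning: int = 10
                           ) -> List[FluxDistribution]:
    """Hit-and-run samples from {v : S·v = 0, lb <= v <= ub}.

    The walk moves along random directions of the null space of S, so every
    iterate satisfies the balances exactly; bounds constrain the chord.
    Burn-in 1000 and thinning 10 by default; reproducible under ``seed``.
    """
    bounds = bounds or FluxBounds()
    flux_ids = net.total_flux_ids
    S = net.stoichiometric_matrix().to_numpy()
    lb, ub = bounds.as_arrays(flux_ids)
    if np.any(~np.isfinite(ub)):
        raise InfeasibleError("unbounded directions: cap all fluxes before sampling")
    # directions must not move coordinates pinned by equal bounds
    pinned = (ub - lb) < 1e-9
    A = S if S.size else np.zeros((0, len(flux_ids)))
    if pinned.any():
        A = np.vstack([A, np.eye(len(flux_ids))[pinned]])
    N = null_space(A) if A.size else np.eye(len(flux_ids))
    if N.shape[1] == 0:
        x = _interior_point(S, lb, ub)
        return [FluxDistribution(dict(zip(flux_ids, x)))] * n
    rng = np.random.default_rng(seed)
    x = _interior_point(S, lb, ub)
    samples: List[FluxDistribution] = []
    steps = burn_in + n * thinning
    for k in range(steps):
        d = N @ rng.standard_normal(N.shape[1])
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        d[np.abs(d) < 1e-12] = 0.0  # null-space round-off on pinned coords
        # chord limits from lb <= x + t d <= ub
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = np.where(d != 0, (lb - x) / d, -np.inf)
            t_hi = np.where(d != 0, (ub - x) / d, np.inf)
        tmin = np.max(np.minimum(t_lo, t_hi))
        tmax = np.min(np.maximum(t_lo, t_hi))
        if tmax <= tmin:
            continue
        x = x + rng.uniform(tmin, tmax) * d
        x = np.clip(x, lb, ub)
        if k >= burn_in and (k - burn_in) % thinning == thinning - 1:
            samples.append(FluxDistribution(dict(zip(flux_ids, x))))
    while len(samples) < n:  # pathological rejections; keep contract
        samples.append(FluxDistribution(dict(zip(flux_ids, x))))
    return samples[:n]
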