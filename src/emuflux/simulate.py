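"""Forward labeling simulation on decomposed EMU networks.

Steady state: for each EMU size n in ascending order the balances are
linear, ``A·X = -B·Y``, where X stacks the MDVs of the internal EMUs of
size n and Y stacks the source MDVs (substrate EMUs and convolutions of
already-solved smaller EMUs).  A accumulates the total influx of each EMU
on its diagonal (equal to its consumption when S·v = 0) and flux-weighted
internal links off-diagonal; B accumulates flux weights of sources.

Isotopically nonstationary (INST) state: with metabolite pool sizes c the
same structure becomes a linear ODE per size,

    diag(c) · dX/dt = A·X + B·Y(t),   X(0) = natural MDVs,

whose inhomogeneity Y(t) is time-varying for sizes > 1 (convolutions of
smaller-size trajectories).  Each internal step is advanced with the exact
solution of the system under a linearly interpolated inhomogeneity — the
noncausal first-order-hold equivalent discretization — using cached matrix
exponentials of the augmented system, since A is time-invariant.

Labeled pools that exchange with metabolically inactive (unlabeled)
material can be declared diluted with a G-value: every appearance of such a
pool as a labeling *source* is replaced by the mixture
``G·(pool MDV) + (1-G)·(natural MDV)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .emu import EMU, EMUNetwork, decompose_network, parse_emu
from .labeling import LabelingStrategy
from .mdv import DEFAULT_CONSTANTS, MDV, IsotopeConstants, get_natural_MDV
from .network import FluxDistribution, MetabolicNetwork, NetworkError

__all__ = ["EMUSimulator", "Trajectory", "simulate_steady_state", "simulate_inst",
           "SimulationError"]


class SimulationError(RuntimeError):
    pass


# source keys: a substrate EMU, ("nat", size), or ("conv", elements) where
# each element is an EMU or ("nat", size)
SourceKey = Union[EMU, tuple]


def _source_key_name(key) -> str:
    if isinstance(key, EMU):
        return key.name
    kind = key[0]
    if kind == "nat":
        return f"<natural:{key[1]}>"
    return " * ".join(_source_key_name(e) for e in key[1])


@dataclass
class _Stamp:
    """One flux-weighted entry accumulated into a balance matrix."""
    row: int
    col: int
    flux_idx: int
    coef: float
    # multiplicative dilution factors: (dilution index, use 1-G instead of G)
    factors: Tuple[Tuple[int, bool], ...] = ()


class _SizeSystem:
    """Precomputed index structure of the size-n EMU balance."""

    def __init__(self, size: int, net: MetabolicNetwork, emunet: EMUNetwork,
                 flux_index: Mapping[str, int], diluted: Sequence[str]):
        self.size = size
        internal = emunet.internal_emus[size]
        self.dynamic: List[EMU] = [e for e in internal
                                   if net.metabolites[e.metabolite_id].is_balanced]
        self.outputs: List[EMU] = [e for e in internal
                                   if not net.metabolites[e.metabolite_id].is_balanced]
        dyn_idx = {e: i for i, e in enumerate(self.dynamic)}
        out_idx = {e: i for i, e in enumerate(self.outputs)}
        dil_idx = {m: i for i, m in enumerate(diluted)}

        self.source_keys: List[SourceKey] = []
        self._source_index: Dict = {}

        # plain (undiluted) stamps as parallel arrays, one set per matrix
        self._stamps: Dict[str, List[_Stamp]] = {
            "A": [], "B": [], "P": [], "Q": [], "dA": [], "dO": []}

        for r in emunet.by_size[size]:
            is_out = r.target in out_idx
            row = out_idx[r.target] if is_out else dyn_idx[r.target]
            fi = flux_index[r.flux_id]
            # diagonal: total influx of the target EMU
            self._stamps["dO" if is_out else "dA"].append(
                _Stamp(row, row, fi, r.coefficient))
            for key, factors in self._expand_source(r.sources, net, dil_idx):
                if isinstance(key, EMU) and key in dyn_idx:
                    mat = "P" if is_out else "A"
                    col = dyn_idx[key]
                else:
                    mat = "Q" if is_out else "B"
                    col = self._source_col(key)
                self._stamps[mat].append(
                    _Stamp(row, col, fi, r.coefficient, factors))

        self.n_dyn = len(self.dynamic)
        self.n_out = len(self.outputs)
        self.n_src = len(self.source_keys)
        self._arrays = {m: self._to_arrays(st) for m, st in self._stamps.items()}

    def _source_col(self, key) -> int:
        if key not in self._source_index:
            self._source_index[key] = len(self.source_keys)
            self.source_keys.append(key)
        return self._source_index[key]

    def _expand_source(self, sources: Tuple[EMU, ...], net, dil_idx):
        """Yield (key, dilution factors) pairs for one EMU reaction's source.

        A diluted pool appearing as a source splits into a G-weighted link to
        the pool plus a (1-G)-weighted link to a natural MDV; inside a
        convolution every diluted constituent doubles the variants.
        """
        def variants(emu: EMU):
            d = dil_idx.get(emu.metabolite_id)
            if d is None:
                yield emu, ()
            else:
                yield emu, ((d, False),)
                yield ("nat", emu.size), ((d, True),)

        if len(sources) == 1:
            yield from variants(sources[0])
            return
        combos = [((), ())]
        for s in sources:
            combos = [(elems + (e,), facs + f)
                      for elems, facs in combos for e, f in variants(s)]
        for elems, facs in combos:
            yield ("conv", elems), facs

    @staticmethod
    def _to_arrays(stamps: List[_Stamp]):
        plain = [s for s in stamps if not s.factors]
        dil = [s for s in stamps if s.factors]
        arr = (np.array([s.row for s in plain], dtype=np.intp),
               np.array([s.col for s in plain], dtype=np.intp),
               np.array([s.flux_idx for s in plain], dtype=np.intp),
               np.array([s.coef for s in plain], dtype=float))
        return arr, dil

    def assemble(self, v: np.ndarray, g: np.ndarray):
        """Numeric matrices for flux vector v and G-value vector g.

        Returns (A, B, P, Q, out_influx) with the influx diagonal already
        subtracted inside A.
        """
        A = np.zeros((self.n_dyn, self.n_dyn))
        B = np.zeros((self.n_dyn, self.n_src))
        P = np.zeros((self.n_out, self.n_dyn))
        Q = np.zeros((self.n_out, self.n_src))
        out_influx = np.zeros(self.n_out)
        for name, M in (("A", A), ("B", B), ("P", P), ("Q", Q)):
            (rows, cols, fidx, coef), dil = self._arrays[name]
            if rows.size:
                np.add.at(M, (rows, cols), coef * v[fidx])
            for s in dil:
                w = s.coef * v[s.flux_idx]
                for d, comp in s.factors:
                    w *= (1.0 - g[d]) if comp else g[d]
                M[s.row, s.col] += w
        (rows, _, fidx, coef), _ = self._arrays["dA"]
        if rows.size:
            diag = np.zeros(self.n_dyn)
            np.add.at(diag, rows, coef * v[fidx])
            if np.any(diag <= 1e-12):
                bad = [self.dynamic[i].name for i in np.where(diag <= 1e-12)[0]]
                raise SimulationError(
                    f"zero total flux through EMU(s) {bad}: singular balance")
            A[np.arange(self.n_dyn), np.arange(self.n_dyn)] -= diag
        (rows, _, fidx, coef), _ = self._arrays["dO"]
        if rows.size:
            np.add.at(out_influx, rows, coef * v[fidx])
            if np.any(out_influx <= 1e-12):
                bad = [self.outputs[i].name for i in np.where(out_influx <= 1e-12)[0]]
                raise SimulationError(
                    f"zero total influx to excreted EMU(s) {bad}")
        return A, B, P, Q, out_influx


@dataclass
class Trajectory:
    """Time course of MDVs on an output time grid (t[0] = 0)."""

    timegrid: np.ndarray
    mdvs: Dict[EMU, np.ndarray]  # (len(timegrid), size+1) per EMU

    def at(self, emu: Union[EMU, str], t: float) -> MDV:
        emu = emu if isinstance(emu, EMU) else parse_emu(emu)
        i = int(np.argmin(np.abs(self.timegrid - t)))
        if abs(self.timegrid[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(f"t={t} not on the trajectory grid")
        return MDV(self.mdvs[emu][i])

    def endpoint(self, emu: Union[EMU, str]) -> MDV:
        emu = emu if isinstance(emu, EMU) else parse_emu(emu)
        return MDV(self.mdvs[emu][-1])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: emu_id, t, M0...Mn."""
        rows = []
        for emu, arr in self.mdvs.items():
            for k, t in enumerate(self.timegrid):
                row = {"emu_id": emu.name, "t": t}
                row.update({f"M{i}": arr[k, i] for i in range(arr.shape[1])})
                rows.append(row)
        return pd.DataFrame(rows)


class EMUSimulator:
    """Reusable simulator bound to one decomposition.

    Constructing the simulator precomputes the per-size index structures so
    repeated evaluation at different flux vectors (the inner loop of flux
    estimation) only assembles small numeric matrices and solves them.
    """

    def __init__(self, net: MetabolicNetwork, strategy: LabelingStrategy,
                 targets: Sequence, constants: IsotopeConstants = DEFAULT_CONSTANTS,
                 diluted_pools: Sequence[str] = (), emunet: Optional[EMUNetwork] = None):
        strategy.validate_against(net)
        self.net = net
        self.strategy = strategy
        self.constants = constants
        self.diluted_pools = list(diluted_pools)
        self.targets = [t if isinstance(t, EMU) else parse_emu(str(t))
                        for t in targets]
        self.emunet = emunet or decompose_network(net, self.targets)
        self.flux_ids = net.total_flux_ids
        self._flux_index = {f: i for i, f in enumerate(self.flux_ids)}
        self._systems = [
            _SizeSystem(s, net, self.emunet, self._flux_index, self.diluted_pools)
            for s in self.emunet.sizes
        ]
        self._substrate_cache: Dict[EMU, np.ndarray] = {}
        self._natural_cache: Dict[int, np.ndarray] = {}
        # EMU balances assume flux balance (influx = outflux); S for checking
        self._S = net.stoichiometric_matrix().to_numpy()

    # -- helpers -----------------------------------------------------------

    def _flux_array(self, v) -> np.ndarray:
        if isinstance(v, FluxDistribution) or hasattr(v, "as_array"):
            arr = v.as_array(self.flux_ids)
        else:
            arr = np.array([v[f] for f in self.flux_ids], dtype=float)
        if np.any(arr < -1e-9):
            raise SimulationError("negative total flux")
        resid = np.abs(self._S @ arr).max() if self._S.size else 0.0
        scale = max(1.0, np.abs(arr).max())
        if resid > 1e-6 * scale:
            raise SimulationError(
                f"flux vector violates S·v = 0 (residual {resid:.3g}); EMU "
                "balances require a mass-balanced flux distribution")
        return np.clip(arr, 0.0, None)

    def _g_array(self, dilution: Optional[Mapping[str, float]]) -> np.ndarray:
        g = np.ones(len(self.diluted_pools))
        for i, met in enumerate(self.diluted_pools):
            if dilution and met in dilution:
                g[i] = float(dilution[met])
                if not (0.0 <= g[i] <= 1.0):
                    raise SimulationError(f"G-value of {met} not in [0,1]")
        return g

    def _natural(self, n: int) -> np.ndarray:
        if n not in self._natural_cache:
            self._natural_cache[n] = get_natural_MDV(n, self.constants).values
        return self._natural_cache[n]

    def _substrate(self, emu: EMU) -> np.ndarray:
        if emu not in self._substrate_cache:
            self._substrate_cache[emu] = self.strategy.substrate_mdv(
                emu, self.constants).values
        return self._substrate_cache[emu]

    def _source_value(self, key, solved: Dict[EMU, np.ndarray]) -> np.ndarray:
        if isinstance(key, EMU):
            if self.net.metabolites[key.metabolite_id].is_substrate:
                return self._substrate(key)
            return solved[key]
        if key[0] == "nat":
            return self._natural(key[1])
        out = np.array([1.0])
        for e in key[1]:
            out = np.convolve(out, self._source_value(e, solved))
        return out

    # -- steady state -------------------------------------------------------

    def steady_state(self, v, dilution: Optional[Mapping[str, float]] = None
                     ) -> Dict[EMU, MDV]:
        """Solve the cascaded EMU balances; returns MDVs of the target EMUs."""
        varr = self._flux_array(v)
        g = self._g_array(dilution)
        solved: Dict[EMU, np.ndarray] = {}
        for sys in self._systems:
            A, B, P, Q, out_influx = sys.assemble(varr, g)
            Y = np.array([self._source_value(k, solved) for k in sys.source_keys]) \
                if sys.n_src else np.zeros((0, sys.size + 1))
            if sys.n_dyn:
                try:
                    X = np.linalg.solve(A, -B @ Y)
                except np.linalg.LinAlgError as exc:
                    raise SimulationError(
                        f"singular size-{sys.size} EMU balance: {exc}") from exc
                for i, emu in enumerate(sys.dynamic):
                    solved[emu] = X[i]
            else:
                X = np.zeros((0, sys.size + 1))
            if sys.n_out:
                Xout = (P @ X + Q @ Y) / out_influx[:, None]
                for i, emu in enumerate(sys.outputs):
                    solved[emu] = Xout[i]
        out = {}
        for t in self.targets:
            m = solved.get(t)
            if m is None:  # target on a substrate metabolite
                m = self._substrate(t)
            out[t] = MDV(np.clip(m, 0.0, None))
        return out

    # -- INST ---------------------------------------------------------------

    def _internal_grid(self, timegrid: np.ndarray, varr: np.ndarray,
                       pools: Mapping[str, float], refine: int,
                       n_substeps: Optional[int] = None) -> tuple:
        """Uniform-per-interval internal grid; returns (grid, indices of
        output times).

        By default the step is bounded by min pool turnover time / (5 *
        2^refine).  With ``n_substeps`` every output interval is split into
        a fixed number of substeps (* 2^refine) independent of pools and
        fluxes — flux estimation uses this so the objective stays smooth in
        the parameters.
        """
        if n_substeps is None:
            taus = []
            for sys in self._systems:
                for emu in sys.dynamic:
                    met = emu.metabolite_id
                    c = float(pools[met])
                    outflux = sum(w * varr[self._flux_index[f]]
                                  for f, w in self.net.consumption_weights(met))
                    if outflux > 0:
                        taus.append(c / outflux)
            if not taus:
                raise SimulationError("no dynamic EMUs to integrate")
            # tau/20 keeps the first-order-hold error ~1e-7 even when
            # convolution sources vary rapidly (multi-position tracers)
            dt_max = min(taus) / (20.0 * 2 ** refine)
        else:
            dt_max = None
        grid = [0.0]
        out_idx = [0]
        for t0, t1 in zip(timegrid[:-1], timegrid[1:]):
            if dt_max is not None:
                nsub = max(1, int(np.ceil((t1 - t0) / dt_max)))
            else:
                nsub = n_substeps * 2 ** refine
            for j in range(1, nsub + 1):
                grid.append(t0 + (t1 - t0) * j / nsub)
            out_idx.append(len(grid) - 1)
        return np.array(grid), np.array(out_idx, dtype=np.intp)

    def inst(self, v, pools: Mapping[str, float], timegrid: Sequence[float],
             dilution: Optional[Mapping[str, float]] = None,
             dt_factor_refinements: int = 6,
             n_substeps: Optional[int] = None) -> Trajectory:
        """Integrate the EMU labeling ODEs; returns target MDV trajectories.

        The output grid must start at 0 and be strictly increasing; the
        initial condition is natural abundance (cells grown on unlabeled
        substrate until the tracer switch at t = 0).
        """
        timegrid = np.asarray(list(timegrid), dtype=float)
        if timegrid[0] != 0.0 or np.any(np.diff(timegrid) <= 0):
            raise SimulationError("timegrid must start at 0 and be increasing")
        varr = self._flux_array(v)
        g = self._g_array(dilution)
        for sys in self._systems:
            for emu in sys.dynamic:
                c = pools.get(emu.metabolite_id)
                if c is None or c <= 0:
                    raise SimulationError(
                        f"positive pool size required for {emu.metabolite_id}")

        for refine in range(dt_factor_refinements + 1):
            grid, out_idx = self._internal_grid(timegrid, varr, pools, refine,
                                                n_substeps)
            try:
                traj = self._integrate(varr, g, pools, grid)
            except _NormalizationDrift:
                continue
            return Trajectory(
                timegrid=timegrid,
                mdvs={t: traj[t][out_idx] for t in self.targets})
        raise SimulationError(
            "normalization drift persisted after maximum grid refinement")

    def _integrate(self, varr, g, pools, grid) -> Dict[EMU, np.ndarray]:
        nt = grid.size
        traj: Dict[EMU, np.ndarray] = {}

        def source_grid(key) -> np.ndarray:
            # (nt, n+1) time course of one source row
            if isinstance(key, EMU):
                if self.net.metabolites[key.metabolite_id].is_substrate:
                    return np.broadcast_to(self._substrate(key),
                                           (nt, key.size + 1))
                return traj[key]
            if key[0] == "nat":
                return np.broadcast_to(self._natural(key[1]), (nt, key[1] + 1))
            parts = [source_grid(e) for e in key[1]]
            out = parts[0]
            for p in parts[1:]:
                conv = np.zeros((nt, out.shape[1] + p.shape[1] - 1))
                for i in range(out.shape[1]):
                    conv[:, i:i + p.shape[1]] += out[:, i:i + 1] * p
                out = conv
            return out

        for sys in self._systems:
            A, B, P, Q, out_influx = sys.assemble(varr, g)
            n1 = sys.size + 1
            Ys = (np.stack([source_grid(k) for k in sys.source_keys], axis=1)
                  if sys.n_src else np.zeros((nt, 0, n1)))
            if sys.n_dyn:
                c = np.array([pools[e.metabolite_id] for e in sys.dynamic])
                M = A / c[:, None]
                Bc = B / c[:, None]
                X = np.empty((nt, sys.n_dyn, n1))
                X[0] = np.broadcast_to(self._natural(sys.size),
                                       (sys.n_dyn, n1)).copy()
                G = Bc @ Ys if sys.n_src else np.zeros((nt, sys.n_dyn, n1))
                cache: Dict[float, tuple] = {}
                nd = sys.n_dyn
                for k in range(nt - 1):
                    h = grid[k + 1] - grid[k]
                    key = round(float(h), 15)
                    if key not in cache:
                        Z = np.zeros((3 * nd, 3 * nd))
                        Z[:nd, :nd] = M
                        Z[:nd, nd:2 * nd] = np.eye(nd)
                        Z[nd:2 * nd, 2 * nd:] = np.eye(nd)
                        E = expm(Z * h)
                        cache[key] = (E[:nd, :nd], E[:nd, nd:2 * nd],
                                      E[:nd, 2 * nd:])
                    Ad, F1, P2 = cache[key]
                    dk = (G[k + 1] - G[k]) / h
                    X[k + 1] = Ad @ X[k] + F1 @ G[k] + P2 @ dk
                drift = np.abs(X.sum(axis=2) - 1.0).max()
                if drift > 1e-6:
                    raise _NormalizationDrift(drift)
                for i, emu in enumerate(sys.dynamic):
                    traj[emu] = X[:, i, :]
            else:
                X = np.zeros((nt, 0, n1))
            if sys.n_out:
                Xout = (np.einsum("od,tdm->tom", P, X)
                        + np.einsum("os,tsm->tom", Q, Ys)) / out_influx[None, :, None]
                for i, emu in enumerate(sys.outputs):
                    traj[emu] = Xout[:, i, :]
        for t in self.targets:
            if t not in traj:  # substrate target: constant at its tracer MDV
                traj[t] = np.broadcast_to(self._substrate(t), (nt, t.size + 1))
        return traj


class _NormalizationDrift(Exception):
    def __init__(self, drift):
        super().__init__(f"normalization drift {drift:.3g}")
        self.drift = drift


def simulate_steady_state(net: MetabolicNetwork, v, strategy: LabelingStrategy,
                          targets: Sequence,
                          constants: IsotopeConstants = DEFAULT_CONSTANTS,
                          dilution: Optional[Mapping[str, float]] = None,
                          emunet: Optional[EMUNetwork] = None) -> Dict[EMU, MDV]:
    """MDVs of the target EMUs at isotopic steady state.

    ``dilution`` maps metabolite ids to G-values (the labeled fraction of
    the pool); omitted pools are fully labeled.
    """
    diluted = sorted(dilution) if dilution else ()
    sim = EMUSimulator(net, strategy, targets, constants, diluted, emunet)
    return sim.steady_state(v, dilution)


def simulate_inst(net: MetabolicNetwork, v, pools: Mapping[str, float],
                  strategy: LabelingStrategy, targets: Sequence,
                  timegrid: Sequence[float],
                  constants: IsotopeConstants = DEFAULT_CONSTANTS,
                  dilution: Optional[Mapping[str, float]] = None,
                  emunet: Optional[EMUNetwork] = None) -> Trajectory:
    """Transient MDV trajectories of the target EMUs (INST state)."""
    diluted = sorted(dilution) if dilution else ()
    sim = EMUSimulator(net, strategy, targets, constants, diluted, emunet)
    return sim.inst(v, pools, timegrid, dilution)
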