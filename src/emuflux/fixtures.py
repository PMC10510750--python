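"""Self-contained test-data layer.

This module is first-class, tested code: it provides small atom-mapped
networks whose EMU structure exercises every code path (cleavage,
condensation, reversibility, flux-dependent labeling), an exhaustive
isotopomer simulator that serves as an independent oracle for the EMU
engine, and the synthetic-data protocol used throughout validation —
sample a reference flux distribution from the feasible polytope, simulate
the measured fragments, add 1 mol % Gaussian noise, and package the result
as measurements for refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .constraint import FluxBounds, sample_feasible_fluxes
from .emu import EMU, parse_emu
from .estimate import FluxMeasurement, MDVMeasurement
from .labeling import LabelingStrategy
from .mdv import DEFAULT_CONSTANTS, MDV, IsotopeConstants
from .network import (FluxDistribution, MetabolicNetwork, NetworkError,
                      read_network)
from .simulate import Trajectory, simulate_inst, simulate_steady_state

__all__ = ["ToyNetworkSpec", "SyntheticDataset", "toynet1",
           "random_toy_network", "brute_force_steady_state",
           "brute_force_inst", "generate_synthetic_dataset"]

MAX_ISOTOPOMER_STATES = 4096


@dataclass
class ToyNetworkSpec:
    """A small network bundled with everything a labeling experiment needs."""

    name: str
    reactions_tsv: str
    tracer: Dict[str, List[Tuple[str, float, float]]]
    measured_targets: List[str]
    uptake_reaction: str
    uptake_value: float
    default_pools: Dict[str, float] = field(default_factory=dict)
    default_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    identifiable_fluxes: List[str] = field(default_factory=list)
    inst_timegrid: Tuple[float, ...] = ()
    #: tracer used by the nonstationary protocol; single-position tracers
    #: leave some atoms (and hence some pools) uninformative in time-course
    #: data, so INST runs default to a multi-position mixture when set
    inst_tracer: Optional[Dict[str, List[Tuple[str, float, float]]]] = None

    @property
    def network(self) -> MetabolicNetwork:
        import io
        return read_network(io.StringIO(self.reactions_tsv))

    @property
    def strategy(self) -> LabelingStrategy:
        return LabelingStrategy(self.tracer)

    @property
    def inst_strategy(self) -> LabelingStrategy:
        return LabelingStrategy(self.inst_tracer or self.tracer)

    def flux_bounds(self) -> FluxBounds:
        fb = FluxBounds()
        for fid, (lo, hi) in self.default_bounds.items():
            fb.set(fid, lo, hi)
        return fb

    def net_flux_bounds(self) -> Dict[str, Tuple[float, float]]:
        net = self.network
        out = {}
        for rid in net.reactions:
            if rid in self.default_bounds:
                out[rid] = self.default_bounds[rid]
        return out

    def fit_net_flux_bounds(self) -> Dict[str, Tuple[float, float]]:
        """Net-flux bounds for fitting: the uptake reaction is anchored by
        its flux measurement, not pinned (a pinned box degenerates the
        initial-guess sampler)."""
        return {rid: b for rid, b in self.net_flux_bounds().items()
                if rid != self.uptake_reaction}


_TOYNET1_TSV = """id\tequation\treversible
v1\tA{abc} -> B{abc}\t0
v2\tB{abc} -> D{abc}\t1
v3\tB{abc} -> C{bc} + E{a}\t0
v4\tB{abc} + C{de} -> D{bcd} + E{a} + E{e}\t0
v5\tD{abc} -> F{abc}\t0
"""


def toynet1() -> ToyNetworkSpec:
    """Five-reaction exemplar network (substrate A, sink F).

    Contains a cleavage (v3), a condensation (v4), a reversible
    interconversion (v2) and flux-dependent target MDVs; tracer is
    [1-13C]A.  The stoichiometric system has two net degrees of freedom
    (the uptake scale and the cleavage/condensation branch) plus one
    exchange flux.
    """
    return ToyNetworkSpec(
        name="ToyNet-1",
        reactions_tsv=_TOYNET1_TSV,
        tracer={"A": [("100", 1.0, 1.0)]},
        measured_targets=["F_123", "D_123", "C_12", "E_1"],
        uptake_reaction="v1",
        uptake_value=100.0,
        default_pools={"B": 5.0, "C": 3.0, "D": 8.0},
        default_bounds={"v1": (100.0, 100.0), "v2": (-300.0, 300.0),
                        "v3": (0.0, 300.0), "v4": (0.0, 300.0),
                        "v5": (0.0, 300.0),
                        "v2_f": (0.0, 300.0), "v2_b": (0.0, 300.0)},
        identifiable_fluxes=["v1", "v2", "v3", "v4", "v5"],
        inst_timegrid=(0.0, 0.02, 0.05, 0.1, 0.2, 0.4),
        inst_tracer={"A": [("100", 0.6, 0.997), ("111", 0.4, 0.997)]},
    )


def random_toy_network(seed: int) -> ToyNetworkSpec:
    """A randomized small network with the ToyNet-1 code-path coverage.

    A 4-carbon substrate A is processed through a randomized cleavage
    C/D + condensation branch in parallel with a direct isomerization, so
    target MDVs depend on the flux split; atom maps are random
    permutations, making every seed a distinct labeling topology.
    """
    rng = np.random.default_rng(seed)
    letters = "abcd"

    def perm() -> str:
        return "".join(rng.permutation(list(letters)))

    k = int(rng.integers(1, 4))  # split size of the cleavage
    b_map = letters
    order = rng.permutation(list(letters))
    c_letters = "".join(order[:k])
    d_letters = "".join(order[k:])
    e_map = perm()
    rows = ["id\tequation\treversible",
            f"r1\tA{{{perm()}}} -> B{{{b_map}}}\t0",
            f"r2\tB{{{letters}}} -> C{{{c_letters}}} + D{{{d_letters}}}\t0",
            f"r3\tC{{{e_map[:k]}}} + D{{{e_map[k:]}}} -> E{{{e_map}}}\t0",
            f"r4\tB{{{letters}}} -> E{{{perm()}}}\t0",
            f"r5\tE{{{letters}}} -> F{{{letters}}}\t0"]
    n_labeled = int(rng.integers(1, 3))
    mask = ["0"] * 4
    for i in rng.choice(4, size=n_labeled, replace=False):
        mask[i] = "1"
    return ToyNetworkSpec(
        name=f"RandomNet(seed={seed})",
        reactions_tsv="\n".join(rows) + "\n",
        tracer={"A": [("".join(mask), 1.0, 1.0)]},
        measured_targets=["F_1234"],
        uptake_reaction="r1",
        uptake_value=100.0,
        default_pools={"B": 4.0, "C": 2.0, "D": 3.0, "E": 5.0},
        default_bounds={"r1": (100.0, 100.0), "r2": (0.0, 300.0),
                        "r3": (0.0, 300.0), "r4": (0.0, 300.0),
                        "r5": (0.0, 300.0)},
        identifiable_fluxes=["r1", "r5"],
        inst_timegrid=(0.0, 0.02, 0.05, 0.1, 0.2),
    )


# ---------------------------------------------------------------------------
# brute-force full-isotopomer simulator (the oracle)
# ---------------------------------------------------------------------------

def _marginal_tensor(x: np.ndarray, n: int, atoms: Sequence[int]) -> np.ndarray:
    """Marginal isotopomer distribution on a 1-based atom subset, returned
    as a (2,)*k tensor whose axes follow the order of ``atoms``.

    Flat isotopomer indices use bit j = atom j+1 (LSB = atom 1), so in the
    (2,)*n tensor view axis i corresponds to atom n-i.
    """
    t = x.reshape((2,) * n)
    keep = [n - a for a in atoms]
    other = tuple(ax for ax in range(n) if ax not in keep)
    m = t.sum(axis=other) if other else t
    sorted_keep = sorted(keep)
    perm = [sorted_keep.index(ax) for ax in keep]
    return m.transpose(perm)


def _mdv_weights(k: int) -> np.ndarray:
    return np.array([bin(p).count("1") for p in range(2 ** k)])


def mdv_from_isotopomers(x: np.ndarray, n: int, atoms: Sequence[int]) -> MDV:
    """Marginalize a 2^n isotopomer distribution to the MDV of an EMU."""
    k = len(atoms)
    m = _marginal_tensor(x, n, sorted(atoms)).reshape(-1)
    out = np.zeros(k + 1)
    np.add.at(out, _mdv_weights(k), m)
    return MDV(out)


class _IsotopomerModel:
    """Full 2^n-state isotopomer balance model of a small network."""

    def __init__(self, net: MetabolicNetwork, strategy: LabelingStrategy,
                 constants: IsotopeConstants):
        self.net = net
        self.constants = constants
        mapped = [m for m in net.metabolites.values() if m.n_atoms > 0]
        self.substrates = {m.id: strategy.isotopomer_distribution(
            m.id, m.n_atoms, constants) for m in mapped if m.is_substrate}
        self.internal = [m.id for m in mapped if not m.is_substrate]
        self.n_atoms = {m.id: m.n_atoms for m in mapped}
        total_states = sum(2 ** self.n_atoms[m] for m in self.internal)
        if total_states > MAX_ISOTOPOMER_STATES:
            raise NetworkError(
                f"{total_states} isotopomer states exceed the oracle cap "
                f"{MAX_ISOTOPOMER_STATES}")
        # production terms: met -> list of (flux_id, coef, pieces) where
        # pieces = [(source met, source atoms (pairing order), product atoms)]
        self.terms: Dict[str, list] = {m: [] for m in self.internal}
        for rxn in net.reactions.values():
            if not rxn.has_atom_maps:
                continue
            directions = [(rxn.id, rxn.substrates, rxn.products)]
            if rxn.reversible:
                directions = [(rxn.id + "_f", rxn.substrates, rxn.products),
                              (rxn.id + "_b", rxn.products, rxn.substrates)]
            for flux_id, subs, prods in directions:
                for met, coef, amap in prods:
                    if met not in self.terms or not amap:
                        continue
                    pieces: Dict[int, Tuple[list, list]] = {}
                    for pi, ch in enumerate(amap, start=1):
                        for si, (smet, _, samap) in enumerate(subs):
                            j = samap.find(ch) if samap else -1
                            if j >= 0:
                                pieces.setdefault(si, ([], []))
                                pieces[si][0].append(j + 1)
                                pieces[si][1].append(pi)
                                break
                        else:
                            raise NetworkError(
                                f"{rxn.id}: product atom {ch!r} unmatched")
                    plist = [(subs[si][0], satoms, patoms)
                             for si, (satoms, patoms) in sorted(pieces.items())]
                    self.terms[met].append((flux_id, float(coef), plist))
        # consumption weights per internal metabolite
        self.outflux_terms = {m: net.consumption_weights(m) for m in self.internal}

    def production(self, met: str, state: Dict[str, np.ndarray],
                   v: Mapping[str, float]) -> Tuple[np.ndarray, float]:
        """(flux-weighted production distribution, total influx)."""
        n = self.n_atoms[met]
        acc = np.zeros(2 ** n)
        influx = 0.0
        for flux_id, coef, pieces in self.terms[met]:
            w = coef * v[flux_id]
            if w == 0.0:
                continue
            margs = []
            patoms_all: List[int] = []
            for smet, satoms, patoms in pieces:
                x = self.substrates.get(smet)
                if x is None:
                    x = state[smet]
                margs.append(_marginal_tensor(x, self.n_atoms[smet], satoms))
                patoms_all += patoms
            joint = reduce(np.multiply.outer, margs)
            order = np.argsort([-a for a in patoms_all])
            acc += w * joint.transpose(order).reshape(-1)
            influx += w
        return acc, influx

    def natural_state(self) -> Dict[str, np.ndarray]:
        unlabeled = LabelingStrategy({})
        return {m: unlabeled.isotopomer_distribution(m, self.n_atoms[m],
                                                     self.constants)
                for m in self.internal}

    def fixed_point(self, v: Mapping[str, float], tol: float = 1e-14,
                    max_iter: int = 50000) -> Dict[str, np.ndarray]:
        """Gauss-Seidel iteration of x_M = production(x)/influx(M)."""
        state = self.natural_state()
        balanced = [m for m in self.internal
                    if self.net.metabolites[m].is_balanced]
        outputs = [m for m in self.internal if m not in balanced]
        for it in range(max_iter):
            delta = 0.0
            for met in balanced:
                prod, influx = self.production(met, state, v)
                if influx <= 1e-12:
                    raise NetworkError(f"no influx to {met}")
                new = prod / influx
                delta = max(delta, np.abs(new - state[met]).max())
                state[met] = new
            if delta < tol:
                break
        else:
            raise RuntimeError("isotopomer fixed point did not converge")
        for met in outputs:
            prod, influx = self.production(met, state, v)
            state[met] = prod / influx
        return state

    def ode(self, v: Mapping[str, float], pools: Mapping[str, float],
            timegrid: np.ndarray, rtol: float = 1e-10,
            atol: float = 1e-12) -> Dict[str, np.ndarray]:
        """High-accuracy adaptive integration of the full isotopomer ODE."""
        balanced = [m for m in self.internal
                    if self.net.metabolites[m].is_balanced]
        outputs = [m for m in self.internal if m not in balanced]
        sizes = [2 ** self.n_atoms[m] for m in balanced]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        outflux = {m: sum(w * v[f] for f, w in self.outflux_terms[m])
                   for m in self.internal}

        def unpack(y):
            return {m: y[offs[i]:offs[i + 1]] for i, m in enumerate(balanced)}

        def rhs(t, y):
            state = unpack(y)
            dy = np.empty_like(y)
            for i, met in enumerate(balanced):
                prod, _ = self.production(met, state, v)
                dy[offs[i]:offs[i + 1]] = (
                    prod - outflux[met] * state[met]) / pools[met]
            return dy

        nat = self.natural_state()
        y0 = np.concatenate([nat[m] for m in balanced])
        sol = solve_ivp(rhs, (timegrid[0], timegrid[-1]), y0, t_eval=timegrid,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"oracle ODE failed: {sol.message}")
        trajs = {m: sol.y[offs[i]:offs[i + 1], :].T
                 for i, m in enumerate(balanced)}
        for met in outputs:
            rows = []
            for kk in range(timegrid.size):
                state = {m: trajs[m][kk] for m in balanced}
                prod, influx = self.production(met, state, v)
                rows.append(prod / influx)
            trajs[met] = np.vstack(rows)
        return trajs


def brute_force_steady_state(net: MetabolicNetwork, v, strategy: LabelingStrategy,
                             targets: Sequence,
                             constants: IsotopeConstants = DEFAULT_CONSTANTS
                             ) -> Dict[EMU, MDV]:
    """Steady-state MDVs from the exhaustive isotopomer balance.

    Independent of the EMU engine: solves the full 2^n-state balance by
    Gauss-Seidel fixed-point iteration and marginalizes to MDVs.
    """
    model = _IsotopomerModel(net, strategy, constants)
    vmap = v if hasattr(v, "__getitem__") else dict(v)
    state = model.fixed_point(vmap)
    out = {}
    for t in targets:
        emu = t if isinstance(t, EMU) else parse_emu(str(t))
        met = net.metabolites[emu.metabolite_id]
        x = model.substrates.get(emu.metabolite_id)
        if x is None:
            x = state[emu.metabolite_id]
        out[emu] = mdv_from_isotopomers(x, met.n_atoms, emu.atom_indices)
    return out


def brute_force_inst(net: MetabolicNetwork, v, pools: Mapping[str, float],
                     strategy: LabelingStrategy, targets: Sequence,
                     timegrid: Sequence[float],
                     constants: IsotopeConstants = DEFAULT_CONSTANTS
                     ) -> Trajectory:
    """Transient MDVs from the exhaustive isotopomer ODE (adaptive LSODA)."""
    model = _IsotopomerModel(net, strategy, constants)
    tg = np.asarray(list(timegrid), dtype=float)
    trajs = model.ode(v, pools, tg)
    mdvs = {}
    for t in targets:
        emu = t if isinstance(t, EMU) else parse_emu(str(t))
        met = net.metabolites[emu.metabolite_id]
        sub = model.substrates.get(emu.metabolite_id)
        rows = []
        for kk in range(tg.size):
            x = sub if sub is not None else trajs[emu.metabolite_id][kk]
            rows.append(mdv_from_isotopomers(x, met.n_atoms,
                                             emu.atom_indices).values)
        mdvs[emu] = np.vstack(rows)
    return Trajectory(timegrid=tg, mdvs=mdvs)


# ---------------------------------------------------------------------------
# synthetic-data protocol
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Reference fluxes + simulated noisy measurements, seed-reproducible."""

    spec: ToyNetworkSpec
    mode: str
    true_total_fluxes: FluxDistribution
    true_net_fluxes: Dict[str, float]
    true_exchange_fluxes: Dict[str, float]
    true_pools: Dict[str, float]
    mdv_measurements: List[MDVMeasurement]
    flux_measurements: List[FluxMeasurement]
    noise_molpct: float
    seed: Optional[int]
    strategy: LabelingStrategy = None
    timegrid: Tuple[float, ...] = ()


def generate_synthetic_dataset(spec: ToyNetworkSpec, noise_molpct: float = 1.0,
                               seed: Optional[int] = None, mode: str = "ss",
                               timegrid: Optional[Sequence[float]] = None,
                               pools: Optional[Mapping[str, float]] = None,
                               constants: IsotopeConstants = DEFAULT_CONSTANTS,
                               renormalize: bool = True,
                               reference_fluxes: Optional[FluxDistribution] = None
                               ) -> SyntheticDataset:
    """The synthetic validation protocol.

    Samples one reference flux distribution from the feasible polytope
    (hit-and-run), simulates the MDVs of the measured fragments (steady
    state, or the time course with the network spec's default pools), perturbs
    every MDV entry with Gaussian noise of sd = noise_molpct/100
    (renormalizing afterwards unless ``renormalize=False``), and packages
    measurements whose declared sd equals the noise level (floored at
    0.001).  The uptake flux is reported with sd = max(1 mol% of its value,
    noise level) and a matching Gaussian perturbation.
    """
    rng = np.random.default_rng(seed)
    net = spec.network
    strategy = spec.strategy if mode == "ss" else spec.inst_strategy
    if reference_fluxes is None:
        v = sample_feasible_fluxes(net, spec.flux_bounds(), n=1,
                                   seed=int(rng.integers(2 ** 31 - 1)))[0]
    else:
        v = reference_fluxes
    sd = max(noise_molpct / 100.0, 1e-3)
    noise = noise_molpct / 100.0
    targets = spec.measured_targets
    mdv_meas: List[MDVMeasurement] = []

    def noisy(values: np.ndarray) -> np.ndarray:
        y = values + rng.standard_normal(values.size) * noise
        y = np.clip(y, 0.0, None)
        if renormalize and y.sum() > 0:
            y = y / y.sum()
        return y

    if mode == "ss":
        sim = simulate_steady_state(net, v, strategy, targets, constants)
        for t in targets:
            emu = parse_emu(t)
            mdv_meas.append(MDVMeasurement(
                emu, "ss", noisy(sim[emu].values), np.full(emu.size + 1, sd)))
        pools_used: Dict[str, float] = {}
        tg: Tuple[float, ...] = ()
    elif mode == "inst":
        pools_used = dict(pools or spec.default_pools)
        tg = tuple(timegrid if timegrid is not None else spec.inst_timegrid)
        traj = simulate_inst(net, v, pools_used, strategy, targets, tg,
                             constants)
        for t in targets:
            emu = parse_emu(t)
            for k, tk in enumerate(tg):
                if tk == 0.0:
                    continue  # t=0 is the known natural initial condition
                mdv_meas.append(MDVMeasurement(
                    emu, tk, noisy(traj.mdvs[emu][k]),
                    np.full(emu.size + 1, sd)))
    else:
        raise ValueError("mode must be 'ss' or 'inst'")

    uptake_true = v.net(spec.uptake_reaction)
    flux_sd = max(0.01 * abs(uptake_true), sd)
    flux_mean = uptake_true + (rng.standard_normal() * flux_sd
                               if noise_molpct > 0 else 0.0)
    flux_meas = [FluxMeasurement(spec.uptake_reaction, float(flux_mean),
                                 float(flux_sd))]
    net_true = {rid: v.net(rid) for rid in net.reactions}
    xch_true = {rid: v.exchange(rid) for rid in net.reversible_reaction_ids()}
    return SyntheticDataset(
        spec=spec, mode=mode, true_total_fluxes=v, true_net_fluxes=net_true,
        true_exchange_fluxes=xch_true, true_pools=pools_used,
        mdv_measurements=mdv_meas, flux_measurements=flux_meas,
        noise_molpct=noise_molpct, seed=seed, strategy=strategy, timegrid=tg)
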