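"""Elementary metabolite unit (EMU) decomposition.

An EMU is a specific subset of a metabolite's carbon atoms.  Its mass
isotopomer distribution obeys balances that are *linear* in the MDVs of the
EMUs feeding it, which is what makes network-scale labeling simulation
tractable: instead of 2^n isotopomer states per metabolite, only the EMUs
actually upstream of the measured fragments are simulated.

``decompose_network`` walks backward from the target EMUs: for every EMU it
enumerates the producing reactions, maps the EMU's atoms through each
reaction's atom maps onto the reactant molecules, and recurses until only
substrate (labeling-source) EMUs remain.  The resulting EMU reactions are
grouped by size; sizes are solved in ascending order because a condensation
node (a reaction joining two source EMUs) convolves strictly smaller EMUs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .network import MetabolicNetwork, NetworkError, Reaction

__all__ = ["EMU", "EMUReaction", "EMUNetwork", "decompose_network", "parse_emu"]


@dataclass(frozen=True, order=True)
class EMU:
    """A (metabolite, atom subset) pair; atom indices are 1-based, sorted."""

    metabolite_id: str
    atom_indices: Tuple[int, ...]

    def __post_init__(self):
        idx = tuple(sorted(self.atom_indices))
        if idx != tuple(self.atom_indices):
            object.__setattr__(self, "atom_indices", idx)
        if not idx:
            raise NetworkError(f"EMU of {self.metabolite_id} has no atoms")
        if len(set(idx)) != len(idx):
            raise NetworkError(f"EMU of {self.metabolite_id} repeats atoms {idx}")
        if idx[0] < 1:
            raise NetworkError("EMU atom indices are 1-based")

    @property
    def size(self) -> int:
        return len(self.atom_indices)

    @property
    def name(self) -> str:
        idx = self.atom_indices
        if all(b - a == 1 for a, b in zip(idx, idx[1:])) and idx[-1] <= 9:
            return f"{self.metabolite_id}_{''.join(map(str, idx))}"
        return f"{self.metabolite_id}_{','.join(map(str, idx))}"

    def __str__(self):
        return self.name

    def __repr__(self):
        return f"EMU({self.name})"


_EMU_RE = re.compile(r"^(.*)_([0-9,]+)$")


def parse_emu(name: str) -> EMU:
    """Parse canonical EMU names: ``Met_1,2,3`` or contiguous ``Met_123``."""
    m = _EMU_RE.match(name.strip())
    if not m:
        raise NetworkError(f"cannot parse EMU name {name!r}")
    met, idx = m.groups()
    if "," in idx:
        atoms = tuple(int(tok) for tok in idx.split(","))
    else:
        atoms = tuple(int(ch) for ch in idx)
    return EMU(met, atoms)


@dataclass(frozen=True)
class EMUReaction:
    """One labeled-carbon transfer: ``sources -> target`` carried by a flux.

    Multiple sources denote a condensation (convolution) node.  The
    coefficient is the stoichiometric weight of the producing molecule
    instance; the sum of source sizes always equals the target size.
    """

    flux_id: str
    sources: Tuple[EMU, ...]
    target: EMU
    coefficient: float

    def __post_init__(self):
        if sum(s.size for s in self.sources) != self.target.size:
            raise NetworkError(
                f"EMU reaction {self.flux_id}: source sizes "
                f"{[s.size for s in self.sources]} do not add up to target "
                f"{self.target.name} (size {self.target.size})")
        if self.coefficient <= 0:
            raise NetworkError("EMU reaction coefficient must be positive")

    def sort_key(self):
        return (self.target.name, self.flux_id,
                tuple(s.name for s in self.sources))


def _producing_directions(rxn: Reaction):
    """Yield (flux_id, substrate terms, product terms) for each direction
    in which the reaction can *produce* metabolites."""
    if rxn.reversible:
        yield rxn.id + "_f", rxn.substrates, rxn.products
        yield rxn.id + "_b", rxn.products, rxn.substrates
    else:
        yield rxn.id, rxn.substrates, rxn.products


def _producers_of(net: MetabolicNetwork, emu: EMU) -> List[EMUReaction]:
    """All EMU reactions producing ``emu``, found by mapping its atoms
    through every atom-mapped reaction instance that produces its
    metabolite."""
    out: List[EMUReaction] = []
    for rxn in net.reactions.values():
        if not rxn.has_atom_maps:
            continue
        for flux_id, subs, prods in _producing_directions(rxn):
            for met, coef, amap in prods:
                if met != emu.metabolite_id or not amap:
                    continue
                letters = [amap[i - 1] for i in emu.atom_indices]
                # group requested letters by the substrate instance carrying them
                sources: List[EMU] = []
                remaining = set(letters)
                for smet, _, samap in subs:
                    if not samap:
                        continue
                    atoms = tuple(sorted(samap.index(ch) + 1
                                         for ch in letters if ch in samap))
                    if atoms:
                        sources.append(EMU(smet, atoms))
                        remaining -= {samap[i - 1] for i in atoms}
                if remaining:
                    raise NetworkError(
                        f"{rxn.id}: atoms {sorted(remaining)} of product {met} "
                        "not found on the substrate side")
                sources.sort(key=lambda e: (e.metabolite_id, e.atom_indices))
                out.append(EMUReaction(flux_id, tuple(sources), emu, float(coef)))
    return out


class EMUNetwork:
    """Size-ordered EMU reaction system produced by ``decompose_network``.

    Attributes
    ----------
    by_size
        size -> sorted list of :class:`EMUReaction` whose targets are
        non-substrate EMUs of that size.
    internal_emus
        size -> sorted list of non-substrate EMUs balanced at that size.
    source_emus
        size -> sorted list of substrate EMUs appearing as sources.
    targets
        the EMUs the decomposition was requested for.
    """

    def __init__(self, by_size: Dict[int, List[EMUReaction]],
                 targets: Sequence[EMU]):
        self.by_size: Dict[int, List[EMUReaction]] = {
            s: sorted(rs, key=EMUReaction.sort_key)
            for s, rs in sorted(by_size.items())
        }
        self.targets = list(targets)
        self.internal_emus: Dict[int, List[EMU]] = {}
        self.source_emus: Dict[int, List[EMU]] = {}
        for size, rxns in self.by_size.items():
            internal = {r.target for r in rxns}
            sources = set()
            for r in rxns:
                sources.update(r.sources)
            self.internal_emus[size] = sorted(internal)
            self.source_emus[size] = sorted(
                s for s in sources if s not in internal)

    @property
    def sizes(self) -> List[int]:
        return list(self.by_size)

    def all_emus(self) -> List[EMU]:
        seen = set()
        for rxns in self.by_size.values():
            for r in rxns:
                seen.add(r.target)
                seen.update(r.sources)
        return sorted(seen)

    def flux_ids(self) -> List[str]:
        ids = set()
        for rxns in self.by_size.values():
            ids.update(r.flux_id for r in rxns)
        return sorted(ids)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular export: size, target, sources, flux_id, coefficient."""
        rows = []
        for size, rxns in self.by_size.items():
            for r in rxns:
                rows.append({
                    "size": size,
                    "target": r.target.name,
                    "sources": " + ".join(s.name for s in r.sources),
                    "flux_id": r.flux_id,
                    "coefficient": r.coefficient,
                })
        return pd.DataFrame(rows,
                            columns=["size", "target", "sources", "flux_id",
                                     "coefficient"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def __repr__(self):
        sizes = {s: len(r) for s, r in self.by_size.items()}
        return f"EMUNetwork(sizes={sizes}, targets={[t.name for t in self.targets]})"


def decompose_network(net: MetabolicNetwork, targets: Iterable) -> EMUNetwork:
    """Backward EMU decomposition from the target EMUs.

    Targets may be :class:`EMU` objects or canonical names.  The traversal
    is memoized on the EMU and the returned structure is deterministically
    ordered (sorted canonical names), so two decompositions of the same
    network and targets are identical.
    """
    tgt: List[EMU] = []
    for t in targets:
        emu = t if isinstance(t, EMU) else parse_emu(str(t))
        met = net.metabolites.get(emu.metabolite_id)
        if met is None:
            raise NetworkError(f"target EMU {emu.name}: unknown metabolite")
        if emu.atom_indices[-1] > met.n_atoms:
            raise NetworkError(
                f"target EMU {emu.name}: atom index out of range "
                f"(metabolite has {met.n_atoms} atoms)")
        tgt.append(emu)

    by_size: Dict[int, List[EMUReaction]] = {}
    visited = set()
    stack = list(tgt)
    while stack:
        emu = stack.pop()
        if emu in visited:
            continue
        visited.add(emu)
        met = net.metabolites[emu.metabolite_id]
        if met.is_substrate:
            continue  # labeling source: MDV given by the tracer strategy
        producers = _producers_of(net, emu)
        if not producers:
            raise NetworkError(
                f"EMU {emu.name} is unreachable from any substrate: no "
                "atom-mapped reaction produces it")
        by_size.setdefault(emu.size, []).extend(producers)
        for r in producers:
            for s in r.sources:
                if s not in visited:
                    stack.append(s)
    return EMUNetwork(by_size, tgt)
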