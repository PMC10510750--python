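"""Tracer labeling strategies.

A labeling strategy declares, per substrate metabolite, the isotopomer
mixture added to the culture: each component is a 0/1 mask over the
molecule's atoms (1 = position declared 13C-labeled), the molar fraction of
that component, and the isotopic purity of the labeled positions.  Atoms not
declared labeled carry natural 13C abundance.

Example: 80% [1-13C] + 20% [U-13C] glucose::

    LabelingStrategy({"Glc": [("100000", 0.8, 0.995),
                              ("111111", 0.2, 0.995)]})
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .emu import EMU
from .mdv import DEFAULT_CONSTANTS, MDV, IsotopeConstants, get_substrate_MDV
from .network import MetabolicNetwork, NetworkError

__all__ = ["LabelingStrategy"]


class LabelingStrategy:
    """Per-substrate tracer isotopomer mixtures."""

    def __init__(self, tracers: Mapping[str, Sequence[Tuple[str, float, float]]]):
        self.tracers: Dict[str, List[Tuple[str, float, float]]] = {}
        for met, comps in tracers.items():
            comps = [(str(mask), float(frac), float(purity))
                     for mask, frac, purity in comps]
            if not comps:
                raise NetworkError(f"tracer for {met} has no isotopomers")
            n = len(comps[0][0])
            for mask, frac, purity in comps:
                if len(mask) != n:
                    raise NetworkError(
                        f"tracer {met}: isotopomer masks differ in length")
                if not set(mask) <= {"0", "1"}:
                    raise NetworkError(
                        f"tracer {met}: mask {mask!r} must be 0/1")
                if not (0.0 <= purity <= 1.0):
                    raise NetworkError(f"tracer {met}: purity {purity} not in [0,1]")
            total = sum(f for _, f, _ in comps)
            if abs(total - 1.0) > 1e-6:
                raise NetworkError(
                    f"tracer {met}: fractions sum to {total}, not 1")
            self.tracers[met] = comps

    def covers(self, metabolite_id: str) -> bool:
        return metabolite_id in self.tracers

    def validate_against(self, net: MetabolicNetwork) -> None:
        for met_id, comps in self.tracers.items():
            met = net.metabolites.get(met_id)
            if met is None:
                raise NetworkError(f"tracer metabolite {met_id} not in network")
            if met.n_atoms != len(comps[0][0]):
                raise NetworkError(
                    f"tracer {met_id}: mask length {len(comps[0][0])} != "
                    f"{met.n_atoms} atoms")

    def substrate_mdv(self, emu: EMU,
                      constants: IsotopeConstants = DEFAULT_CONSTANTS) -> MDV:
        """MDV of a substrate EMU under this strategy (natural MDV for
        substrates with no declared tracer)."""
        comps = self.tracers.get(emu.metabolite_id)
        if comps is None:
            from .mdv import get_natural_MDV
            return get_natural_MDV(emu.size, constants)
        return get_substrate_MDV(emu.atom_indices, comps, constants)

    def isotopomer_distribution(self, metabolite_id: str, n_atoms: int,
                                constants: IsotopeConstants = DEFAULT_CONSTANTS
                                ) -> np.ndarray:
        """Full 2^n isotopomer distribution of a substrate molecule.

        Index bit k (LSB = atom 1) set means atom k+1 is 13C.  Used by the
        brute-force oracles.
        """
        comps = self.tracers.get(metabolite_id)
        dist = np.zeros(2 ** n_atoms)
        if comps is None:
            comps = [("0" * n_atoms, 1.0, 1.0)]
        for mask, frac, purity in comps:
            probs = [purity if ch == "1" else constants.p13 for ch in mask]
            comp = np.array([1.0])
            for p in probs:  # atom order: LSB first
                comp = np.concatenate([comp * (1 - p), comp * p])
            dist += frac * comp
        return dist

    def __repr__(self):
        parts = []
        for met, comps in self.tracers.items():
            parts.append(f"{met}: " + " + ".join(
                f"{f:.0%} [{mask}] (purity {p})" for mask, f, p in comps))
        return f"LabelingStrategy({'; '.join(parts)})"
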