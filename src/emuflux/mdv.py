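"""Mass isotopomer distribution vectors (MDVs) and measurement algebra.

An MDV of an n-carbon metabolite fragment is the length-(n+1) vector of
fractional abundances of its mass isotopomers M+0 ... M+n.  It is the
universal unit of both simulation and measurement in 13C metabolic flux
analysis: labeling states propagate through the network as MDVs, and mass
spectrometry measures them (after correction for natural isotope abundance
of non-tracer atoms and for unlabeled biomass carried over from the
inoculum).

This module provides the :class:`MDV` container together with

* discrete convolution (``conv`` / the ``*`` operator) — the merged
  distribution of the substrates of a condensation reaction,
* natural-abundance MDVs of unlabeled fragments,
* substrate MDVs derived from a tracer labeling strategy,
* correction of raw measurements for natural isotope abundance of
  non-tracer elements (H, N, O, S, Si, non-tracer C) and for the unlabeled
  fraction introduced by the inoculum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MDV",
    "IsotopeConstants",
    "CorrectionSpec",
    "conv",
    "get_natural_MDV",
    "get_substrate_MDV",
    "correct_for_natural_abundance",
    "correct_for_inoculum",
]


#: Mass-shift distributions of naturally occurring isotopes, one probability
#: vector per element, indexed by mass shift relative to the lightest
#: isotope.  Values are IUPAC representative isotopic compositions.
NATURAL_SHIFT_DISTRIBUTIONS: Dict[str, tuple] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    # S isotopes 32/33/34/36: mass shift 3 does not occur.
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
}


@dataclass(frozen=True)
class IsotopeConstants:
    """Isotopic-abundance constants used across simulation and correction.

    Parameters
    ----------
    p13
        Natural abundance of 13C.  The default 0.0107 is the IUPAC
        representative value; set to 0 for idealized (noise-free tracer)
        calculations.
    element_shifts
        Per-element natural mass-shift probability vectors used when
        correcting derivatized fragments for non-tracer atoms.
    """

    p13: float = 0.0107
    element_shifts: Mapping[str, tuple] = field(
        default_factory=lambda: dict(NATURAL_SHIFT_DISTRIBUTIONS)
    )

    def shift_distribution(self, element: str) -> np.ndarray:
        try:
            d = np.asarray(self.element_shifts[element], dtype=float)
        except KeyError as exc:
            raise KeyError(f"no natural-isotope data for element {element!r}") from exc
        s = d.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError(f"isotope distribution of {element} does not sum to 1")
        return d / s


DEFAULT_CONSTANTS = IsotopeConstants()


class MDV:
    """A normalized mass isotopomer distribution vector.

    The constructor accepts any nonnegative vector with positive sum and
    normalizes it to sum exactly to 1 (idempotent for already-normalized
    input).  Entries more negative than ``-1e-9`` are rejected; tiny
    negative round-off is clipped to zero.
    """

    __slots__ = ("values",)

    def __init__(self, values: Iterable[float]):
        v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                       dtype=float).ravel()
        if v.size == 0:
            raise ValueError("MDV must have at least one entry (M+0)")
        if np.any(v < -1e-9):
            raise ValueError(f"negative MDV entries: {v}")
        v = np.clip(v, 0.0, None)
        s = v.sum()
        if s <= 0:
            raise ValueError("MDV has zero total abundance")
        object.__setattr__(self, "values", v / s)

    @property
    def n_atoms(self) -> int:
        return self.values.size - 1

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, i):
        return self.values[i]

    def __iter__(self):
        return iter(self.values)

    def __mul__(self, other: "MDV") -> "MDV":
        return conv(self, other)

    def __repr__(self) -> str:
        vals = ", ".join(f"{x:.6g}" for x in self.values)
        return f"MDV([{vals}])"

    def __eq__(self, other) -> bool:
        return isinstance(other, MDV) and self.values.shape == other.values.shape \
            and bool(np.allclose(self.values, other.values, atol=1e-12))

    def __hash__(self):  # frozen container, hash on rounded values
        return hash(self.values.round(12).tobytes())

    def enrichment(self) -> float:
        """Fractional 13C enrichment: sum_i i*m_i / n."""
        if self.n_atoms == 0:
            return 0.0
        return float(np.arange(len(self)) @ self.values / self.n_atoms)

    def isclose(self, other: "MDV", atol: float = 1e-9) -> bool:
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, atol=atol)
        )


def conv(a: MDV, b: MDV) -> MDV:
    """Convolution of two MDVs: the distribution of the condensed fragment.

    The result has ``a.n_atoms + b.n_atoms`` tracer atoms and its entries
    are the discrete convolution of the inputs; normalization is preserved.
    """
    return MDV(np.convolve(a.values, b.values))


def get_natural_MDV(n_atoms: int, constants: IsotopeConstants = DEFAULT_CONSTANTS) -> MDV:
    """Natural-abundance MDV of an unlabeled n-carbon EMU.

    Each carbon is 13C independently with probability ``constants.p13``, so
    the MDV is the binomial(n, p13) probability mass function.
    """
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    p = constants.p13
    # binomial pmf via iterated convolution keeps exact normalization
    out = np.array([1.0])
    one = np.array([1.0 - p, p])
    for _ in range(n_atoms):
        out = np.convolve(out, one)
    return MDV(out)


def _atom_bernoullis(mask: str, purity: float, p13: float) -> list:
    """Per-atom single-carbon MDVs of a tracer isotopomer.

    Atoms flagged '1' in the mask are 13C with probability ``purity``;
    atoms flagged '0' carry natural abundance ``p13``.
    """
    out = []
    for ch in mask:
        if ch == "1":
            out.append(np.array([1.0 - purity, purity]))
        elif ch == "0":
            out.append(np.array([1.0 - p13, p13]))
        else:
            raise ValueError(f"isotopomer mask must be 0/1, got {mask!r}")
    return out


def get_substrate_MDV(atom_indices: Sequence[int], isotopomers: Sequence[tuple],
                      constants: IsotopeConstants = DEFAULT_CONSTANTS) -> MDV:
    """MDV of a substrate EMU under a tracer mixture.

    Parameters
    ----------
    atom_indices
        1-based atom positions of the EMU within the substrate molecule.
    isotopomers
        Sequence of ``(mask, fraction, purity)`` tuples describing the
        tracer mixture, e.g. ``[("100000", 0.8, 0.995), ("111111", 0.2,
        0.995)]`` for 80% [1-13C] + 20% [U-13C] glucose.  Fractions must
        sum to 1 (tolerance 1e-6).

    The per-atom labeling probabilities are Bernoulli(purity) for atoms
    declared labeled and Bernoulli(p13) otherwise; the EMU's atoms are
    convolved and the mixture is weighted by fractions.
    """
    fracs = np.array([f for _, f, _ in isotopomers], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"isotopomer fractions sum to {fracs.sum()}, not 1")
    n = len(atom_indices)
    mix = np.zeros(n + 1)
    for mask, frac, purity in isotopomers:
        for i in atom_indices:
            if not (1 <= i <= len(mask)):
                raise ValueError(
                    f"atom index {i} out of range for isotopomer mask {mask!r}")
        atoms = _atom_bernoullis(mask, purity, constants.p13)
        m = np.array([1.0])
        for i in atom_indices:
            m = np.convolve(m, atoms[i - 1])
        mix += frac * m
    return MDV(mix)


@dataclass(frozen=True)
class CorrectionSpec:
    """What to correct a raw fragment MDV for.

    ``elemental_formula`` counts the fragment's *non-tracer* atoms (e.g. the
    H, N, O, Si of a TMS-derivatized amino-acid fragment, plus any carbons
    outside the tracer backbone); ``tracer_atoms`` is the number of carbons
    the MDV is resolved over; ``inoculum_fraction`` is the unlabeled biomass
    fraction carried into the labeling culture.
    """

    tracer_atoms: int
    elemental_formula: Mapping[str, int] = field(default_factory=dict)
    inoculum_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.inoculum_fraction <= 1.0):
            raise ValueError("inoculum fraction must be in [0, 1]")
        for el, cnt in self.elemental_formula.items():
            if cnt < 0:
                raise ValueError(f"negative atom count for {el}")


def _formula_shift_distribution(formula: Mapping[str, int],
                                constants: IsotopeConstants) -> np.ndarray:
    """Mass-shift distribution of the non-tracer atoms: convolution cascade
    of each element's natural distribution raised to its atom count."""
    d = np.array([1.0])
    for el, cnt in sorted(formula.items()):
        base = constants.shift_distribution(el)
        for _ in range(int(cnt)):
            d = np.convolve(d, base)
    return d


def correction_matrix(n_tracer: int, formula: Mapping[str, int],
                      constants: IsotopeConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """(n+1)x(n+1) matrix M with raw = M @ true for non-tracer-atom shifts."""
    d = _formula_shift_distribution(formula, constants)
    n = n_tracer + 1
    M = np.zeros((n, n))
    for j in range(n):
        top = min(n - j, d.size)
        M[j:j + top, j] = d[:top]
    return M


def correct_for_natural_abundance(raw, spec: CorrectionSpec,
                                  constants: IsotopeConstants = DEFAULT_CONSTANTS) -> MDV:
    """Recover the tracer-only MDV from a raw fragment measurement.

    Builds the correction matrix from the fragment's non-tracer elemental
    formula and solves the linear system by least squares.  Entries in
    [-1e-3, 0) after the solve are treated as measurement noise, clipped to
    zero, and the vector renormalized; larger negatives signal an
    inconsistent formula and raise.
    """
    r = np.asarray(raw, dtype=float).ravel()
    if r.size != spec.tracer_atoms + 1:
        raise ValueError(
            f"raw MDV has {r.size} entries, expected {spec.tracer_atoms + 1}")
    M = correction_matrix(spec.tracer_atoms, spec.elemental_formula, constants)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("correction matrix is singular or ill-conditioned")
    x, *_ = np.linalg.lstsq(M, r, rcond=None)
    if np.any(x < -1e-3):
        raise ValueError(
            f"correction produced large negative abundances {x.min():.3g}; "
            "the elemental formula is likely inconsistent with the data")
    return MDV(np.clip(x, 0.0, None))


def correct_for_inoculum(raw, f: float,
                         constants: IsotopeConstants = DEFAULT_CONSTANTS) -> MDV:
    """Remove the unlabeled fraction ``f`` introduced by the inoculum.

    Inverts raw = f * natural + (1 - f) * true, renormalizing afterwards.
    """
    if not (0.0 <= f < 1.0):
        raise ValueError("inoculum fraction must satisfy 0 <= f < 1")
    r = np.asarray(raw, dtype=float).ravel()
    nat = get_natural_MDV(r.size - 1, constants).values
    x = (r - f * nat) / (1.0 - f)
    if np.any(x < -1e-3):
        raise ValueError(
            f"inoculum correction produced negative abundances {x.min():.3g}; "
            "the declared fraction is likely too large")
    return MDV(np.clip(x, 0.0, None))
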