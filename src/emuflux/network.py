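"""Atom-mapped metabolic networks and the stoichiometric system.

A network is a set of reactions over carbon-backboned metabolites, each
reaction carrying an atom map that states which reactant carbon becomes
which product carbon.  Reversible reactions are split into forward and
backward components ("total fluxes"), so that the stoichiometric matrix S
over total fluxes together with S·v = 0 and v >= 0 defines the feasible
flux space.

Reaction dialect (one reaction per line / per TSV row)::

    id: coef Met{abc} + Met2{d} -> coef Met3{abcd} [+ ...]

* coefficients are optional (default 1) and may be rationals like ``1/2``;
* atom maps are lowercase letters in ``{}``, unique within one molecule
  instance; the multiset of letters must balance across the arrow unless
  the reaction is flagged ``nocheck`` (biomass and similar pseudo
  reactions);
* a molecule may appear twice on one side with two different maps (the
  standard treatment of molecular symmetry, e.g. succinate, fumarate);
* metabolites without braces carry no tracer atoms (cofactors).
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxDistribution",
    "parse_reaction",
    "read_network",
    "split_total_fluxes",
    "validate_network",
    "NetworkError",
]


class NetworkError(ValueError):
    """Malformed reaction/network input."""


@dataclass
class Metabolite:
    id: str
    n_atoms: int = 0
    is_balanced: bool = True
    is_substrate: bool = False
    is_excreted: bool = False

    def __post_init__(self):
        if self.n_atoms < 0:
            raise NetworkError(f"{self.id}: negative atom count")


#: one molecule instance on one side of a reaction
#: (metabolite id, stoichiometric coefficient, atom map string or "")
Term = Tuple[str, Fraction, str]

_TERM_RE = re.compile(
    r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?([A-Za-z_][A-Za-z0-9_.\-]*)"
    r"(?:\{([a-z]*)\})?$"
)


def _parse_coef(tok: Optional[str]) -> Fraction:
    if tok is None:
        return Fraction(1)
    if "/" in tok:
        return Fraction(tok)
    return Fraction(tok).limit_denominator(10**6)


def _parse_side(side: str, rxn_id: str) -> List[Term]:
    terms: List[Term] = []
    for part in side.split("+"):
        part = part.strip()
        if not part:
            raise NetworkError(f"{rxn_id}: empty term in {side!r}")
        m = _TERM_RE.match(part)
        if not m:
            raise NetworkError(f"{rxn_id}: malformed term {part!r}")
        coef_tok, met, amap = m.groups()
        coef = _parse_coef(coef_tok)
        if coef <= 0:
            raise NetworkError(f"{rxn_id}: non-positive coefficient in {part!r}")
        amap = amap or ""
        if len(set(amap)) != len(amap):
            raise NetworkError(
                f"{rxn_id}: duplicate atom letter within one molecule: {part!r}")
        terms.append((met, coef, amap))
    return terms


@dataclass
class Reaction:
    id: str
    substrates: List[Term]
    products: List[Term]
    reversible: bool = False
    carbon_checked: bool = True

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise NetworkError(f"{self.id}: reaction needs both sides")
        if self.carbon_checked:
            # coefficient-weighted letter counts: a symmetric molecule listed
            # twice at 1/2 each contributes every letter exactly once
            lhs: Counter = Counter()
            rhs: Counter = Counter()
            for _, coef, amap in self.substrates:
                for ch in amap:
                    lhs[ch] += coef
            for _, coef, amap in self.products:
                for ch in amap:
                    rhs[ch] += coef
            if lhs != rhs:
                raise NetworkError(
                    f"{self.id}: unbalanced atom letters "
                    f"(substrates {sorted(lhs)}, products {sorted(rhs)}); "
                    "flag the reaction 'nocheck' if intentional")

    @property
    def has_atom_maps(self) -> bool:
        return any(amap for _, _, amap in self.substrates + self.products)

    def equation(self) -> str:
        def side(terms):
            out = []
            for met, coef, amap in terms:
                c = "" if coef == 1 else f"{coef} "
                a = f"{{{amap}}}" if amap else ""
                out.append(f"{c}{met}{a}")
            return " + ".join(out)

        arrow = "<->" if self.reversible else "->"
        return f"{side(self.substrates)} {arrow} {side(self.products)}"


def parse_reaction(line: str, reversible: Optional[bool] = None,
                   nocheck: bool = False) -> Reaction:
    """Parse one reaction line of the dialect described in the module docs.

    Trailing ``[rev]`` / ``[nocheck]`` flags in the line are honored; the
    keyword arguments override/augment them.  ``<->`` as the arrow also
    marks reversibility.
    """
    s = line.strip()
    flags = set()
    while True:
        m = re.search(r"\[\s*(rev|nocheck)\s*\]\s*$", s)
        if not m:
            break
        flags.add(m.group(1))
        s = s[: m.start()].rstrip()
    if ":" not in s:
        raise NetworkError(f"missing 'id:' prefix in {line!r}")
    rxn_id, eq = s.split(":", 1)
    rxn_id = rxn_id.strip()
    if not rxn_id:
        raise NetworkError(f"empty reaction id in {line!r}")
    arrow = None
    for cand in ("<->", "<=>", "->", "=>"):
        if cand in eq:
            arrow = cand
            break
    if arrow is None:
        raise NetworkError(f"{rxn_id}: no reaction arrow found")
    lhs, rhs = eq.split(arrow, 1)
    rev = reversible if reversible is not None else (
        arrow in ("<->", "<=>") or "rev" in flags)
    return Reaction(
        id=rxn_id,
        substrates=_parse_side(lhs, rxn_id),
        products=_parse_side(rhs, rxn_id),
        reversible=bool(rev),
        carbon_checked=not (nocheck or "nocheck" in flags),
    )


_TRUE_TOKENS = {"1", "true", "yes", "y", "t", "rev", "reversible"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", "irrev", "irreversible", "", "nan"}


def _parse_bool(tok) -> bool:
    s = str(tok).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise NetworkError(f"cannot interpret reversibility flag {tok!r}")


class FluxDistribution:
    """A vector of total fluxes (irreversible ``r``; reversible ``r_f``/``r_b``).

    Behaves as a read-only mapping from total-flux id to value and provides
    net/exchange accessors per reaction.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        self._values = {k: float(v) for k, v in values.items()}
        for k, v in self._values.items():
            if v < -1e-9:
                raise NetworkError(f"negative total flux {k} = {v}")

    def __getitem__(self, flux_id: str) -> float:
        return self._values[flux_id]

    def __contains__(self, flux_id: str) -> bool:
        return flux_id in self._values

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def items(self):
        return self._values.items()

    def keys(self):
        return self._values.keys()

    def get(self, k, default=None):
        return self._values.get(k, default)

    def net(self, reaction_id: str) -> float:
        if reaction_id in self._values:
            return self._values[reaction_id]
        return self._values[reaction_id + "_f"] - self._values[reaction_id + "_b"]

    def exchange(self, reaction_id: str) -> float:
        if reaction_id in self._values:
            return 0.0
        return min(self._values[reaction_id + "_f"],
                   self._values[reaction_id + "_b"])

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self._values[k] for k in order], dtype=float)

    def __repr__(self):
        items = ", ".join(f"{k}={v:.4g}" for k, v in self._values.items())
        return f"FluxDistribution({items})"


class MetabolicNetwork:
    """Atom-mapped reactions plus the stoichiometric system over total fluxes."""

    def __init__(self):
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self._role_overrides: Dict[str, dict] = {}

    # -- construction ------------------------------------------------------

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise NetworkError(f"duplicate reaction id {rxn.id!r}")
        for met, _, amap in rxn.substrates + rxn.products:
            if amap:
                known = self.metabolites.get(met)
                if known is None:
                    self.metabolites[met] = Metabolite(met, n_atoms=len(amap))
                elif known.n_atoms == 0:
                    known.n_atoms = len(amap)
                elif known.n_atoms != len(amap):
                    raise NetworkError(
                        f"{rxn.id}: metabolite {met} has {len(amap)} mapped atoms "
                        f"but {known.n_atoms} elsewhere")
            else:
                self.metabolites.setdefault(met, Metabolite(met, n_atoms=0))
        self.reactions[rxn.id] = rxn
        self._infer_roles()

    def add_reactions_from_text(self, text: str) -> None:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            self.add_reaction(parse_reaction(line))

    def set_roles(self, substrates: Sequence[str] = (), excreted: Sequence[str] = (),
                  unbalanced: Sequence[str] = ()) -> None:
        """Override inferred metabolite roles (config block of a model file)."""
        for m in substrates:
            self._role_overrides.setdefault(m, {})["is_substrate"] = True
        for m in excreted:
            self._role_overrides.setdefault(m, {})["is_excreted"] = True
        for m in unbalanced:
            self._role_overrides.setdefault(m, {})["is_balanced"] = False
        self._infer_roles()

    def _infer_roles(self) -> None:
        produced = set()
        consumed = set()
        for rxn in self.reactions.values():
            subs = {m for m, _, _ in rxn.substrates}
            prods = {m for m, _, _ in rxn.products}
            consumed |= subs
            produced |= prods
            if rxn.reversible:
                consumed |= prods
                produced |= subs
        for met in self.metabolites.values():
            met.is_substrate = met.id not in produced
            met.is_excreted = met.id not in consumed
            met.is_balanced = (met.id in produced) and (met.id in consumed)
            for k, v in self._role_overrides.get(met.id, {}).items():
                setattr(met, k, v)
                if k == "is_substrate" and v:
                    met.is_balanced = False
                if k == "is_excreted" and v:
                    met.is_balanced = False

    # -- stoichiometric system --------------------------------------------

    @property
    def total_flux_ids(self) -> List[str]:
        ids: List[str] = []
        for rid, rxn in self.reactions.items():
            if rxn.reversible:
                ids.extend([rid + "_f", rid + "_b"])
            else:
                ids.append(rid)
        return ids

    @property
    def balanced_metabolites(self) -> List[str]:
        return [m.id for m in self.metabolites.values() if m.is_balanced]

    def _stoich_column(self, rxn: Reaction, rows: Dict[str, int]) -> np.ndarray:
        col = np.zeros(len(rows))
        for met, coef, _ in rxn.substrates:
            if met in rows:
                col[rows[met]] -= float(coef)
        for met, coef, _ in rxn.products:
            if met in rows:
                col[rows[met]] += float(coef)
        return col

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """S over total fluxes: rows = balanced metabolites, columns = total
        fluxes; the backward column of a reversible reaction is the negation
        of its forward column."""
        rows = {m: i for i, m in enumerate(self.balanced_metabolites)}
        cols = {}
        for rid, rxn in self.reactions.items():
            base = self._stoich_column(rxn, rows)
            if rxn.reversible:
                cols[rid + "_f"] = base
                cols[rid + "_b"] = -base
            else:
                cols[rid] = base
        return pd.DataFrame(cols, index=list(rows)).astype(float)

    def net_stoichiometric_matrix(self) -> pd.DataFrame:
        """S over net reaction fluxes (one column per reaction)."""
        rows = {m: i for i, m in enumerate(self.balanced_metabolites)}
        cols = {rid: self._stoich_column(rxn, rows)
                for rid, rxn in self.reactions.items()}
        return pd.DataFrame(cols, index=list(rows)).astype(float)

    def reversible_reaction_ids(self) -> List[str]:
        return [rid for rid, r in self.reactions.items() if r.reversible]

    # -- consumption/production weights used by EMU balances ---------------

    def consumption_weights(self, metabolite_id: str) -> List[Tuple[str, float]]:
        """(total flux id, stoichiometric weight) pairs consuming a metabolite."""
        out = []
        for rid, rxn in self.reactions.items():
            sub_coef = sum(float(c) for m, c, _ in rxn.substrates if m == metabolite_id)
            prod_coef = sum(float(c) for m, c, _ in rxn.products if m == metabolite_id)
            if rxn.reversible:
                if sub_coef:
                    out.append((rid + "_f", sub_coef))
                if prod_coef:
                    out.append((rid + "_b", prod_coef))
            elif sub_coef:
                out.append((rid, sub_coef))
        return out

    def __repr__(self):
        return (f"MetabolicNetwork({len(self.reactions)} reactions, "
                f"{len(self.metabolites)} metabolites, "
                f"{len(self.total_flux_ids)} total fluxes)")


def read_network(path_or_buffer, substrates: Sequence[str] = (),
                 excreted: Sequence[str] = (),
                 unbalanced: Sequence[str] = ()) -> MetabolicNetwork:
    """Read a network from a TSV/CSV file with columns id, equation, reversible.

    Metabolite roles (labeling source / excreted) are inferred from the
    topology — never produced / never consumed — and can be overridden via
    the keyword arguments.  Reversibility accepts 1/0, true/false, yes/no.
    """
    if isinstance(path_or_buffer, (str, Path)):
        text = Path(path_or_buffer).read_text()
    else:
        text = path_or_buffer.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#",
                     skip_blank_lines=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"id", "equation"}
    if not required <= set(df.columns):
        raise NetworkError(f"network file must have columns id, equation "
                           f"(got {list(df.columns)})")
    if df.empty:
        raise NetworkError("no reactions in network file")
    net = MetabolicNetwork()
    for _, row in df.iterrows():
        eq = str(row["equation"]).strip()
        rev = _parse_bool(row["reversible"]) if "reversible" in df.columns else None
        line = f"{str(row['id']).strip()}: {eq}"
        rxn = parse_reaction(line, reversible=rev)
        net.add_reaction(rxn)
    if substrates or excreted or unbalanced:
        net.set_roles(substrates, excreted, unbalanced)
    return net


def read_network_xlsx(path, sheet: int | str = 0, **roles) -> MetabolicNetwork:
    """Import the two-column spreadsheet layout (reactants_with_atoms /
    products_with_atoms) common in published reaction-table spreadsheets."""
    df = pd.read_excel(path, sheet_name=sheet)
    df.columns = [str(c).strip().lower() for c in df.columns]
    need = {"id", "reactants_with_atoms", "products_with_atoms"}
    if not need <= set(df.columns):
        raise NetworkError(
            f"XLSX importer expects columns {sorted(need)}, got {list(df.columns)}")
    net = MetabolicNetwork()
    for _, row in df.iterrows():
        rev = _parse_bool(row.get("reversible", "0"))
        line = (f"{str(row['id']).strip()}: {row['reactants_with_atoms']} -> "
                f"{row['products_with_atoms']}")
        net.add_reaction(parse_reaction(line, reversible=rev))
    if roles:
        net.set_roles(**roles)
    return net


def split_total_fluxes(net: MetabolicNetwork, v_net: Mapping[str, float],
                       v_xch: Optional[Mapping[str, float]] = None) -> FluxDistribution:
    """Combine net and exchange values into total fluxes.

    For a reversible reaction, ``forward = v_net + v_xch`` when the net flux
    is nonnegative, ``forward = v_xch`` otherwise, and ``backward = forward
    - v_net``; the identity ``v_f - v_b = v_net`` holds exactly.  Negative
    exchange values, or negative net values on irreversible reactions, are
    rejected.
    """
    v_xch = dict(v_xch or {})
    out: Dict[str, float] = {}
    for rid, rxn in net.reactions.items():
        vn = float(v_net[rid])
        if rxn.reversible:
            xch = float(v_xch.pop(rid, 0.0))
            if xch < 0:
                raise NetworkError(f"{rid}: negative exchange flux {xch}")
            fwd = vn + xch if vn >= 0 else xch
            out[rid + "_f"] = fwd
            out[rid + "_b"] = fwd - vn
        else:
            if vn < -1e-12:
                raise NetworkError(f"{rid}: negative net flux {vn} on "
                                   "irreversible reaction")
            if rid in v_xch:
                raise NetworkError(f"{rid}: exchange flux given for "
                                   "irreversible reaction")
            out[rid] = max(vn, 0.0)
    if v_xch:
        raise NetworkError(f"exchange fluxes for unknown reactions: {sorted(v_xch)}")
    return FluxDistribution(out)


@dataclass
class ValidationReport:
    ok: bool
    dead_end_metabolites: List[str] = field(default_factory=list)
    carbon_unbalanced_reactions: List[str] = field(default_factory=list)
    unmapped_reactions: List[str] = field(default_factory=list)

    def __str__(self):
        lines = [f"network validation: {'ok' if self.ok else 'FAIL'}"]
        if self.dead_end_metabolites:
            lines.append(f"  dead-end balanced metabolites: "
                         f"{', '.join(self.dead_end_metabolites)}")
        if self.carbon_unbalanced_reactions:
            lines.append(f"  carbon-unbalanced reactions: "
                         f"{', '.join(self.carbon_unbalanced_reactions)}")
        if self.unmapped_reactions:
            lines.append(f"  reactions without atom maps: "
                         f"{', '.join(self.unmapped_reactions)}")
        return "\n".join(lines)


def validate_network(net: MetabolicNetwork) -> ValidationReport:
    """Report-only sanity checks: dead ends, unbalanced/unmapped reactions."""
    produced = set()
    consumed = set()
    for rxn in net.reactions.values():
        subs = {m for m, _, _ in rxn.substrates}
        prods = {m for m, _, _ in rxn.products}
        consumed |= subs
        produced |= prods
        if rxn.reversible:
            consumed |= prods
            produced |= subs
    dead = sorted(m.id for m in net.metabolites.values()
                  if m.is_balanced and not
                  (m.id in produced and m.id in consumed))
    unbal = sorted(r.id for r in net.reactions.values() if not r.carbon_checked)
    unmapped = sorted(r.id for r in net.reactions.values() if not r.has_atom_maps)
    return ValidationReport(ok=not dead, dead_end_metabolites=dead,
                            carbon_unbalanced_reactions=unbal,
                            unmapped_reactions=unmapped)
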