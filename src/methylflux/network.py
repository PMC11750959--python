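"""Stoichiometric reaction networks.

A :class:`ReactionNetwork` holds metabolites, reactions and the dense
stoichiometric matrix ``S`` (rows = metabolites in declaration order,
columns = reactions in declaration order).  Internal metabolites are the
ones subject to the steady-state constraint ``S_int @ v = 0``; boundary
(external) species are exempt.

Two on-disk formats are supported: a plain TSV reaction table (the
first-class fixture format) and a read-only subset of SBML Level 3 core
(species, reactions, stoichiometry, reversibility, boundaryCondition;
kinetic laws are ignored).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionNetwork",
    "NetworkError",
    "load_network",
    "parse_equation",
    "format_equation",
    "build_stoichiometric_matrix",
]


class NetworkError(ValueError):
    """Malformed network definition (duplicate ids, unknown metabolites...)."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_internal: bool = True


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed).

    ``lower_bound``/``upper_bound`` are flux bounds in mmol·gDW⁻¹·day⁻¹.
    Reversibility is encoded purely through the bounds: an irreversible
    reaction must have ``lower_bound >= 0``.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = True
    lower_bound: float = -math.inf
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise NetworkError(
                f"reaction {self.id!r}: irreversible but lower_bound < 0"
            )


@dataclass
class ReactionNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    S: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise NetworkError(f"duplicate {label} id(s): {sorted(dupes)}")
        if not self.metabolites or not self.reactions:
            raise NetworkError("empty network")
        if not any(m.is_internal for m in self.metabolites):
            raise NetworkError("network needs at least one internal metabolite")
        known = set(met_ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise NetworkError(
                    f"reaction {r.id!r}: unknown metabolite {sorted(unknown)}"
                )
        self.S = build_stoichiometric_matrix(self)

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise NetworkError(f"unknown metabolite {metabolite_id!r}") from None

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise NetworkError(f"unknown reaction {reaction_id!r}") from None

    @property
    def internal_mask(self) -> np.ndarray:
        return np.array([m.is_internal for m in self.metabolites], dtype=bool)

    @property
    def S_internal(self) -> np.ndarray:
        """Rows of S restricted to internal (steady-state) metabolites."""
        return self.S[self.internal_mask]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- serialization ---------------------------------------------------
    def to_reaction_table(self, path: str | Path | None = None) -> str:
        """Serialize to the TSV reaction-table format (round-trippable)."""
        lines = ["# metabolite\tid\tname\tis_internal"]
        for m in self.metabolites:
            lines.append(f"metabolite\t{m.id}\t{m.name}\t{int(m.is_internal)}")
        lines.append("# reaction\tid\tequation\treversible\tlb\tub")
        for r in self.reactions:
            lines.append(
                f"reaction\t{r.id}\t{format_equation(r.stoichiometry)}\t"
                f"{int(r.reversible)}\t{_fmt_bound(r.lower_bound)}\t"
                f"{_fmt_bound(r.upper_bound)}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def build_stoichiometric_matrix(
    network: ReactionNetwork,
) -> np.ndarray:
    """Dense S with rows ordered by metabolite declaration, columns by reaction."""
    index = {m.id: i for i, m in enumerate(network.metabolites)}
    S = np.zeros((len(network.metabolites), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[index[met_id], j] = coeff
    return S


# ---------------------------------------------------------------------------
# equation strings:  "2 A + B -> C"  /  "A <-> B"
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into a signed stoichiometry map.

    Returns ``(stoichiometry, reversible)`` where reversible is True for
    ``<->``/``<=>`` arrows.  A side may be empty (exchange reactions),
    e.g. ``"-> A"`` or ``"B ->"``.
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise NetworkError(f"no reaction arrow in equation {equation!r}")
    reversible = arrow in ("<->", "<=>")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"empty term in equation {equation!r}")
            m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
            if m is None:
                raise NetworkError(f"cannot parse term {term!r} in {equation!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            stoich[m.group(2)] = stoich.get(m.group(2), 0.0) + sign * coeff

    _accumulate(left, -1.0)
    _accumulate(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise NetworkError(f"equation {equation!r} has no net stoichiometry")
    return stoich, reversible


def format_equation(stoichiometry: dict[str, float]) -> str:
    def _side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, c in items:
            parts.append(met if c == 1.0 else f"{c:g} {met}")
        return " + ".join(parts)

    lhs = [(m, -c) for m, c in stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in stoichiometry.items() if c > 0]
    return f"{_side(lhs)} -> {_side(rhs)}"


def _fmt_bound(x: float) -> str:
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    return f"{x:g}"


def _parse_bound(tok: str) -> float:
    return float(tok)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_network(source: str | Path, format: str = "auto") -> ReactionNetwork:
    """Load a :class:`ReactionNetwork` from a reaction-table TSV or SBML file.

    ``source`` may be a path or the raw text itself.  With ``format="auto"``
    the format is sniffed (an XML declaration or ``<sbml`` tag means SBML).
    """
    text = None
    path = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        path = Path(source)
        text = path.read_text()
    else:
        text = str(source)

    if format == "auto":
        head = text.lstrip()[:200].lower()
        format = "sbml" if head.startswith("<?xml") or "<sbml" in head else "reaction-table"
    if format == "sbml":
        return _load_sbml(text)
    if format == "reaction-table":
        return _load_reaction_table(text)
    raise ValueError(f"unknown network format {format!r}")


def _load_reaction_table(text: str) -> ReactionNetwork:
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    declared_mets: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "metabolite":
            if len(fields) < 2:
                raise NetworkError(f"line {lineno}: metabolite row needs an id")
            name = fields[2] if len(fields) > 2 else ""
            internal = bool(int(fields[3])) if len(fields) > 3 else True
            metabolites.append(Metabolite(fields[1], name, internal))
            declared_mets.add(fields[1])
        elif kind == "reaction":
            if len(fields) < 3:
                raise NetworkError(f"line {lineno}: reaction row needs id+equation")
            rid, equation = fields[1], fields[2]
            stoich, rev_from_arrow = parse_equation(equation)
            reversible = (
                bool(int(fields[3])) if len(fields) > 3 and fields[3] != ""
                else rev_from_arrow
            )
            lb = _parse_bound(fields[4]) if len(fields) > 4 and fields[4] != "" else (
                -math.inf if reversible else 0.0
            )
            ub = _parse_bound(fields[5]) if len(fields) > 5 and fields[5] != "" else math.inf
            reactions.append(Reaction(rid, stoich, reversible, lb, ub))
        else:
            raise NetworkError(f"line {lineno}: unknown row kind {kind!r}")
    # metabolites used but never declared get a strict error so typos surface
    used = {m for r in reactions for m in r.stoichiometry}
    unknown = used - declared_mets
    if unknown:
        raise NetworkError(f"unknown metabolite {sorted(unknown)}")
    return ReactionNetwork(metabolites, reactions)


def _load_sbml(text: str) -> ReactionNetwork:
    import libsbml

    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise NetworkError("SBML parse error: " + "; ".join(msgs))
    model = doc.getModel()
    if model is None:
        raise NetworkError("SBML document has no model")
    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        metabolites.append(
            Metabolite(
                sp.getId(),
                sp.getName() or "",
                is_internal=not sp.getBoundaryCondition(),
            )
        )
    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        reversible = rx.getReversible()
        reactions.append(
            Reaction(
                rx.getId(),
                stoich,
                reversible=reversible,
                lower_bound=-math.inf if reversible else 0.0,
                upper_bound=math.inf,
            )
        )
    return ReactionNetwork(metabolites, reactions)
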