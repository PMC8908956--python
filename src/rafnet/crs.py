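"""Catalytic reaction systems (CRS) and foodset reachability.

A CRS is the tuple Q = (X, R, C, F): a set ``X`` of element types, a set
``R`` of reactions, a catalysis assignment ``C`` (stored per reaction as
the set of element types that catalyze it) and a foodset ``F ⊆ X`` of
elements present at the start.  Reactants and products are multisets of
element names, but *availability* is set-based: once an element is
producible it is available in any multiplicity.  This matches the
cognitive reading in which elements are non-consumed resources (a mental
representation is not used up by thinking with it); stoichiometric
accounting is deliberately out of scope.

The module also defines a line-based plain-text CRS format::

    # comment
    elements: a, b, c      # optional, repeatable; union of all lines
    food: a, b             # required, repeatable; union of all lines
    r1: a + b -> ab [c]    # reaction; catalyst bracket optional

and the reachability primitive :func:`producible_closure` on which every
RAF algorithm is built.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

__all__ = [
    "TOKEN_RE",
    "CRSError",
    "CRSFormatError",
    "ElementType",
    "Reaction",
    "CRS",
    "parse_crs",
    "write_crs",
    "producible_closure",
    "is_f_generated",
]

TOKEN_RE = re.compile(r"^[A-Za-z0-9_]+$")


class CRSError(ValueError):
    """A structurally invalid CRS (bad reference, duplicate id, ...)."""


class CRSFormatError(CRSError):
    """A malformed CRS document; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_token(name: str, what: str, line: int | None = None) -> str:
    if not TOKEN_RE.match(name):
        raise CRSFormatError(f"invalid {what} {name!r}: tokens are non-empty "
                             "strings over [A-Za-z0-9_]", line)
    return name


@dataclass(frozen=True)
class ElementType:
    """A member of the element set X, identified by a unique token name."""

    name: str

    def __post_init__(self) -> None:
        _check_token(self.name, "element name")


@dataclass(frozen=True)
class Reaction:
    """One reaction: reactant multiset -> product multiset, with catalysts.

    ``reactants`` and ``products`` are stored as sorted tuples so that
    repeated names (multiset multiplicity) survive round-trips; catalysis
    is by element type only, so ``catalysts`` is a plain set of names.  An
    empty catalyst set is legal — such a reaction can belong to the CRS
    but can never satisfy the reflexively-autocatalytic condition, so it
    cannot be part of any RAF.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    catalysts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        _check_token(self.id, "reaction id")
        if not self.reactants or not self.products:
            raise CRSError(f"reaction {self.id!r}: reactants and products "
                           "must be non-empty")
        object.__setattr__(self, "reactants", tuple(sorted(self.reactants)))
        object.__setattr__(self, "products", tuple(sorted(self.products)))
        object.__setattr__(self, "catalysts", frozenset(self.catalysts))
        for name in (*self.reactants, *self.products, *self.catalysts):
            _check_token(name, "element name")

    def referenced(self) -> frozenset[str]:
        """All element names this reaction mentions."""
        return frozenset(self.reactants) | frozenset(self.products) | self.catalysts


@dataclass(frozen=True)
class CRS:
    """A catalytic reaction system Q = (X, R, C, F).

    Elements are identified by name; ``elements`` is the name set X,
    ``food`` the foodset F ⊆ X.  Reactions are kept sorted by id and all
    iteration in this package follows that order, so derived quantities
    are bit-stable across runs.
    """

    elements: frozenset[str]
    reactions: tuple[Reaction, ...]
    food: frozenset[str]

    def __init__(self,
                 elements: Iterable[str | ElementType],
                 reactions: Iterable[Reaction],
                 food: Iterable[str | ElementType]):
        names = frozenset(e.name if isinstance(e, ElementType) else e
                          for e in elements)
        food_names = frozenset(e.name if isinstance(e, ElementType) else e
                               for e in food)
        rxns = tuple(sorted(reactions, key=lambda r: r.id))
        object.__setattr__(self, "elements", names)
        object.__setattr__(self, "reactions", rxns)
        object.__setattr__(self, "food", food_names)
        self._validate()

    def _validate(self) -> None:
        for name in sorted(self.elements):
            _check_token(name, "element name")
        missing = self.food - self.elements
        if missing:
            raise CRSError(f"food elements not declared: {sorted(missing)}")
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise CRSError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            undeclared = r.referenced() - self.elements
            if undeclared:
                raise CRSError(f"reaction {r.id!r} references undeclared "
                               f"elements: {sorted(undeclared)}")

    @cached_property
    def reaction_map(self) -> Mapping[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(self.reaction_map)

    def subsystem(self, reaction_ids: Iterable[str]) -> "CRS":
        """The CRS restricted to a subset of its reactions (same X and F)."""
        wanted = self._resolve(reaction_ids)
        return CRS(self.elements,
                   [r for r in self.reactions if r.id in wanted],
                   self.food)

    def with_food(self, food: Iterable[str]) -> "CRS":
        """The same CRS with a different foodset."""
        return CRS(self.elements, self.reactions, food)

    def _resolve(self, reaction_ids: Iterable[str]) -> frozenset[str]:
        wanted = frozenset(reaction_ids)
        unknown = wanted - self.reaction_ids
        if unknown:
            raise CRSError(f"unknown reaction ids: {sorted(unknown)}")
        return wanted

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CRS):
            return NotImplemented
        return (self.elements == other.elements
                and self.reactions == other.reactions
                and self.food == other.food)

    def __hash__(self) -> int:
        return hash((self.elements, self.reactions, self.food))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"CRS(|X|={len(self.elements)}, |R|={len(self.reactions)}, "
                f"|F|={len(self.food)})")


# ---------------------------------------------------------------------------
# plain-text format

_REACTION_LINE = re.compile(
    r"^(?P<id>[A-Za-z0-9_]+)\s*:\s*(?P<lhs>[^->\[\]]+)->"
    r"\s*(?P<rhs>[^\[\]]+?)\s*(?:\[(?P<cats>[^\]]*)\])?\s*$")


def _split_names(chunk: str, line: int) -> list[str]:
    names = [t.strip() for t in chunk.split(",")]
    names = [t for t in names if t]
    return [_check_token(t, "element name", line) for t in names]


def _split_terms(chunk: str, line: int) -> list[str]:
    terms = [t.strip() for t in chunk.split("+")]
    if any(not t for t in terms):
        raise CRSFormatError("empty term in reaction side", line)
    return [_check_token(t, "element name", line) for t in terms]


def parse_crs(text: str, implicit_elements: bool = False) -> CRS:
    """Parse a CRS document.

    By default every element must be declared on an ``elements:`` or
    ``food:`` line and an undeclared name in a reaction is an error (this
    catches typos).  With ``implicit_elements=True`` any name used in a
    reaction is auto-declared.

    Raises :class:`CRSFormatError` naming the offending line.
    """
    declared: set[str] = set()
    food: set[str] = set()
    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    saw_food_line = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, sep, rest = line.partition(":")
        head = head.strip()
        if not sep:
            raise CRSFormatError(f"cannot parse {raw.strip()!r}", lineno)
        if head == "elements":
            declared.update(_split_names(rest, lineno))
            continue
        if head == "food":
            names = _split_names(rest, lineno)
            food.update(names)
            declared.update(names)
            saw_food_line = True
            continue
        m = _REACTION_LINE.match(line)
        if m is None:
            raise CRSFormatError(f"malformed reaction line {raw.strip()!r}",
                                 lineno)
        rid = m.group("id")
        if rid in seen_ids:
            raise CRSFormatError(f"duplicate reaction id {rid!r}", lineno)
        seen_ids.add(rid)
        cats = _split_names(m.group("cats") or "", lineno)
        try:
            rxn = Reaction(id=rid,
                           reactants=tuple(_split_terms(m.group("lhs"), lineno)),
                           products=tuple(_split_terms(m.group("rhs"), lineno)),
                           catalysts=frozenset(cats))
        except CRSError as exc:
            raise CRSFormatError(str(exc), lineno) from exc
        used = rxn.referenced() - declared
        if used and not implicit_elements:
            raise CRSFormatError(
                f"reaction {rid!r} uses undeclared elements "
                f"{sorted(used)} (declare them, or parse with "
                "implicit_elements=True)", lineno)
        declared.update(used)
        reactions.append(rxn)

    if not saw_food_line:
        raise CRSFormatError("no food line")
    return CRS(declared, reactions, food)


def write_crs(crs: CRS) -> str:
    """Serialize a CRS to canonical text: elements line, food line, then
    reactions sorted by id with single spaces.  ``parse_crs(write_crs(q))``
    equals ``q``.
    """
    lines = []
    if crs.elements:
        lines.append("elements: " + ", ".join(sorted(crs.elements)))
    lines.append("food: " + ", ".join(sorted(crs.food)))
    for r in crs.reactions:
        line = (f"{r.id}: " + " + ".join(r.reactants)
                + " -> " + " + ".join(r.products))
        if r.catalysts:
            line += " [" + ", ".join(sorted(r.catalysts)) + "]"
        lines.append(line)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reachability

def producible_closure(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """Elements generable from the foodset through reactions in ``subset``.

    The smallest superset W of F such that every reaction in the subset
    with all reactants in W contributes its products to W.  Catalysis is
    ignored here: this is pure reachability, the F-generated condition is
    layered on top of it.  The result is a fixed point, idempotent, and
    monotone in both F and the subset.
    """
    wanted = crs._resolve(subset)
    pending = [r for r in crs.reactions if r.id in wanted]
    available = set(crs.food)
    changed = True
    while changed and pending:
        changed = False
        still = []
        for r in pending:
            if all(x in available for x in r.reactants):
                available.update(r.products)
                changed = True
            else:
                still.append(r)
        pending = still
    return frozenset(available)


def is_f_generated(crs: CRS, subset: Iterable[str]) -> bool:
    """True iff every reactant of every reaction in ``subset`` lies in
    ``producible_closure(crs, subset)`` — i.e. the subset can be fired up
    from the foodset alone.  Vacuously true for the empty subset.
    """
    wanted = crs._resolve(subset)
    closure = producible_closure(crs, wanted)
    return all(x in closure
               for r in crs.reactions if r.id in wanted
               for x in r.reactants)
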