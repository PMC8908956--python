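"""Provenance-tagged cultural-lineage events over conceptual networks.

Each individual *i* carries a conceptual network split into two disjoint
sets of mental representations (MRs): the foodset F_i (MRs that are
innate, or acquired by social or individual learning of pre-existing
information) and the foodset-derived set ¬F_i (MRs generated by the
individual's own creative thought).  Three event kinds update the state:

- ``social``   — F_i ↦ F_i ∪ {c}, with c learned from an MR possessed by
  a named source individual.  A creative product transmitted socially is
  *re-tagged*: it enters the recipient's foodset even though it sits in
  the sender's foodset-derived set, because for the recipient it is
  pre-existing information.
- ``individual`` — F_i ↦ F_i ∪ {c}: non-social assimilation of
  pre-existing information from the environment.
- ``creative`` — ¬F_i ↦ ¬F_i ∪ {c}: a mental operation a → c or
  a + a' → c, catalyzed by one or more MRs b (a need, desire or piece of
  knowledge) that the actor already possesses.  Written a →_b c; both
  reactants and catalysts must already be in F_i ∪ ¬F_i.

MRs are never consumed — the semantics is catalytic and
non-stoichiometric; events only ever add MRs.  A per-MR provenance
ledger records where each MR came from, so any creative product can be
traced back through its reactant ancestry to foodset items, and an
actor's history projects onto a CRS whose reactions are their creative
events — making the RAF machinery applicable to conceptual networks.

Lineages serialize to a TSV dialect with columns
``step kind actor inputs catalysts outputs source`` (``;``-separated MR
ids within a cell, ``-`` for empty); row order is the single source of
temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from rafnet.crs import CRS, Reaction, TOKEN_RE

__all__ = [
    "Provenance",
    "MentalRepresentation",
    "IndividualState",
    "LineageEvent",
    "LineageError",
    "Lineage",
    "apply_event",
    "run_lineage",
    "lineage_to_crs",
    "trace_origin",
    "read_lineage_tsv",
    "write_lineage_tsv",
]


class Provenance(str, Enum):
    """How an MR entered an individual's conceptual network."""

    INNATE = "innate"
    SOCIAL = "social"
    INDIVIDUAL = "individual"
    CREATIVE = "creative"


#: provenances that place an MR in the foodset rather than ¬F
FOODSET_PROVENANCES = frozenset(
    {Provenance.INNATE, Provenance.SOCIAL, Provenance.INDIVIDUAL})


class LineageError(ValueError):
    """An event that violates lineage preconditions; carries the step."""

    def __init__(self, message: str, step: int | None = None):
        self.step = step
        if step is not None:
            message = f"step {step}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MentalRepresentation:
    """One provenance-tagged MR in some individual's network."""

    id: str
    owner: str
    provenance: Provenance
    label: str = ""
    source: str | None = None
    derived_from: frozenset[str] = frozenset()
    catalyzed_by: frozenset[str] = frozenset()
    step: int | None = None

    def __post_init__(self) -> None:
        if self.provenance is Provenance.SOCIAL and self.source is None:
            raise LineageError(f"MR {self.id!r}: social provenance requires "
                               "a source individual")
        if self.provenance is Provenance.CREATIVE and not self.derived_from:
            raise LineageError(f"MR {self.id!r}: creative provenance requires "
                               "non-empty derived_from")


@dataclass
class IndividualState:
    """One individual's conceptual network: foodset F_i and derived ¬F_i."""

    id: str
    foodset: set[str] = field(default_factory=set)
    derived: set[str] = field(default_factory=set)

    def possesses(self, mr_id: str) -> bool:
        return mr_id in self.foodset or mr_id in self.derived

    @property
    def all_mrs(self) -> frozenset[str]:
        return frozenset(self.foodset | self.derived)


@dataclass(frozen=True)
class LineageEvent:
    """One social-learning, individual-learning, or creative-thought step.

    ``inputs`` for a creative event are the reactants a_k (and a'_k); for
    a social event they name the MRs, possessed by ``source``, that the
    transmission copies.  ``catalysts`` (creative only) are the enabling
    MRs b_k; ``outputs`` are the new MR ids c_k added to the actor.
    """

    step: int
    kind: str  # "social" | "individual" | "creative"
    actor: str
    outputs: tuple[str, ...]
    inputs: tuple[str, ...] = ()
    catalysts: tuple[str, ...] = ()
    source: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("social", "individual", "creative"):
            raise LineageError(f"unknown event kind {self.kind!r}", self.step)
        if not self.outputs:
            raise LineageError("event has no outputs", self.step)
        for tok in (self.actor, *self.outputs, *self.inputs, *self.catalysts):
            if not TOKEN_RE.match(tok):
                raise LineageError(f"invalid token {tok!r}", self.step)
        if self.kind == "creative" and (not self.inputs or not self.catalysts):
            raise LineageError("creative event requires inputs and catalysts",
                               self.step)
        if self.kind == "social" and self.source is None:
            raise LineageError("social event requires a source individual",
                               self.step)


@dataclass
class Lineage:
    """Result of running an event sequence: final per-individual states,
    the per-MR provenance ledger, and the events themselves."""

    states: dict[str, IndividualState] = field(default_factory=dict)
    ledger: dict[str, MentalRepresentation] = field(default_factory=dict)
    events: list[LineageEvent] = field(default_factory=list)

    def state(self, individual: str) -> IndividualState:
        if individual not in self.states:
            raise LineageError(f"unknown individual {individual!r}")
        return self.states[individual]


def _get_or_create(states: dict[str, IndividualState],
                   individual: str) -> IndividualState:
    if individual not in states:
        states[individual] = IndividualState(individual)
    return states[individual]


def apply_event(lineage: Lineage, event: LineageEvent) -> Lineage:
    """Apply one event in place, enforcing all preconditions.

    Social and individual events grow the actor's foodset; creative
    events grow the actor's derived set.  An output id already present
    anywhere in the lineage is rejected — MR ids are global, one per
    (individual, content) pair, which is what makes cross-individual
    tracing unambiguous.
    """
    actor = _get_or_create(lineage.states, event.actor)

    if event.kind == "creative":
        for mr_id in (*event.inputs, *event.catalysts):
            if not actor.possesses(mr_id):
                raise LineageError(
                    f"creative event by {event.actor!r} needs {mr_id!r}, "
                    "which the actor does not possess (no reachable stream "
                    "of thought)", event.step)
    elif event.kind == "social":
        if event.source not in lineage.states:
            raise LineageError(f"social event sources from unknown "
                               f"individual {event.source!r}", event.step)
        src = lineage.states[event.source]
        for mr_id in event.inputs:
            if not src.possesses(mr_id):
                raise LineageError(
                    f"social event sources {mr_id!r}, which {event.source!r} "
                    "does not possess", event.step)

    for out in event.outputs:
        if out in lineage.ledger:
            raise LineageError(f"MR id {out!r} already exists", event.step)

    provenance = {"social": Provenance.SOCIAL,
                  "individual": Provenance.INDIVIDUAL,
                  "creative": Provenance.CREATIVE}[event.kind]
    for out in event.outputs:
        mr = MentalRepresentation(
            id=out,
            owner=event.actor,
            provenance=provenance,
            source=event.source if event.kind == "social" else None,
            derived_from=frozenset(event.inputs),
            catalyzed_by=frozenset(event.catalysts),
            step=event.step)
        lineage.ledger[out] = mr
        # re-tag rule: whatever the sender's tag, a socially transmitted MR
        # is pre-existing information for the recipient -> foodset
        if provenance is Provenance.CREATIVE:
            actor.derived.add(out)
        else:
            actor.foodset.add(out)
    lineage.events.append(event)
    return lineage


def run_lineage(events: Sequence[LineageEvent]) -> Lineage:
    """Run an ordered event sequence from an empty state.

    Events must be in non-decreasing step order (several events may share
    one step ordinal).  Any precondition failure propagates with the
    failing step number attached.
    """
    lineage = Lineage()
    last_step: int | None = None
    for ev in events:
        if last_step is not None and ev.step < last_step:
            raise LineageError(
                f"events out of order: step {ev.step} after {last_step}",
                ev.step)
        last_step = ev.step
        apply_event(lineage, ev)
    return lineage


def lineage_to_crs(lineage: Lineage, actor: str) -> CRS:
    """Project one actor's history onto a CRS.

    Elements are all MRs the actor possesses, the foodset is F_actor, and
    there is one reaction per creative event of the actor (reactants =
    inputs, products = outputs, catalysts as recorded).  Reaction ids are
    ``s<step>_<first output>``.  The RAF machinery then applies: a
    possible stream of thought from the foodset to an MR is exactly
    F-generation, and catalysis by possessed MRs is the RA condition.
    """
    state = lineage.state(actor)
    reactions = []
    for ev in lineage.events:
        if ev.actor != actor or ev.kind != "creative":
            continue
        reactions.append(Reaction(id=f"s{ev.step}_{ev.outputs[0]}",
                                  reactants=ev.inputs,
                                  products=ev.outputs,
                                  catalysts=frozenset(ev.catalysts)))
    return CRS(state.all_mrs, reactions, state.foodset)


@dataclass(frozen=True)
class TraceNode:
    """One link in a provenance chain."""

    mr_id: str
    individual: str
    provenance: Provenance
    step: int | None
    parents: frozenset[str]


def trace_origin(lineage: Lineage, mr_id: str) -> list[TraceNode]:
    """Trace an MR back to foodset items, across individuals.

    Follows ``derived_from`` for creative MRs and the source individual's
    copy for social MRs, breadth-first.  Returns the chain as TraceNodes
    in visit order, starting at ``mr_id``; a foodset MR with no ancestry
    yields a single node (chain of length 0 beyond itself).  The chain is
    finite and acyclic and terminates only in non-creative MRs.
    """
    if mr_id not in lineage.ledger:
        raise LineageError(f"unknown MR {mr_id!r}")
    out: list[TraceNode] = []
    seen: set[str] = set()
    frontier = [mr_id]
    active: set[str] = set()
    while frontier:
        current = frontier.pop(0)
        if current in seen:
            continue
        seen.add(current)
        mr = lineage.ledger[current]
        parents = frozenset(mr.derived_from)
        out.append(TraceNode(mr.id, mr.owner, mr.provenance, mr.step, parents))
        for p in sorted(parents):
            if p in active:
                raise LineageError(f"provenance cycle at {p!r}")
            if p in lineage.ledger:
                frontier.append(p)
    return out


# ---------------------------------------------------------------------------
# TSV dialect

_COLUMNS = ("step", "kind", "actor", "inputs", "catalysts", "outputs",
            "source")


def _join(cell: Iterable[str]) -> str:
    items = list(cell)
    return ";".join(items) if items else "-"


def _split(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell or cell == "-":
        return ()
    return tuple(t.strip() for t in cell.split(";") if t.strip())


def write_lineage_tsv(events: Sequence[LineageEvent]) -> str:
    lines = ["\t".join(_COLUMNS)]
    for ev in events:
        lines.append("\t".join([
            str(ev.step), ev.kind, ev.actor, _join(ev.inputs),
            _join(ev.catalysts), _join(ev.outputs), ev.source or "-"]))
    return "\n".join(lines) + "\n"


def read_lineage_tsv(text: str) -> list[LineageEvent]:
    """Parse the lineage TSV dialect; ``#`` lines and blanks are skipped."""
    events: list[LineageEvent] = []
    rows = [ln for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        return events
    header = tuple(c.strip() for c in rows[0].split("\t"))
    if header != _COLUMNS:
        raise LineageError(f"bad lineage header {header!r}, "
                           f"expected {_COLUMNS!r}")
    for lineno, row in enumerate(rows[1:], start=2):
        cells = row.split("\t")
        if len(cells) != len(_COLUMNS):
            raise LineageError(f"row {lineno}: expected {len(_COLUMNS)} "
                               f"columns, got {len(cells)}")
        step_s, kind, actor, inputs, catalysts, outputs, source = cells
        events.append(LineageEvent(
            step=int(step_s),
            kind=kind.strip(),
            actor=actor.strip(),
            inputs=_split(inputs),
            catalysts=_split(catalysts),
            outputs=_split(outputs),
            source=None if source.strip() in ("", "-") else source.strip()))
    return events
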