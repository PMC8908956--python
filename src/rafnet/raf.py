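"""RAF decision and structure algorithms.

A RAF of a CRS Q = (X, R, C, F) is a non-empty subset R' ⊆ R that is

- *reflexively autocatalytic* (RA): every reaction in R' has at least one
  catalyst in F ∪ products(R'); and
- *F-generated*: every reactant of R' is producible from F through R'.

The set of all RAFs of a CRS, ordered by inclusion, is a poset whose
unique maximal element (when any RAF exists) is the *maxRAF*; the union
of any two RAFs is again a RAF, which is why the maximum is unique.  The
maxRAF is computed by the standard alternating fixed-point reduction:
prune reactions whose reactants fall outside the producible closure of
the survivors, prune reactions with no available catalyst, repeat until
stable.  Both prunes only ever remove reactions that belong to no RAF,
so the fixed point is the maxRAF regardless of prune order.

On top of the maxRAF the module computes closed RAFs and closures,
irreducible RAFs (irrRAFs: RAFs containing no smaller RAF), co-RAFs, and
union decomposability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from rafnet.crs import CRS, producible_closure

__all__ = [
    "RAFResult",
    "IrrRAFReport",
    "products_of",
    "is_raf",
    "max_raf",
    "max_raf_within",
    "is_closed_raf",
    "closure_of_subraf",
    "is_co_raf",
    "find_irr_rafs",
    "is_union_decomposable",
    "EXHAUSTIVE_SIZE_CAP",
]

#: Largest reaction count for which exhaustive subset enumeration
#: (2^|R| - 1 candidate subsets) is attempted; 12 keeps it well under a
#: second while still covering every fixture the test oracles use.
EXHAUSTIVE_SIZE_CAP = 12


@dataclass(frozen=True)
class RAFResult:
    """Outcome of a maxRAF computation.

    ``reaction_ids`` is empty exactly when the CRS has no RAF at all
    (reported as a distinct status, not an error); ``iterations`` counts
    fixed-point sweeps until stabilization.
    """

    reaction_ids: frozenset[str]
    iterations: int

    @property
    def is_empty(self) -> bool:
        return not self.reaction_ids

    def __len__(self) -> int:
        return len(self.reaction_ids)


def products_of(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """Union of the product multisets of the given reactions (as a set)."""
    wanted = crs._resolve(subset)
    out: set[str] = set()
    for r in crs.reactions:
        if r.id in wanted:
            out.update(r.products)
    return frozenset(out)


def is_raf(crs: CRS, subset: Iterable[str]) -> bool:
    """Decide the RAF property for a reaction subset.

    True iff the subset is non-empty, F-generated, and every member
    reaction has at least one catalyst in F ∪ products(subset).
    """
    wanted = crs._resolve(subset)
    if not wanted:
        return False
    closure = producible_closure(crs, wanted)
    available = crs.food | products_of(crs, wanted)
    for r in crs.reactions:
        if r.id not in wanted:
            continue
        if not all(x in closure for x in r.reactants):
            return False
        if not r.catalysts & available:
            return False
    return True


def max_raf(crs: CRS) -> RAFResult:
    """The unique maximal RAF of the CRS (empty if none exists).

    Alternating fixed point: starting from all of R, repeatedly remove
    reactions whose reactants are outside the producible closure of the
    current survivors, then reactions with no catalyst in F ∪ products of
    the survivors, until neither prune removes anything.  Every RAF of
    the CRS survives both prunes, so the fixed point contains every RAF
    and is itself a RAF whenever it is non-empty.
    """
    return max_raf_within(crs, crs.reaction_ids)


def max_raf_within(crs: CRS, subset: Iterable[str]) -> RAFResult:
    """maxRAF of the sub-network restricted to ``subset`` (same X and F)."""
    survivors = set(crs._resolve(subset))
    iterations = 0
    changed = True
    while changed:
        changed = False
        iterations += 1
        closure = producible_closure(crs, survivors)
        for rid in sorted(survivors):
            r = crs.reaction_map[rid]
            if not all(x in closure for x in r.reactants):
                survivors.discard(rid)
                changed = True
        available = crs.food | products_of(crs, survivors)
        for rid in sorted(survivors):
            r = crs.reaction_map[rid]
            if not r.catalysts & available:
                survivors.discard(rid)
                changed = True
    return RAFResult(frozenset(survivors), iterations)


def _require_raf(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    wanted = crs._resolve(subset)
    if not is_raf(crs, wanted):
        raise ValueError(f"subset {sorted(wanted)} is not a RAF of this CRS")
    return wanted


def is_closed_raf(crs: CRS, subset: Iterable[str]) -> bool:
    """Whether a RAF is *closed*: it already contains every reaction of
    the full network whose reactants are all available from it and which
    has at least one catalyst available from it (availability meaning
    F ∪ products of the RAF).  A RAF that is not closed is *transient* —
    left to itself it would accrete the missing reactions.  The maxRAF is
    always closed.
    """
    raf = _require_raf(crs, subset)
    available = crs.food | products_of(crs, raf)
    for r in crs.reactions:
        if r.id in raf:
            continue
        if (all(x in available for x in r.reactants)
                and r.catalysts & available):
            return False
    return True


def closure_of_subraf(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """The closure of a subRAF: iteratively add every network reaction
    whose reactants and at least one catalyst are available from the
    current set, until stable.  Contains its argument, is a closed RAF,
    and is idempotent.
    """
    current = set(_require_raf(crs, subset))
    changed = True
    while changed:
        changed = False
        available = crs.food | products_of(crs, current)
        for r in crs.reactions:
            if r.id in current:
                continue
            if (all(x in available for x in r.reactants)
                    and r.catalysts & available):
                current.add(r.id)
                changed = True
    return frozenset(current)


def is_co_raf(crs: CRS, raf: Iterable[str], candidate: Iterable[str]) -> bool:
    """Whether ``candidate`` is a co-RAF of ``raf``: a non-empty reaction
    set, disjoint from the RAF, that is not a RAF on its own but forms
    one when united with it.
    """
    base = _require_raf(crs, raf)
    cand = crs._resolve(candidate)
    if cand & base:
        raise ValueError("candidate must be disjoint from the RAF")
    if not cand:
        return False
    return not is_raf(crs, cand) and is_raf(crs, base | cand)


# ---------------------------------------------------------------------------
# irreducible RAFs

@dataclass(frozen=True)
class IrrRAFReport:
    """Irreducible RAFs found, and (in exhaustive mode) whether the
    network has a unique irrRAF.  ``unique`` is None in sampling mode,
    which may miss irrRAFs."""

    irr_rafs: tuple[frozenset[str], ...]
    exhaustive: bool
    unique: bool | None


def _all_sub_rafs(crs: CRS, within: frozenset[str]) -> list[frozenset[str]]:
    """Every non-empty RAF subset of ``within`` (exhaustive enumeration)."""
    ids = sorted(within)
    found: list[frozenset[str]] = []
    for k in range(1, len(ids) + 1):
        for combo in combinations(ids, k):
            s = frozenset(combo)
            if is_raf(crs, s):
                found.append(s)
    return found


def find_irr_rafs(crs: CRS,
                  mode: str = "exhaustive",
                  seed: int | None = None,
                  restarts: int = 100) -> IrrRAFReport:
    """Irreducible RAFs: RAFs that cannot be broken into smaller RAFs.

    ``mode="exhaustive"`` enumerates every reaction subset (refused when
    |R| exceeds :data:`EXHAUSTIVE_SIZE_CAP`), returns all irrRAFs and
    reports whether the irrRAF is unique.  ``mode="sample"`` performs
    seeded randomized single-reaction contraction from the maxRAF
    (remove one reaction, take the maxRAF of the remainder, repeat until
    no removal leaves a RAF); each restart yields one irrRAF, and the
    union over restarts is a subset of the true irrRAF collection.
    """
    top = max_raf(crs)
    if top.is_empty:
        return IrrRAFReport((), mode == "exhaustive",
                            False if mode == "exhaustive" else None)
    if mode == "exhaustive":
        if len(crs.reactions) > EXHAUSTIVE_SIZE_CAP:
            raise ValueError(
                f"exhaustive irrRAF search refused for |R| = "
                f"{len(crs.reactions)} > {EXHAUSTIVE_SIZE_CAP}; use "
                "mode='sample'")
        rafs = _all_sub_rafs(crs, top.reaction_ids)
        raf_set = set(rafs)
        irr = tuple(sorted((s for s in rafs
                            if not any(o < s for o in raf_set)),
                           key=sorted))
        return IrrRAFReport(irr, True, len(irr) == 1)
    if mode != "sample":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    found: set[frozenset[str]] = set()
    for _ in range(restarts):
        current = top.reaction_ids
        while True:
            order = sorted(current)
            rng.shuffle(order)
            for rid in order:
                sub = max_raf_within(crs, current - {rid})
                if not sub.is_empty:
                    current = sub.reaction_ids
                    break
            else:
                break
        found.add(current)
    return IrrRAFReport(tuple(sorted(found, key=sorted)), False, None)


def is_union_decomposable(crs: CRS, raf: Iterable[str]) -> bool:
    """Whether a RAF is the union of two strictly smaller RAFs.

    For each reaction r in the RAF, let M_r be the maxRAF of the RAF with
    r removed: M_r is the largest proper subRAF avoiding r, and every
    proper subRAF avoids some reaction, so the union of all proper
    subRAFs equals ∪_r M_r.  The RAF is a union of two proper subRAFs iff
    that union is the whole RAF (peeling the M_r off one at a time shows
    two always suffice when the cover is complete).  This is polynomial —
    no subset enumeration — and an irrRAF is never decomposable.
    """
    base = _require_raf(crs, raf)
    covered: set[str] = set()
    for rid in sorted(base):
        sub = max_raf_within(crs, base - {rid})
        covered |= sub.reaction_ids
        if covered == base:
            return True
    return False
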