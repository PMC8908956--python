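"""Independent brute-force oracles for the RAF algorithms.

Deliberately naive re-implementations — plain loops over explicit
subsets, no shared code with the package — used to cross-check the
fixed-point algorithms on small instances.
"""

from itertools import combinations


def naive_closure(crs, subset):
    """Reachable element set by repeated full passes (no early stopping)."""
    subset = set(subset)
    available = set(crs.food)
    for _ in range(len(crs.reactions) + 1):
        for r in crs.reactions:
            if r.id in subset and all(x in available for x in r.reactants):
                available |= set(r.products)
    return available


def naive_is_raf(crs, subset):
    subset = set(subset)
    if not subset:
        return False
    reachable = naive_closure(crs, subset)
    products = set()
    for r in crs.reactions:
        if r.id in subset:
            products |= set(r.products)
    for r in crs.reactions:
        if r.id not in subset:
            continue
        if not all(x in reachable for x in r.reactants):
            return False
        if not (set(r.catalysts) & (set(crs.food) | products)):
            return False
    return True


def all_rafs(crs):
    """Every RAF subset, by exhaustive enumeration (small |R| only)."""
    ids = sorted(r.id for r in crs.reactions)
    found = []
    for k in range(1, len(ids) + 1):
        for combo in combinations(ids, k):
            if naive_is_raf(crs, combo):
                found.append(frozenset(combo))
    return found


def exhaustive_max_raf(crs):
    """Largest-cardinality RAF found by exhaustive search (empty set if
    the CRS has no RAF)."""
    rafs = all_rafs(crs)
    if not rafs:
        return frozenset()
    return max(rafs, key=lambda s: (len(s), sorted(s)))
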