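"""RAF decision, maxRAF fixed point, and structure algorithms."""

from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from rafnet.crs import parse_crs
from rafnet.raf import (closure_of_subraf, find_irr_rafs, is_closed_raf,
                        is_co_raf, is_raf, is_union_decomposable, max_raf,
                        max_raf_within)
from rafnet.polymer import random_crs

from tests.oracles import all_rafs, exhaustive_max_raf, naive_is_raf


def _fuzz_crs(seed):
    # small instances for the exhaustive oracle; reaction count <= 8
    return random_crs(n_elements=8, n_reactions=2 + seed % 7, p=0.25,
                      seed=seed)


class TestIsRAF:
    def test_empty_subset_is_not_a_raf(self, toy1):
        assert not is_raf(toy1, set())

    def test_food_catalyzed_single_reaction(self, toy2):
        assert is_raf(toy2, {"r1"})

    def test_mutual_catalysis_pair(self, toy1):
        # r1 alone lacks a catalyst (c is neither food nor r1's product);
        # together r1 and r2 catalyze each other
        assert not is_raf(toy1, {"r1"})
        assert not is_raf(toy1, {"r2"})
        assert is_raf(toy1, {"r1", "r2"})

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_naive_oracle(self, seed):
        crs = _fuzz_crs(seed)
        ids = sorted(crs.reaction_ids)
        for k in range(len(ids) + 1):
            for combo in combinations(ids, min(k, len(ids))):
                assert is_raf(crs, combo) == naive_is_raf(crs, combo)


class TestMaxRAF:
    def test_toy1_maxraf(self, toy1):
        assert max_raf(toy1).reaction_ids == {"r1", "r2"}

    def test_uncatalyzed_reaction_means_no_raf(self):
        crs = parse_crs("food: a\nelements: b\nr1: a -> b")
        result = max_raf(crs)
        assert result.is_empty
        assert result.reaction_ids == frozenset()

    def test_maxraf_satisfies_ra_condition(self, toy3):
        result = max_raf(toy3)
        available = set(toy3.food)
        for r in toy3.reactions:
            if r.id in result.reaction_ids:
                available |= set(r.products)
        for r in toy3.reactions:
            if r.id in result.reaction_ids:
                assert set(r.catalysts) & available

    def test_maximality_no_reaction_can_be_added(self, toy1, toy2, toy3):
        for crs in (toy1, toy2, toy3):
            top = max_raf(crs).reaction_ids
            for rid in crs.reaction_ids - top:
                assert not is_raf(crs, top | {rid})

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_equals_exhaustive_oracle(self, seed):
        crs = _fuzz_crs(seed)
        assert max_raf(crs).reaction_ids == exhaustive_max_raf(crs)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_foodset_expansion_never_shrinks_maxraf(self, seed):
        crs = _fuzz_crs(seed)
        extra = sorted(crs.elements - crs.food)[:2]
        bigger = crs.with_food(set(crs.food) | set(extra))
        assert max_raf(crs).reaction_ids <= max_raf(bigger).reaction_ids

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_prune_order_does_not_change_fixed_point(self, seed):
        # catalysis-first reduction must land on the same fixed point as
        # the reactant-first sweep used by max_raf
        crs = _fuzz_crs(seed)
        from rafnet.crs import producible_closure
        from rafnet.raf import products_of
        survivors = set(crs.reaction_ids)
        changed = True
        while changed:
            changed = False
            available = crs.food | products_of(crs, survivors)
            for rid in sorted(survivors):
                if not crs.reaction_map[rid].catalysts & available:
                    survivors.discard(rid)
                    changed = True
            closure = producible_closure(crs, survivors)
            for rid in sorted(survivors):
                r = crs.reaction_map[rid]
                if not all(x in closure for x in r.reactants):
                    survivors.discard(rid)
                    changed = True
        assert frozenset(survivors) == max_raf(crs).reaction_ids


class TestPosetStructure:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_union_of_rafs_is_raf_and_max_is_top(self, seed):
        crs = _fuzz_crs(seed)
        rafs = all_rafs(crs)
        top = max_raf(crs).reaction_ids
        for a in rafs:
            assert a <= top  # unique maximal element
        for a, b in combinations(rafs, 2):
            assert is_raf(crs, a | b)

    def test_union_property_on_fixtures(self, toy3):
        rafs = all_rafs(toy3)
        assert frozenset({"r1"}) in rafs
        for a, b in combinations(rafs, 2):
            assert is_raf(toy3, a | b)


class TestClosedRAFs:
    def test_maxraf_is_always_closed(self, toy1, toy2, toy3):
        for crs in (toy1, toy2, toy3):
            top = max_raf(crs)
            assert is_closed_raf(crs, top.reaction_ids)

    def test_transient_subraf(self, toy3):
        # r2's reactants (ab, b) and catalyst ab are all available from
        # {r1}, so {r1} is transient
        assert not is_closed_raf(toy3, {"r1"})

    def test_closure_adds_until_closed(self, toy3):
        assert closure_of_subraf(toy3, {"r1"}) == {"r1", "r2"}

    def test_closure_of_closed_raf_is_itself(self, toy2):
        assert closure_of_subraf(toy2, {"r1"}) == {"r1"}

    def test_closed_raf_equals_its_closure(self, toy1):
        top = max_raf(toy1).reaction_ids
        assert closure_of_subraf(toy1, top) == top

    def test_precondition_enforced(self, toy1):
        with pytest.raises(ValueError, match="not a RAF"):
            is_closed_raf(toy1, {"r1"})

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_closure_idempotent_and_extensive_on_random_rafs(self, seed):
        crs = _fuzz_crs(seed)
        for raf in all_rafs(crs):
            closed = closure_of_subraf(crs, raf)
            assert raf <= closed
            assert is_closed_raf(crs, closed)
            assert closure_of_subraf(crs, closed) == closed


class TestCoRAF:
    def test_dependent_reaction_is_a_co_raf(self, toy3):
        # r2 alone is not F-generated (needs ab), but {r1, r2} is a RAF
        assert is_co_raf(toy3, {"r1"}, {"r2"})

    def test_empty_candidate_is_not_a_co_raf(self, toy3):
        assert not is_co_raf(toy3, {"r1"}, set())

    def test_candidate_that_is_itself_a_raf_is_excluded(self):
        crs = parse_crs("food: a, b\nelements: aa, bb\n"
                        "r1: a -> aa [a]\nr2: b -> bb [b]")
        assert not is_co_raf(crs, {"r1"}, {"r2"})

    def test_overlapping_candidate_rejected(self, toy3):
        with pytest.raises(ValueError, match="disjoint"):
            is_co_raf(toy3, {"r1"}, {"r1", "r2"})


class TestIrrRAFs:
    def test_toy1_unique_irrraf_is_the_pair(self, toy1):
        report = find_irr_rafs(toy1, mode="exhaustive")
        assert report.irr_rafs == (frozenset({"r1", "r2"}),)
        assert report.unique

    def test_toy3_unique_irrraf_is_r1(self, toy3):
        report = find_irr_rafs(toy3, mode="exhaustive")
        assert report.irr_rafs == (frozenset({"r1"}),)
        assert report.unique

    def test_no_raf_means_no_irrrafs(self):
        crs = parse_crs("food: a\nelements: b\nr1: a -> b")
        assert find_irr_rafs(crs).irr_rafs == ()

    def test_exhaustive_mode_refused_above_cap(self):
        crs = random_crs(n_elements=20, n_reactions=13, p=0.3, seed=0)
        with pytest.raises(ValueError, match="refused"):
            find_irr_rafs(crs, mode="exhaustive")

    def test_irrrafs_have_no_proper_subraf(self, toy1, toy3):
        for crs in (toy1, toy3):
            for irr in find_irr_rafs(crs).irr_rafs:
                for k in range(1, len(irr)):
                    for combo in combinations(sorted(irr), k):
                        assert not is_raf(crs, combo)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_sampled_subset_of_exhaustive(self, seed):
        crs = _fuzz_crs(seed)
        if max_raf(crs).is_empty:
            return
        exhaustive = set(find_irr_rafs(crs, mode="exhaustive").irr_rafs)
        sampled = set(find_irr_rafs(crs, mode="sample", seed=seed,
                                    restarts=20).irr_rafs)
        assert sampled <= exhaustive
        assert sampled  # at least one contraction path terminates

    def test_sampling_is_seed_deterministic(self, toy3):
        a = find_irr_rafs(toy3, mode="sample", seed=5, restarts=10)
        b = find_irr_rafs(toy3, mode="sample", seed=5, restarts=10)
        assert a == b


class TestUnionDecomposable:
    def test_irreducible_pair_not_decomposable(self, toy1):
        assert not is_union_decomposable(toy1, {"r1", "r2"})

    def test_two_independent_food_reactions_decompose(self):
        crs = parse_crs("food: a, b\nelements: aa, bb\n"
                        "r1: a -> aa [a]\nr2: b -> bb [b]")
        assert is_union_decomposable(crs, {"r1", "r2"})

    def test_any_irrraf_is_not_decomposable(self, toy3):
        for irr in find_irr_rafs(toy3).irr_rafs:
            assert not is_union_decomposable(toy3, irr)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_exhaustive_pair_search(self, seed):
        crs = _fuzz_crs(seed)
        rafs = all_rafs(crs)
        for raf in rafs:
            proper = [s for s in rafs if s < raf]
            expected = any(a | b == raf
                           for a, b in combinations(proper, 2))
            assert is_union_decomposable(crs, raf) == expected


class TestMaxRAFWithin:
    def test_restriction_to_subnetwork(self, toy3):
        assert max_raf_within(toy3, {"r2"}).is_empty
        assert max_raf_within(toy3, {"r1"}).reaction_ids == {"r1"}
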