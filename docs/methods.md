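# Methods

## The model

A catalytic reaction system (CRS) is a tuple Q = (X, R, C, F): element
types X, reactions R (reactant multiset → product multiset), a catalysis
assignment C recorded per reaction as the set of element types that
catalyze it, and a foodset F ⊆ X of elements present at the start.  A
**RAF** is a non-empty R′ ⊆ R that is

- *reflexively autocatalytic* — every reaction in R′ has at least one
  catalyst in F ∪ products(R′), and
- *F-generated* — every reactant of R′ lies in the producible closure of
  F under R′ itself (the smallest W ⊇ F such that any reaction in R′
  with all reactants in W contributes its products to W).

Availability is set-based: reactants and products are multisets for
fidelity of the notation, but an element, once producible, is available
in any multiplicity.  This is the catalytic, non-stoichiometric reading
appropriate for conceptual networks — a mental representation (MR) is
not consumed by being thought with — and it also keeps every operation
monotone, which is what makes the fixed-point algorithms exact.

The RAFs of a CRS, ordered by inclusion, form a poset: the union of two
RAFs is again a RAF (the union remains F-generated and each reaction
keeps its catalyst), so when any RAF exists there is a unique maximal
one, the **maxRAF**.  `max_raf` computes it by the alternating
reduction — prune reactions with a reactant outside the producible
closure of the survivors, prune reactions with no catalyst in
F ∪ products(survivors), repeat until stable.  Each prune removes only
reactions that belong to no RAF, so the fixed point contains every RAF
and is itself one when non-empty; the prune order does not affect the
fixed point (asserted by test), and sweeps run in lexicographic id
order so results are bit-stable.

On top of the maxRAF:

- a RAF is **closed** when it already contains every network reaction
  whose reactants and at least one catalyst are available from it; a
  non-closed (*transient*) subRAF accretes reactions until closed
  (`closure_of_subraf`, extensive and idempotent; the maxRAF is always
  closed);
- an **irrRAF** contains no smaller RAF.  Exhaustive enumeration is
  refused above |R| = 12 (4095 subsets keeps the oracle well under a
  second; the cap is a module constant).  Sampling mode runs seeded
  randomized single-reaction contraction (remove one reaction, take the
  maxRAF of the remainder, repeat until stuck; default 100 restarts) and
  returns a subset of the true irrRAF collection;
- a **co-RAF** of R′ is a non-empty disjoint reaction set that is not a
  RAF alone but forms one with R′;
- **union decomposability** (is the RAF a union of two strictly smaller
  RAFs?) is decided exactly in polynomial time: for each reaction r, the
  maxRAF of the RAF minus r is its largest proper subRAF avoiding r, and
  every proper subRAF avoids some r, so the union of these |R′| maxRAFs
  equals the union of *all* proper subRAFs; peeling them off one at a
  time shows two suffice whenever that union covers the RAF.  No subset
  enumeration is needed; the exhaustive pair search survives as an
  independent test oracle.

## Cognitive semantics: lineages

Per individual *i* the conceptual network splits into the foodset F_i
(MRs that are innate or acquired by social or individual learning of
pre-existing information) and the foodset-derived set ¬F_i (MRs created
by the individual's own creative thought).  Three event kinds update a
lineage: social learning and individual learning add to F_i; a creative
event a →_b c (or a + a′ →_b c) adds c to ¬F_i and requires the actor to
already possess the reactants a and the catalysts b — a catalyst here is
a need, desire or piece of knowledge that enables the mental operation,
and is modeled as an ordinary foodset MR so that the RA condition is
checkable.  A creative product transmitted socially is **re-tagged**: it
enters the *recipient's* foodset, because for the recipient it is
pre-existing information.

Every MR carries a provenance record (kind, step, owner, reactant
ancestry, catalysts, source individual), so `trace_origin` walks any
creative product back to foodset items, across individuals, and
`lineage_to_crs` projects one actor's history onto a CRS — elements are
the actor's MRs, food is F_actor, and each creative event is a reaction.
A "possible stream of thought" from the foodset to an MR is then exactly
F-generation, and the RAF machinery applies unchanged.

Design choices that were genuinely open:

- Social transmission requires the source to possess the transmitted MR.
  So that the six-step fixture needs no hidden pre-seeded state, the
  fixture includes the teacher's and the carver's own acquisition as
  individual-learning events inside steps one and three (every social
  transmission is preceded, somewhere in the lineage, by individual
  learning or creative thought of the content); the distinct step count
  stays six.
- The creative catalyst n_i (domain knowledge plus the desire to express
  the figurine in the creator's medium) enters the creator's foodset by
  an individual-learning event in step two; no acquisition rule for it
  is otherwise specified.
- The final synthesis product musL_i is treated as creative (added to
  ¬F_i), although one notational variant writes it as individual
  learning; the creative reading is the one consistent with the update
  rule and with the re-tag behavior at step six.
- The musical group is a single actor; its members are roster metadata.
- Event order in the TSV is the single source of temporal order.

## Study encoding

The packaged fixtures transcribe the study tables: a roster of nine
artists of whom three form the group SLT (so seven participant
entities: six individuals plus one group), with exactly three process
descriptions (SLT, SW, WC); and a 4 × 3 through-line presence matrix
(LH, S, D, W × SLT, SW, WC).  The thematic coding that produced the
matrix is a human procedure; the matrix is the data interface.

Through-line selection keeps themes present in at least `min_count`
descriptions (default 2: LH = 3, D = 2, W = 2) plus an explicit
`retained` set for themes kept on qualitative grounds (default {S}:
present only in the music but central to it and not straightforwardly
implementable elsewhere).  Both the study's rule and the plain
multiplicity rule are therefore expressible; selection is monotone
non-increasing in `min_count`.

## Synthetic data: the binary polymer model

Elements are all strings of length ≤ n over a k-letter alphabet
(default k = 2), reactions are all ligations x + y → xy with
|x| + |y| ≤ n, and the foodset is every string of length ≤ t (default
t = 2).  Each (element, reaction) pair is catalytic independently with
probability p.  For k = 2, n = 4 this gives 30 elements and 68
ligations — closed-form counts the tests pin down.

Catalysis is drawn as one uniform variate per (element, reaction) pair
over the sorted (element, reaction-id) grid, from a generator seeded by
the instance seed alone; a pair is catalytic iff its variate is below p.
Hence for a fixed seed the catalysis set at p₁ is a subset of the one at
p₂ whenever p₁ ≤ p₂, and since enlarging catalysis can only enlarge the
maxRAF, per-instance maxRAF size is *exactly* monotone in p — an
assertable invariant rather than a statistical tendency.  In the
transition experiment, replicate seeds derive from the base seed and the
replicate index only (never from p), so each replicate is one coupled
instance across the whole grid.  The experiment reports, per grid point,
the fraction of replicates with a non-empty maxRAF and the mean maxRAF
size; the endpoints are exact (p = 0: no reaction can satisfy the RA
condition; p = 1: every food-pair ligation is catalyzed by a food
element).  No specific numeric transition threshold is asserted — only
monotonicity and the endpoints.

What the generator does *not* emulate: cleavage or reversible
reactions, rate constants, concentrations, template-based catalysis, or
any empirically calibrated catalysis distribution.  Passing tests
therefore certify the algorithms' correctness and the qualitative phase
behavior, not quantitative claims about real chemistries or real
conceptual networks.

## Problem sizes and numerics

The exhaustive oracles (maxRAF equivalence, irrRAF minimality, union
decomposition) run on random systems with 2–12 reactions, where 2^|R|−1
subset enumeration is cheap; the oracle-equivalence suite uses 200 such
instances.  The phase-behavior check uses the binary alphabet with
n = 6, t = 2 (126 elements, 516 ligations) and 50 replicates per grid
point over p ∈ {0, 5·10⁻⁴, 10⁻³, 2·10⁻³, 5·10⁻³, 1}.  All comparisons
are exact set/integer comparisons; there is no floating-point tolerance
anywhere in the core algorithms (the only floats are catalysis
probabilities and Monte-Carlo fractions).

Degenerate inputs are defined, not errors: the empty reaction subset is
F-generated but not a RAF; a CRS may have no RAF (reported as a status);
a reaction with no catalysts is legal but can never join a RAF; an
element appearing as both reactant and catalyst of one reaction is
allowed.  Strict element declaration is the parser default (typo
safety); auto-declaration from use sits behind `implicit_elements`.

## Limitations

- Exhaustive enumeration is capped at 12 reactions; above it, irrRAF
  sampling is a lower bound on the irrRAF collection (union
  decomposition, by contrast, stays exact at any size).
- The lineage model has no forgetting, no stochastic event generation,
  no MR "reactivity" magnitudes, and no population-scale dynamics.
- The fixture lineage encodes one creator and an audience; the other
  creators' processes are represented only through the presence matrix.
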