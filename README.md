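# rafnet

Reflexively autocatalytic, foodset-generated (RAF) network analysis —
for chemical reaction systems and for the conceptual networks behind
cultural lineages.

A **catalytic reaction system** (CRS) is a tuple Q = (X, R, C, F):
element types X, reactions R, a catalysis assignment C, and a foodset
F ⊆ X of elements present at the start.  A **RAF** is a non-empty
R′ ⊆ R such that every reaction in R′ is catalyzed by an element of
F ∪ products(R′) (*reflexively autocatalytic*) and every reactant of R′
is producible from F through R′ itself (*F-generated*).  RAFs are the
standard formal setting for collectively self-sustaining structure: in
origin-of-life work the elements are molecules; in cognitive
applications they are mental representations (MRs), catalysts are the
needs, desires and knowledge that spark mental operations, and a RAF is
a mutually accessible body of thought in which each creative step can
be triggered from within.

`rafnet` is for researchers who want to (1) run the RAF algorithms —
maxRAF, closed RAFs and closures, irreducible RAFs, co-RAFs, union
decomposition — on systems described in a plain-text format; (2) model
cultural lineages in which individuals acquire MRs by social learning,
individual learning and catalyzed creative thought, trace any creative
product back to its sources, and analyze an individual's conceptual
network as a CRS; and (3) generate random binary-polymer chemistries to
study the phase transition from no RAF to a system-spanning RAF as
catalysis probability p grows.

The set of RAFs of a CRS is closed under union, so when any RAF exists
there is a unique maximal one, the **maxRAF**, computed by the
alternating fixed-point reduction: repeatedly delete reactions whose
reactants are not producible by the survivors or that have no available
catalyst.  The package ships a worked cultural lineage: a study in
which seven creators/creator groups produced artworks inspired by a
Paleolithic lion-human figurine, four *through-lines* (lion-human
hybrid LH, subtractive sculpting S, deterioration D, waiting to be
found W) connect the figurine to the new works, and a six-step lineage
carries them from carver to musician to audience — the musician's five
creative MRs (musLH, musS, musD, musW and the finished piece musL) form
exactly the maxRAF of their conceptual network.

## Worked example

A two-reaction system in the CRS text format, `toy.crs`:

```text
elements: ab, abb
food: a, b
r1: a + b -> ab [a]
r2: ab + b -> abb [ab]
```

```sh
$ raf maxraf toy.crs
{
  "file": "toy.crs",
  "n_reactions": 2,
  "status": "RAF found",
  "maxraf": ["r1", "r2"],
  "maxraf_size": 2,
  "iterations": 1
}
```

Both reactions survive: r1 is catalyzed by the food element `a`, its
product `ab` catalyzes r2, and both reactants chains trace back to the
foodset {a, b}.  `{r1}` alone is also a RAF but a *transient* one — r2's
reactants and catalyst are all available from it — so its closure grows:

```sh
$ raf closure toy.crs --subset r1
{ "subset": ["r1"], "closure": ["r1", "r2"], "was_already_closed": false }
$ raf irr toy.crs --exhaustive
{ "irr_rafs": [["r1"]], "unique": true }
```

The full study pipeline (fixtures → through-line selection → six-step
lineage → creator CRS → maxRAF):

```sh
$ raf analyze
```

prints, among other fields:

```json
{
  "participants": {"entities": 7, "roster_rows": 10},
  "themes": {
    "counts": {"LH": 3, "S": 1, "D": 2, "W": 2},
    "through_lines": ["LH", "S", "D", "W"]
  },
  "lineage": {"n_steps": 6, "n_events": 20},
  "creator_crs": {
    "n_elements": 12, "n_food": 7, "n_reactions": 5,
    "maxraf": ["s4_musD_SLT", "s4_musLH_SLT", "s4_musS_SLT",
               "s4_musW_SLT", "s5_musL_SLT"],
    "maxraf_size": 5
  },
  "all_checks_pass": true
}
```

Reading this: the roster holds nine artists of whom three form the
musical group SLT, giving seven participant entities; the lion-human
theme appears in all three process descriptions, deterioration and
waiting-to-be-found in two, and subtractive sculpting in one (retained
as a through-line by the qualitative exception, expressed as the
`retained` parameter).  The six-step lineage gives the creator a
12-element conceptual network whose foodset holds 7 socially/
individually learned MRs, and whose five creative reactions — four
cross-domain transfers plus the final synthesis — are precisely the
maxRAF.

The phase-transition experiment:

```sh
$ raf polymer --n 6 --t 2 --p-grid 0,0.001,0.005,1 --reps 50 --seed 1
```

writes a TSV of RAF-existence fractions along the p grid (exactly 0 at
p = 0, exactly 1 at p = 1, monotone in between thanks to the coupled
catalysis draw — see `docs/methods.md`).

Everything the CLI does is a thin wrapper over the library
(`rafnet.crs`, `rafnet.raf`, `rafnet.lineage`, `rafnet.study`,
`rafnet.polymer`, `rafnet.report`).

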