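"""Synthetic catalytic reaction systems: the binary polymer model.

Elements are all non-empty strings of length ≤ n over a k-letter
alphabet; reactions are ligations x + y → xy for every ordered pair with
|x| + |y| ≤ n; the foodset is every string of length ≤ t (t < n).  Each
(element, reaction) catalysis pair is included independently with
probability p.  As p (or n) grows the system undergoes a phase
transition from no RAF to a RAF spanning most of the molecule set; this
module generates instances for exploring that transition and for
property-based testing of the RAF algorithms.

The catalysis draw is *coupled across p*: one uniform variate per
(element, reaction) pair is generated from the instance seed alone, and
the pair is catalytic iff the variate is below p.  For a fixed seed the
catalysis set at p1 is therefore a subset of the one at p2 whenever
p1 ≤ p2, which makes per-instance maxRAF size exactly monotone in p —
an assertable invariant, not merely a statistical tendency.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from rafnet.crs import CRS, Reaction
from rafnet.raf import max_raf

__all__ = [
    "PolymerConfig",
    "generate_polymer_crs",
    "estimate_raf_probability",
    "random_crs",
    "plot_transition",
]


@dataclass(frozen=True)
class PolymerConfig:
    """Parameters of one binary-polymer instance.

    ``max_length`` (n) and ``catalysis_prob`` (p) are the two knobs the
    phase transition depends on; ``food_max_length`` (t) sets which short
    polymers are freely available; ``seed`` fixes the catalysis draw.
    """

    max_length: int
    catalysis_prob: float
    seed: int = 0
    alphabet_size: int = 2
    food_max_length: int = 2

    def __post_init__(self) -> None:
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2")
        if not 1 <= self.food_max_length < self.max_length:
            raise ValueError("need 1 <= food_max_length < max_length")
        if not 0.0 <= self.catalysis_prob <= 1.0:
            raise ValueError("catalysis_prob must be in [0, 1]")


def _polymers(alphabet_size: int, max_length: int) -> list[str]:
    letters = string.ascii_lowercase[:alphabet_size]
    out: list[str] = []
    layer = [""]
    for _ in range(max_length):
        layer = [s + ch for s in layer for ch in letters]
        out.extend(layer)
    return out


def generate_polymer_crs(config: PolymerConfig) -> CRS:
    """Instantiate the binary polymer model under the given config.

    For alphabet size k there are k + k² + ... + kⁿ elements and
    Σ_{s=2..n} (s−1)·kˢ ligation reactions (each product of length s
    splits at s−1 points).  Reaction ids are ``L_<x>_<y>``.  Catalysis
    uses one uniform draw per (element, reaction) pair, ordered by the
    lexicographic (element, reaction-id) grid, from a generator seeded
    with ``config.seed`` only — see the module docstring for the
    coupling-across-p property this buys.
    """
    elements = sorted(_polymers(config.alphabet_size, config.max_length))
    food = [s for s in elements if len(s) <= config.food_max_length]
    pairs = [(x, y) for x in elements for y in elements
             if len(x) + len(y) <= config.max_length]
    pairs.sort(key=lambda xy: f"L_{xy[0]}_{xy[1]}")
    rng = np.random.default_rng(config.seed)
    u = rng.random((len(elements), len(pairs)))
    catalytic = u < config.catalysis_prob
    reactions = []
    for j, (x, y) in enumerate(pairs):
        cats = frozenset(elements[i] for i in np.flatnonzero(catalytic[:, j]))
        reactions.append(Reaction(id=f"L_{x}_{y}", reactants=(x, y),
                                  products=(x + y,), catalysts=cats))
    return CRS(elements, reactions, food)


def estimate_raf_probability(config: PolymerConfig,
                             p_grid: Sequence[float],
                             replicates: int) -> pd.DataFrame:
    """Monte-Carlo estimate of RAF emergence along a catalysis-probability
    grid.

    For each p in the grid, ``replicates`` instances are generated and
    the fraction with a non-empty maxRAF recorded, together with the
    mean maxRAF size.  Replicate seeds derive from ``config.seed`` and
    the replicate index only — not from p — so each replicate is the
    same coupled instance across the whole grid and its maxRAF size is
    monotone in p.  Returns a tidy frame with columns
    ``p, replicates, raf_fraction, mean_maxraf_size``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rep_seeds = [int(np.random.SeedSequence([config.seed, rep])
                     .generate_state(1)[0] % (2 ** 31))
                 for rep in range(replicates)]
    rows = []
    for p in p_grid:
        sizes = []
        for rep_seed in rep_seeds:
            crs = generate_polymer_crs(replace(config, catalysis_prob=p,
                                               seed=rep_seed))
            sizes.append(len(max_raf(crs)))
        sizes_arr = np.array(sizes)
        rows.append({"p": float(p),
                     "replicates": replicates,
                     "raf_fraction": float(np.mean(sizes_arr > 0)),
                     "mean_maxraf_size": float(sizes_arr.mean())})
    return pd.DataFrame(rows)


def random_crs(n_elements: int,
               n_reactions: int,
               p: float,
               seed: int,
               food_fraction: float = 0.3) -> CRS:
    """Small random CRS for oracle fuzzing (not a polymer chemistry).

    Elements ``e00..``; the lexicographically first ``food_fraction`` of
    them (at least one) form the foodset.  Each reaction draws one or
    two reactants and one or two products uniformly, and each (element,
    reaction) pair is catalytic with probability p.  Fully reproducible
    from the seed.
    """
    if n_elements < 1 or n_reactions < 1:
        raise ValueError("n_elements and n_reactions must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_elements - 1)))
    elements = [f"e{i:0{width}d}" for i in range(n_elements)]
    n_food = max(1, int(round(food_fraction * n_elements)))
    food = elements[:n_food]
    reactions = []
    for j in range(n_reactions):
        n_re = int(rng.integers(1, 3))
        n_pr = int(rng.integers(1, 3))
        reactants = tuple(rng.choice(elements, size=n_re, replace=False))
        products = tuple(rng.choice(elements, size=n_pr, replace=False))
        cats = frozenset(e for e in elements if rng.random() < p)
        reactions.append(Reaction(id=f"r{j:03d}", reactants=reactants,
                                  products=products, catalysts=cats))
    return CRS(elements, reactions, food)


def plot_transition(table: pd.DataFrame, path: str) -> None:
    """Optional helper: RAF-existence fraction vs p, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["p"], table["raf_fraction"], marker="o")
    ax.set_xlabel("catalysis probability p")
    ax.set_ylabel("fraction of instances with a RAF")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
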