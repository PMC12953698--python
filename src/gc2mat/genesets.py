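"""Gene-set intersections and overlap significance.

Implements exact k-way intersections, Venn-region summaries, the upper-tail
hypergeometric overlap test, and an empirical randomization test in which
each iteration redraws every set uniformly (without replacement, preserving
set sizes) from the declared gene universe and counts how often the
randomized k-way intersection reaches the observed one.

The randomization is simulated by chained hypergeometric draws: because the
redrawn sets are independent uniform subsets, the overlap of set j with the
running intersection of sets 1..j-1 is hypergeometric given that
intersection's size.  This is distributionally identical to materializing the
random subsets and intersecting them, but runs in O(k x iterations) scalar
draws, which makes the million-iteration setting cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        self.name = name
        members = list(members)
        if len(members) != len(set(members)):
            raise ValueError(f"duplicate members in gene set {name!r}")
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        path = Path(path)
        lines = [ln.strip() for ln in path.read_text().splitlines()]
        return cls(name or path.stem, [ln for ln in lines if ln])

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.members)) + "\n")


@dataclass
class OverlapResult:
    """Randomization-test result for a k-way overlap."""

    observed_intersection: int
    n_iterations: int
    n_exceedances: int
    empirical_p: float
    shared_fraction: float
    hypergeometric_p: float | None = None


def intersect_sets(sets: list[GeneSet]) -> tuple[int, list[str]]:
    """Exact k-way intersection (size and sorted member list)."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    core = frozenset.intersection(*(s.members for s in sets))
    return len(core), sorted(core)


def overlap_fraction_summary(sets: list[GeneSet]) -> dict:
    """Venn-region sizes and the core-intersection fraction of the union.

    Regions are keyed by membership bitmask strings (e.g. ``"110"`` = in the
    first two sets only, first set = leftmost bit).  Region fractions sum to 1.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    union = frozenset.union(*(s.members for s in sets))
    k = len(sets)
    regions: dict[str, int] = {}
    for gene in union:
        mask = "".join("1" if gene in s.members else "0" for s in sets)
        regions[mask] = regions.get(mask, 0) + 1
    core_size, _ = intersect_sets(sets)
    n_union = len(union)
    return {
        "set_names": [s.name for s in sets],
        "set_sizes": [len(s) for s in sets],
        "union_size": n_union,
        "core_intersection": core_size,
        "core_fraction_of_union": core_size / n_union if n_union else 0.0,
        "regions": {m: regions.get(m, 0) for m in _all_masks(k)},
        "region_fractions": {
            m: (regions.get(m, 0) / n_union if n_union else 0.0)
            for m in _all_masks(k)
        },
    }


def _all_masks(k: int) -> list[str]:
    return [format(i, f"0{k}b") for i in range(1, 2**k)]


def overlap_randomization_test(
    sets: list[GeneSet],
    universe: GeneSet,
    n_iter: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> OverlapResult:
    """Empirical randomization test of a k-way overlap.

    Each iteration draws, for every input set, a uniform subset of the
    universe of the same size, and the randomized k-way intersection is
    compared with the observed one; ties count as exceedances.  The p-value
    uses the add-one pseudocount ``(exceedances + 1) / (iterations + 1)``.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for s in sets:
        extra = s.members - universe.members
        if extra:
            raise ValueError(
                f"set {s.name!r} has members outside the universe, e.g. "
                f"{sorted(extra)[:3]}"
            )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed, _ = intersect_sets(sets)
    n_universe = len(universe)
    sizes = [len(s) for s in sets]
    inter = np.full(n_iter, sizes[0], dtype=np.int64)
    for size in sizes[1:]:
        # overlap of a fresh uniform subset of this size with the running
        # intersection is hypergeometric given the running intersection size
        inter = rng.hypergeometric(inter, n_universe - inter, size)
    n_exceed = int(np.sum(inter >= observed))
    empirical_p = (n_exceed + 1) / (n_iter + 1)
    union = frozenset.union(*(s.members for s in sets))
    result = OverlapResult(
        observed_intersection=observed,
        n_iterations=n_iter,
        n_exceedances=n_exceed,
        empirical_p=empirical_p,
        shared_fraction=observed / len(union) if union else 0.0,
    )
    if len(sets) == 2:
        result.hypergeometric_p = hypergeometric_overlap_test(
            sets[0], sets[1], universe
        )
    return result


def hypergeometric_overlap_test(
    set_a: GeneSet, set_b: GeneSet, universe: GeneSet
) -> float:
    """Upper-tail hypergeometric p for the overlap of two sets.

    P(X >= observed) with X ~ Hypergeometric(|U|, |A|, |B|).
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    for s in (set_a, set_b):
        if s.members - universe.members:
            raise ValueError(f"set {s.name!r} not contained in universe")
    observed = len(set_a.members & set_b.members)
    return float(
        stats.hypergeom.sf(observed - 1, len(universe), len(set_a), len(set_b))
    )


def exact_overlap_tail(
    n_universe: int, size_a: int, size_b: int, observed: int
) -> float:
    """Exact P(random overlap >= observed) by enumeration over overlap values.

    Independent oracle for small universes: sums the hypergeometric pmf
    directly from binomial coefficients.
    """
    from math import comb

    total = comb(n_universe, size_b)
    p = 0.0
    for k in range(observed, min(size_a, size_b) + 1):
        p += comb(size_a, k) * comb(n_universe - size_a, size_b - k) / total
    return min(p, 1.0)
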