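"""Order fields so that strongly co-varying features sit next to each other.

The feature covariance matrix is turned into a per-row *rank* matrix:
within each row, the off-diagonal entry with the largest covariance
magnitude gets rank 1, the next rank 2, and so on (ties go to the lower
column index). A field ordering is a permutation of the d fields; its
cost is the sum of symmetrized ranks over consecutive pairs — an open
travelling-salesman-path objective. Minimizing it places related fields
adjacently, which gives bar-graph encodings local structure.

Two solvers are provided: an exhaustive search (d <= 10) that serves as
the ground truth, and a permutation-encoded genetic algorithm (order
crossover, swap mutation, tournament selection, elitism) for larger d.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tabular_io import TabularDataset

__all__ = [
    "RankMatrix",
    "FieldOrdering",
    "GAConfig",
    "covariance_rank_matrix",
    "rank_matrix_from_covariance",
    "path_cost",
    "brute_force_order",
    "ga_order",
]


@dataclass(frozen=True)
class RankMatrix:
    """d x d integer closeness ranks; rank 1 = most closely related.

    Each off-diagonal row is a permutation of 1..d-1; the diagonal is 0
    and never enters a path cost.
    """

    ranks: np.ndarray
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("ranks must be square")
        d = r.shape[0]
        expected = sorted(range(1, d))
        for i in range(d):
            row = sorted(np.delete(r[i], i).tolist())
            if row != expected:
                raise ValueError(f"row {i} is not a permutation of 1..{d - 1}")

    @property
    def d(self) -> int:
        return self.ranks.shape[0]

    def symmetrized(self) -> np.ndarray:
        """Edge weights (ranks[i,j] + ranks[j,i]) / 2."""
        r = self.ranks.astype(float)
        return (r + r.T) / 2.0


@dataclass(frozen=True)
class FieldOrdering:
    """A permutation of fields (1-based indices) with its path cost."""

    order: tuple[int, ...]
    cost: float

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(1, len(self.order) + 1)):
            raise ValueError("order must be a permutation of 1..d")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the ordering search.

    Mutation reverses a random segment of the permutation (a 2-opt
    move, the standard operator for path problems); ``mutation="swap"``
    selects a plain element swap instead.
    """

    population_size: int = 50
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.5
    mutation: str = "inversion"
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population_size < 2:
            raise ValueError("need >= 1 generation and >= 2 individuals")
        for p in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mutation not in ("inversion", "swap"):
            raise ValueError("mutation must be 'inversion' or 'swap'")


def rank_matrix_from_covariance(cov: np.ndarray) -> RankMatrix:
    """Rank each row's off-diagonal covariances by magnitude, largest first.

    Ties break toward the lower column index, so the result is fully
    deterministic (constant features, whose covariances are all zero,
    simply rank in index order).
    """
    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    if cov.shape != (d, d) or d < 2:
        raise ValueError("covariance must be square with d >= 2")
    ranks = np.zeros((d, d), dtype=int)
    cols = np.arange(d)
    for i in range(d):
        others = cols[cols != i]
        # sort by (-|cov|, column index): stable and deterministic
        order = sorted(others, key=lambda j: (-abs(cov[i, j]), j))
        for rank, j in enumerate(order, start=1):
            ranks[i, j] = rank
    return RankMatrix(ranks, covariance=cov)


def covariance_rank_matrix(ds: TabularDataset | np.ndarray) -> RankMatrix:
    """Rank matrix of the sample covariance between features."""
    feats = ds.features if isinstance(ds, TabularDataset) else np.asarray(ds, float)
    if feats.shape[0] < 2 or feats.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 features")
    cov = np.cov(feats, rowvar=False)
    return rank_matrix_from_covariance(cov)


def path_cost(order: Sequence[int], rm: RankMatrix) -> float:
    """Total symmetrized rank along consecutive pairs of an open path."""
    idx = np.asarray(order, dtype=int) - 1
    if sorted(idx.tolist()) != list(range(rm.d)):
        raise ValueError("order must be a permutation of 1..d")
    sym = rm.symmetrized()
    return float(sym[idx[:-1], idx[1:]].sum())


def brute_force_order(rm: RankMatrix) -> FieldOrdering:
    """Exhaustive minimum-cost ordering; ties go to the lexicographically
    smallest permutation. Refuses d > 10."""
    d = rm.d
    if d > 10:
        raise ValueError("exhaustive search is limited to d <= 10")
    sym = rm.symmetrized()
    best_perm: tuple[int, ...] | None = None
    best_cost = np.inf
    chunk = 40320
    perms = itertools.permutations(range(d))
    while True:
        block = list(itertools.islice(perms, chunk))
        if not block:
            break
        arr = np.asarray(block)
        costs = sym[arr[:, :-1], arr[:, 1:]].sum(axis=1)
        k = int(np.argmin(costs))
        # itertools yields in lexicographic order and argmin returns the
        # first minimum, so strict < keeps the lexicographic tie-break
        if costs[k] < best_cost:
            best_cost = float(costs[k])
            best_perm = tuple(int(v) + 1 for v in arr[k])
    assert best_perm is not None
    return FieldOrdering(best_perm, best_cost)


def _order_crossover(p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """OX1: copy a slice from p1, fill the rest in p2's cyclic order."""
    d = p1.size
    a, b = sorted(rng.integers(0, d, size=2))
    child = np.full(d, -1, dtype=int)
    child[a:b + 1] = p1[a:b + 1]
    used = set(child[a:b + 1].tolist())
    fill = [v for v in np.roll(p2, -(b + 1)) if v not in used]
    pos = [(b + 1 + k) % d for k in range(d - (b - a + 1))]
    child[pos] = fill
    return child


def ga_order(rm: RankMatrix, cfg: GAConfig | None = None) -> FieldOrdering:
    """Genetic search for a low-cost ordering.

    The identity ordering is seeded into the initial population and the
    best individual survives each generation unchanged, so the returned
    cost never exceeds the identity ordering's cost and the best-so-far
    trajectory is monotone. Deterministic for a fixed seed.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    d = rm.d
    sym = rm.symmetrized()

    def cost_of(pop: np.ndarray) -> np.ndarray:
        return sym[pop[:, :-1], pop[:, 1:]].sum(axis=1)

    pop = np.stack([np.arange(d)] + [rng.permutation(d)
                                     for _ in range(cfg.population_size - 1)])
    costs = cost_of(pop)
    best_i = int(np.argmin(costs))
    best_perm, best_cost = pop[best_i].copy(), float(costs[best_i])

    for _ in range(cfg.generations):
        children = [best_perm.copy()]  # elitism
        while len(children) < cfg.population_size:
            c1, c2 = (rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                      for _ in range(2))
            p1 = pop[c1[np.argmin(costs[c1])]]
            p2 = pop[c2[np.argmin(costs[c2])]]
            if rng.random() < cfg.crossover_rate:
                child = _order_crossover(p1, p2, rng)
            else:
                child = p1.copy()
            if rng.random() < cfg.mutation_rate:
                if cfg.mutation == "inversion":
                    i, j = sorted(rng.integers(0, d, size=2))
                    child[i:j + 1] = child[i:j + 1][::-1]
                else:
                    i, j = rng.integers(0, d, size=2)
                    child[i], child[j] = child[j], child[i]
            children.append(child)
        pop = np.stack(children)
        costs = cost_of(pop)
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost:
            best_cost = float(costs[gen_best])
            best_perm = pop[gen_best].copy()

    return FieldOrdering(tuple(int(v) + 1 for v in best_perm), best_cost)
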