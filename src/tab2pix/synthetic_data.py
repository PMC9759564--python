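"""Synthetic tabular datasets with known class structure.

Features are drawn class-conditionally from multivariate normals with a
block-diagonal equicorrelated covariance (unit variances), so the
ordering optimizer has a known ground truth: fields inside a block
co-vary strongly, fields across blocks do not. Informative features get
class means of +/- separation/2 in standardized units, which fixes the
Bayes error in closed form. A configurable fraction of cells can be
knocked out to exercise the ``?``-marker dialect handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_ordering import RankMatrix, FieldOrdering, brute_force_order, \
    rank_matrix_from_covariance
from .tabular_io import TabularDataset

__all__ = ["SimSpec", "simulate", "known_rank_instance"]


@dataclass(frozen=True)
class SimSpec:
    """Generator settings.

    ``separation`` is the standardized mean difference between classes on
    each informative feature; ``class_ratio`` is the expected benign
    fraction; ``block_correlation`` is the within-block feature
    correlation. Defaults give a strongly separable ten-feature problem
    of 400 rows with two correlation blocks.
    """

    n: int = 400
    d: int = 10
    separation: float = 3.0
    informative_fraction: float = 0.5
    block_correlation: float = 0.3
    n_blocks: int = 2
    class_ratio: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4 or self.d < 2:
            raise ValueError("need n >= 4 and d >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        for p in (self.informative_fraction, self.class_ratio):
            if not 0.0 < p <= 1.0:
                raise ValueError("fractions must lie in (0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_blocks > self.d or self.n_blocks < 1:
            raise ValueError("n_blocks must lie in 1..d")


def block_covariance(d: int, n_blocks: int, rho: float) -> np.ndarray:
    """Block-diagonal equicorrelated covariance with unit variances."""
    sizes = [d // n_blocks + (1 if b < d % n_blocks else 0)
             for b in range(n_blocks)]
    cov = np.eye(d)
    start = 0
    for sz in sizes:
        cov[start:start + sz, start:start + sz] = (
            rho * np.ones((sz, sz)) + (1 - rho) * np.eye(sz))
        start += sz
    return cov


def simulate(spec: SimSpec) -> TabularDataset:
    """Draw a dataset; fully deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.class_ratio).astype(int)  # 1 = benign
    cov = block_covariance(spec.d, spec.n_blocks, spec.block_correlation)
    chol = np.linalg.cholesky(cov)
    n_inf = max(1, int(np.ceil(spec.informative_fraction * spec.d)))
    shift = np.zeros(spec.d)
    shift[:n_inf] = spec.separation / 2.0
    z = rng.standard_normal((spec.n, spec.d)) @ chol.T
    signs = np.where(labels == 1, 1.0, -1.0)
    feats = z + signs[:, np.newaxis] * shift[np.newaxis, :]
    mask = np.zeros((spec.n, spec.d), dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.random((spec.n, spec.d)) < spec.missing_rate
        feats = np.where(mask, np.nan, feats)
    names = [f"f{j + 1}" for j in range(spec.d)]
    return TabularDataset(feats, labels, names, mask)


def known_rank_instance(d: int, seed: int) -> tuple[RankMatrix, FieldOrdering]:
    """A random rank matrix plus its exhaustively computed optimum.

    Used as a regression fixture for the genetic-algorithm solver; the
    rank matrix is derived from the covariance of a small random draw so
    its structure resembles real instances.
    """
    if not 3 <= d <= 8:
        raise ValueError("d must lie in 3..8 for exhaustive verification")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((4 * d, d)) @ rng.standard_normal((d, d))
    rm = rank_matrix_from_covariance(np.cov(data, rowvar=False))
    return rm, brute_force_order(rm)
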