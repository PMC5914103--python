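"""Random undersampling and object subsampling.

Every sampler takes an explicit :class:`numpy.random.Generator` so that a
fixed seed makes all downstream models bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Literal

import numpy as np

from .io_data import ABNORMAL, NORMAL, ClassSplit, DataError

SampleMode = Literal["plain", "bootstrap"]


@dataclass(frozen=True)
class BalancedSample:
    """A 2*N_a-row balanced training set: all abnormal rows + undersampled normals.

    ``X`` stacks the full abnormal set first, then the sampled normal rows,
    with ``y`` the matching 1/0 labels.  ``abnormal_indices`` and
    ``normal_indices`` are row indices into the parent dataset for
    provenance; the normal indices are distinct (without replacement).
    """

    X: np.ndarray
    y: np.ndarray
    abnormal_indices: np.ndarray
    normal_indices: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def undersample(X: np.ndarray | int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` distinct row indices uniformly at random, without replacement.

    ``X`` may be the matrix itself or just its row count.  The returned
    indices are sorted, so a fixed seed yields a canonical index set.
    """
    n = X if isinstance(X, (int, np.integer)) else np.asarray(X).shape[0]
    if k > n:
        raise DataError(
            f"cannot undersample {k} rows from {n}: abnormal class larger than normal class"
        )
    if k < 0:
        raise DataError("k must be nonnegative")
    return np.sort(rng.choice(n, size=k, replace=False))


def make_balanced(split: ClassSplit, rng: np.random.Generator) -> BalancedSample:
    """Build D = D_n ∪ X_a with |D_n| = |X_a| by undersampling the normal set.

    Every abnormal row is kept unmodified; exactly N_a normal rows are
    drawn without replacement.  Requires N_n >= N_a.
    """
    n_a, n_n = split.n_abnormal, split.n_normal
    if n_n < n_a:
        raise DataError(f"normal class ({n_n}) smaller than abnormal class ({n_a})")
    chosen = undersample(n_n, n_a, rng)
    X = np.vstack([split.X_a, split.X_n[chosen]])
    y = np.concatenate(
        [np.full(n_a, ABNORMAL, dtype=int), np.full(n_a, NORMAL, dtype=int)]
    )
    return BalancedSample(
        X=X,
        y=y,
        abnormal_indices=split.abnormal_indices.copy(),
        normal_indices=split.normal_indices[chosen],
    )


def object_subsample(
    n_rows: int,
    fraction: float,
    mode: SampleMode = "plain",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a row-index (multi)set of size ceil(fraction * n_rows).

    ``plain`` samples without replacement (distinct indices); ``bootstrap``
    samples with replacement.  The ceiling keeps the sample nonempty even
    for a single-row input.
    """
    if n_rows < 1:
        raise DataError("cannot subsample an empty matrix")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if rng is None:
        raise ValueError("an explicit Generator is required for reproducibility")
    size = ceil(fraction * n_rows)
    if mode == "plain":
        return np.sort(rng.choice(n_rows, size=size, replace=False))
    if mode == "bootstrap":
        return rng.integers(0, n_rows, size=size)
    raise ValueError(f"unknown mode {mode!r}")
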