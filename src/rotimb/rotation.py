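"""Feature-space rotation: random partitions, per-subset PCA, and diversity.

A rotation matrix is an n x n block matrix: the feature set is split
randomly into disjoint subsets, a PCA is fitted on a sample of rows
restricted to each subset, and each subset's full set of loading vectors
becomes one diagonal block (after undoing the partition's permutation, the
matrix is block-diagonal up to row/column relabelling).  Because every
block keeps all of its components, the assembled matrix is orthogonal —
multiplying data by it is a pure rotation of the feature axes, which is
exactly the perturbation axis-parallel decision trees are sensitive to.

The module also provides the combinatorics governing ensemble diversity:
the number T of distinct equal-size partitions and the birthday-problem
probability that M independently drawn partitions are all distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial

import numpy as np


@dataclass(frozen=True)
class FeaturePartition:
    """A random split of features {0..n-1} into disjoint subsets.

    All subsets have size ``L`` except possibly the last, which holds the
    ``n mod L`` remainder when L does not divide n.
    """

    subsets: tuple[np.ndarray, ...]
    L: int
    n: int

    @property
    def K(self) -> int:
        return len(self.subsets)


@dataclass(frozen=True)
class RotationMatrix:
    """An orthogonal n x n block rotation matrix.

    ``matrix[i, j]`` is nonzero only when features i and j fall in the same
    partition subset; the restriction of ``matrix`` to one subset's
    rows/columns is that subset's orthonormal PCA loading block.
    """

    matrix: np.ndarray
    partition: FeaturePartition
    blocks: tuple[np.ndarray, ...]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_text(self) -> str:
        """Plain-text rendering of the full matrix, one row per line."""
        return "\n".join(
            " ".join(f"{v: .10g}" for v in row) for row in self.matrix
        )


@dataclass(frozen=True)
class DiversityEstimate:
    """T distinct partitions, ensemble size M, probability p all M differ."""

    T: int
    M: int
    p: float


def partition_features(n: int, L: int, rng: np.random.Generator) -> FeaturePartition:
    """Split features 0..n-1 uniformly at random into subsets of size L.

    When L does not divide n the last subset holds the remainder, so
    K = ceil(n / L) subsets are produced.
    """
    if L < 1 or L > n:
        raise ValueError(f"subset size L={L} must satisfy 1 <= L <= n={n}")
    perm = rng.permutation(n)
    subsets = tuple(perm[start : start + L] for start in range(0, n, L))
    return FeaturePartition(subsets=subsets, L=L, n=n)


def fit_block(X: np.ndarray, center: bool = True) -> np.ndarray:
    """PCA loading block for a sample of rows restricted to one feature subset.

    Returns a d x d orthonormal matrix whose columns are the eigenvectors
    of the sample covariance, ordered by decreasing eigenvalue.  All d
    components are retained; when the covariance is rank-deficient the
    eigendecomposition supplies an orthonormal complement for the null
    directions, so the block always has full rank.  Sign convention: the
    largest-magnitude entry of each column is positive (first such entry
    on a tie), making results reproducible across numeric backends.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a nonempty 2-D sample")
    if center:
        X = X - X.mean(axis=0)
    denom = max(X.shape[0] - 1, 1)
    cov = (X.T @ X) / denom
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]  # decreasing eigenvalue
    block = eigvecs[:, order]
    for j in range(block.shape[1]):
        pivot = np.argmax(np.abs(block[:, j]))
        if block[pivot, j] < 0:
            block[:, j] = -block[:, j]
    return block


def assemble_rotation(
    partition: FeaturePartition, blocks: list[np.ndarray] | tuple[np.ndarray, ...]
) -> RotationMatrix:
    """Place per-subset loading blocks into the sparse n x n rotation matrix.

    Rows and columns are indexed by original feature number: block j
    occupies the rows and columns of subset F_j, and every cross-subset
    entry is exactly zero.
    """
    if len(blocks) != partition.K:
        raise ValueError(
            f"got {len(blocks)} blocks for {partition.K} subsets"
        )
    R = np.zeros((partition.n, partition.n))
    for subset, block in zip(partition.subsets, blocks):
        block = np.asarray(block, dtype=float)
        if block.shape != (subset.size, subset.size):
            raise ValueError(
                f"block shape {block.shape} does not match subset size {subset.size}"
            )
        R[np.ix_(subset, subset)] = block
    return RotationMatrix(matrix=R, partition=partition, blocks=tuple(blocks))


def rotate(X: np.ndarray, R: RotationMatrix | np.ndarray) -> np.ndarray:
    """Project data into the rotated feature space: X @ R."""
    M = R.matrix if isinstance(R, RotationMatrix) else np.asarray(R, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != M.shape[0]:
        raise ValueError(
            f"cannot rotate {X.shape[1]}-feature data with a {M.shape[0]}-dim matrix"
        )
    return X @ M


def count_partitions(n: int, L: int) -> int:
    """Number T of distinct unordered partitions of n features into n/L subsets of size L.

    T = n! / (K! * (L!)^K) with K = n/L.  Only the equal-size regime is
    defined; L must divide n.
    """
    if L < 1 or n < 1:
        raise ValueError("n and L must be positive")
    if n % L != 0:
        raise ValueError(f"L={L} must divide n={n}: unequal subsets are outside this count")
    K = n // L
    return factorial(n) // (factorial(K) * factorial(L) ** K)


def prob_all_distinct(T: int, M: int) -> float:
    """Probability that M independently drawn uniform partitions are all distinct.

    Computed as the exact product prod_{i=0}^{M-1} (T - i) / T, i.e.
    T! / ((T - M)! * T^M); zero when M > T.  Monotone nonincreasing in M.
    """
    if T < 1 or M < 1:
        raise ValueError("T and M must be at least 1")
    if M > T:
        return 0.0
    p = Fraction(1)
    for i in range(M):
        p *= Fraction(T - i, T)
    return float(p)


def diversity_estimate(n: int, L: int, M: int) -> DiversityEstimate:
    """Convenience wrapper: T for (n, L) and the all-distinct probability for M members."""
    T = count_partitions(n, L)
    return DiversityEstimate(T=T, M=M, p=prob_all_distinct(T, M))
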