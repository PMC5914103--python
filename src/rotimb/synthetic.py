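"""Synthetic imbalanced two-class Gaussian-mixture datasets.

The generator draws both classes from multivariate normals sharing a
covariance; the abnormal-class mean is shifted from the normal-class mean
by ``separation`` within-class standard deviations along a random unit
direction.  A Gaussian mixture is the minimal model with a tunable
overlap, and a one-dimensional mean shift keeps "separation" directly
interpretable: 0 makes the classes indistinguishable, ~2 gives the
overlapping-but-learnable regime typical of screening benchmarks, 6 is
near-perfectly separable.

``gen_profile`` mirrors the shape (size, attribute count, imbalance
degree) of eight published two-class medical benchmark datasets so that
protocol code can be exercised at realistic sizes without any download.
The published attribute counts include the class attribute, so the
predictive dimension is one less.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_data import ABNORMAL, NORMAL, LabeledDataset

Covariance = Literal["identity", "random-correlated"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one imbalanced Gaussian-mixture dataset."""

    n_abnormal: int
    n_normal: int
    n_features: int
    separation: float = 2.0
    covariance: Covariance = "identity"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_abnormal < 1 or self.n_normal < 1:
            raise ValueError("class counts must be at least 1")
        if self.n_features < 1:
            raise ValueError("n_features must be at least 1")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")


@dataclass(frozen=True)
class DatasetProfile:
    """Shape of a published benchmark dataset: imbalance degree, size, attributes."""

    degree: float
    size: int
    attrs: int


#: Shapes of eight two-class medical benchmark datasets (breast cancer,
#: diabetes, hepatitis, lymphography, thyroid and sick-euthyroid cohorts).
#: ``degree`` is abnormal/(abnormal+normal); ``attrs`` counts the class column.
BENCHMARK_PROFILES: dict[str, DatasetProfile] = {
    "d1": DatasetProfile(0.297, 286, 10),
    "d2": DatasetProfile(0.345, 699, 11),
    "d3": DatasetProfile(0.349, 768, 9),
    "d4": DatasetProfile(0.206, 155, 20),
    "d5": DatasetProfile(0.0405, 148, 19),
    "d6": DatasetProfile(0.162, 215, 6),
    "d7": DatasetProfile(0.162, 215, 6),
    "d8": DatasetProfile(0.061, 3772, 30),
}


def _class_geometry(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the abnormal-class mean and the shared Cholesky factor."""
    n = spec.n_features
    direction = rng.normal(size=n)
    direction /= np.linalg.norm(direction)
    if spec.covariance == "identity":
        chol = np.eye(n)
    elif spec.covariance == "random-correlated":
        A = rng.normal(size=(n, n))
        cov = A @ A.T + 0.1 * np.eye(n)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)  # unit variances keep `separation` in SD units
        chol = np.linalg.cholesky(corr)
    else:
        raise ValueError(f"unknown covariance {spec.covariance!r}")
    return spec.separation * direction, chol


def _sample(
    mean_abnormal: np.ndarray,
    chol: np.ndarray,
    n_abnormal: int,
    n_normal: int,
    rng: np.random.Generator,
) -> LabeledDataset:
    n = mean_abnormal.size
    z_a = rng.standard_normal((n_abnormal, n))
    z_n = rng.standard_normal((n_normal, n))
    X = np.vstack([mean_abnormal + z_a @ chol.T, z_n @ chol.T])
    y = np.concatenate(
        [np.full(n_abnormal, ABNORMAL, dtype=int), np.full(n_normal, NORMAL, dtype=int)]
    )
    names = tuple(f"f{i + 1}" for i in range(n))
    return LabeledDataset(features=X, labels=y, feature_names=names)


def gen_gaussian(spec: SyntheticSpec) -> LabeledDataset:
    """Sample a dataset from the two-Gaussian model described by ``spec``.

    Abnormal rows come first, then normal rows; class counts are exact and
    the draw is fully reproducible from ``spec.seed``.  Note that the
    mean-shift direction (and any random correlation structure) is part of
    the draw: two different seeds describe two different populations.  Use
    :func:`gen_train_test` when a matched train/test pair from the *same*
    population is needed.
    """
    rng = np.random.default_rng(spec.seed)
    mean_abnormal, chol = _class_geometry(spec, rng)
    return _sample(mean_abnormal, chol, spec.n_abnormal, spec.n_normal, rng)


def gen_train_test(
    spec: SyntheticSpec,
    n_test_abnormal: int | None = None,
    n_test_normal: int | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """A train/test pair drawn from one population.

    The class geometry (mean shift, covariance) is drawn once from
    ``spec.seed``; the training set uses the spec's class counts and the
    test set defaults to the same counts.
    """
    rng = np.random.default_rng(spec.seed)
    mean_abnormal, chol = _class_geometry(spec, rng)
    train = _sample(mean_abnormal, chol, spec.n_abnormal, spec.n_normal, rng)
    test = _sample(
        mean_abnormal,
        chol,
        n_test_abnormal if n_test_abnormal is not None else spec.n_abnormal,
        n_test_normal if n_test_normal is not None else spec.n_normal,
        rng,
    )
    return train, test


def gen_profile(
    dataset_id: str,
    scale: float = 1.0,
    separation: float = 2.0,
    covariance: Covariance = "identity",
    seed: int | None = None,
) -> LabeledDataset:
    """Synthetic stand-in matching a benchmark profile's shape.

    The generated dataset has ``round(scale * size)`` examples,
    ``attrs - 1`` predictive features, and an abnormal count of
    ``round(degree * N)``, so its imbalance degree matches the profile
    within rounding.  ``scale`` < 1 shrinks the dataset proportionally.
    """
    if dataset_id not in BENCHMARK_PROFILES:
        raise ValueError(
            f"unknown dataset id {dataset_id!r}; choose from {sorted(BENCHMARK_PROFILES)}"
        )
    if scale <= 0:
        raise ValueError("scale must be positive")
    profile = BENCHMARK_PROFILES[dataset_id]
    N = round(scale * profile.size)
    n_abnormal = round(profile.degree * N)
    n_normal = N - n_abnormal
    if n_abnormal < 1 or n_normal < 1:
        raise ValueError(f"scale {scale} leaves an empty class for {dataset_id}")
    spec = SyntheticSpec(
        n_abnormal=n_abnormal,
        n_normal=n_normal,
        n_features=profile.attrs - 1,
        separation=separation,
        covariance=covariance,
        seed=seed,
    )
    return gen_gaussian(spec)
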