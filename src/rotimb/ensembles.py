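"""Ensemble learners for imbalanced two-class data.

The centrepiece is the ensemble of rotation trees (ERT).  Each member is
built independently: undersample the normal class down to the abnormal
count, randomly partition the features, fit a PCA loading block per subset
on a 50% object sample of the balanced set, assemble the blocks into an
orthogonal rotation matrix, and train a decision tree on the rotated
balanced set.  The undersampling biases every member toward the abnormal
class; the random partitions and object samples supply diversity.  Members
vote with equal weight and ties go to the abnormal class (the costlier
error direction).

Comparison methods with the same prediction surface:

- RURF — learns each rotation matrix on a balanced undersample exactly as
  ERT does, but trains the tree on the rotated *full* (imbalanced)
  training set.  This is the single structural difference from ERT.
- Bagging — bootstrap-resampled trees, no rotation, no rebalancing.
- AdaBoost.M1 — sample-weight boosting over a weak tree learner.
- EasyEnsemble — T balanced undersamples, one AdaBoost per sample, all
  weak trees combined in one weighted vote.
- BalanceCascade — like EasyEnsemble, but normal examples the cascade
  already classifies correctly are removed from the sampling pool between
  stages.
- A single decision tree on the raw training set.

The base learner is a C4.5-style entropy decision tree
(:class:`sklearn.tree.DecisionTreeClassifier`); any axis-parallel tree
satisfying the fit/predict contract can be substituted via
:class:`BaseLearnerSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io_data import ABNORMAL, NORMAL, DataError, LabeledDataset, class_split, require_numeric
from .resampling import SampleMode, make_balanced, object_subsample
from .rotation import RotationMatrix, assemble_rotation, fit_block, partition_features, rotate

_MAX_SEED = 2**31 - 1


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or None) into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _tree_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_MAX_SEED))


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Contract for the base decision tree.

    ``criterion='entropy'`` mimics the information-gain splits of C4.5;
    ``max_depth``/``min_samples_leaf`` control complexity (defaults grow
    full, unpruned trees).
    """

    criterion: str = "entropy"
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def make(self, random_state: int | None = None) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion=self.criterion,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=random_state,
        )


#: Default weak learner for the boosting-based methods.  An unpruned tree
#: reaches zero training error on almost any balanced sample, which stops
#: AdaBoost.M1 after one round and would collapse each subensemble to a
#: single tree; a depth-limited tree keeps boosting meaningful so the
#: standard 10-round x 10-subset configuration really learns 100 trees.
WEAK_LEARNER = BaseLearnerSpec(max_depth=2)


@dataclass(frozen=True)
class VoteResult:
    """Per-example vote tallies of a (possibly weighted) ensemble.

    ``score`` is the abnormal vote weight divided by the total weight;
    the decided label is abnormal when the abnormal weight is at least
    half the total (ties favour the abnormal class).
    """

    votes_abnormal: np.ndarray
    total: float

    @property
    def score(self) -> np.ndarray:
        return self.votes_abnormal / self.total

    @property
    def labels(self) -> np.ndarray:
        return np.where(2 * self.votes_abnormal >= self.total, ABNORMAL, NORMAL)


class MajorityVoteEnsemble:
    """Equal-weight voting over (optional rotation, tree) members."""

    def __init__(
        self,
        members: Sequence[tuple[RotationMatrix | None, DecisionTreeClassifier]],
        n_features: int,
        meta: dict | None = None,
    ) -> None:
        self.members = list(members)
        self.n_features = n_features
        self.meta = dict(meta or {})

    @property
    def n_members(self) -> int:
        return len(self.members)

    def vote(self, X: np.ndarray) -> VoteResult:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        votes = np.zeros(X.shape[0])
        for R, tree in self.members:
            Xm = rotate(X, R) if R is not None else X
            votes += (tree.predict(Xm) == ABNORMAL).astype(float)
        return VoteResult(votes_abnormal=votes, total=float(self.n_members))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.vote(X).labels

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.vote(X).score


class ERTModel(MajorityVoteEnsemble):
    """A fitted ensemble of rotation trees (every member carries a rotation)."""


@dataclass
class AdaBoostModel:
    """An AdaBoost.M1 ensemble: weak trees with log(1/beta) voting weights."""

    trees: list[DecisionTreeClassifier]
    alphas: list[float]
    n_features: int

    @property
    def n_members(self) -> int:
        return len(self.trees)

    def weighted_votes(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """Summed alpha-weighted abnormal votes and the total alpha mass."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree, alpha in zip(self.trees, self.alphas):
            votes += alpha * (tree.predict(X) == ABNORMAL)
        return votes, float(sum(self.alphas))

    def vote(self, X: np.ndarray) -> VoteResult:
        votes, total = self.weighted_votes(X)
        return VoteResult(votes_abnormal=votes, total=total)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.vote(X).labels

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.vote(X).score


@dataclass
class WeightedVoteEnsemble:
    """Combines the weak learners of several AdaBoost subensembles in one
    summed weighted vote (used by EasyEnsemble and BalanceCascade)."""

    subensembles: list[AdaBoostModel]
    n_features: int
    meta: dict = field(default_factory=dict)

    @property
    def n_weak_learners(self) -> int:
        return sum(m.n_members for m in self.subensembles)

    def vote(self, X: np.ndarray) -> VoteResult:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        votes = np.zeros(X.shape[0])
        total = 0.0
        for sub in self.subensembles:
            v, t = sub.weighted_votes(X)
            votes += v
            total += t
        return VoteResult(votes_abnormal=votes, total=total)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.vote(X).labels

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.vote(X).score


def _check_trainable(train: LabeledDataset, context: str) -> None:
    require_numeric(train, context)
    if train.n_abnormal == 0 or train.n_normal == 0:
        raise DataError(f"{context} needs both classes present")


def _fit_rotation(
    X: np.ndarray,
    L: int,
    fraction: float,
    mode: SampleMode,
    center: bool,
    rng: np.random.Generator,
) -> RotationMatrix:
    """Partition features, PCA each subset on an independent object sample, assemble."""
    n = X.shape[1]
    part = partition_features(n, min(L, n), rng)
    blocks = []
    for subset in part.subsets:
        sample = object_subsample(X.shape[0], fraction, mode, rng)
        blocks.append(fit_block(X[np.ix_(sample, subset)], center=center))
    return assemble_rotation(part, blocks)


def fit_ert(
    train: LabeledDataset,
    M: int = 100,
    L: int = 3,
    base: BaseLearnerSpec = BaseLearnerSpec(),
    fraction: float = 0.5,
    sample_mode: SampleMode = "plain",
    center_pca: bool = True,
    rng: int | np.random.Generator | None = None,
) -> ERTModel:
    """Fit an ensemble of rotation trees.

    Each of the M members independently: draws a balanced undersample D_i
    (all N_a abnormal rows + N_a random normals), partitions the features
    into subsets of size L, fits a PCA block per subset on an object
    sample of D_i (``fraction`` of its rows, default 50%), assembles the
    rotation matrix R_i, and trains a decision tree on D_i R_i.  Members
    are independent given the seed stream and could be fitted in parallel.
    """
    _check_trainable(train, "fit_ert")
    if M < 1:
        raise ValueError("M must be at least 1")
    split = class_split(train)
    if split.n_normal < split.n_abnormal:
        raise DataError("normal class smaller than abnormal class")
    master = as_rng(rng)
    members = []
    for child in master.spawn(M):
        bal = make_balanced(split, child)
        R = _fit_rotation(bal.X, L, fraction, sample_mode, center_pca, child)
        tree = base.make(_tree_seed(child)).fit(rotate(bal.X, R), bal.y)
        members.append((R, tree))
    return ERTModel(
        members,
        n_features=train.n_features,
        meta={"method": "ert", "M": M, "L": L, "fraction": fraction},
    )


def fit_rurf(
    train: LabeledDataset,
    M: int = 100,
    L: int = 3,
    base: BaseLearnerSpec = BaseLearnerSpec(),
    fraction: float = 0.5,
    sample_mode: SampleMode = "plain",
    center_pca: bool = True,
    rng: int | np.random.Generator | None = None,
) -> ERTModel:
    """Rotation forest on undersampled rotations, trees on the full set.

    The rotation matrix of each member is learned on a balanced
    undersample exactly as in :func:`fit_ert`, but the tree is then
    trained on the rotated full (imbalanced) training set.
    """
    _check_trainable(train, "fit_rurf")
    if M < 1:
        raise ValueError("M must be at least 1")
    split = class_split(train)
    if split.n_normal < split.n_abnormal:
        raise DataError("normal class smaller than abnormal class")
    master = as_rng(rng)
    members = []
    for child in master.spawn(M):
        bal = make_balanced(split, child)
        R = _fit_rotation(bal.X, L, fraction, sample_mode, center_pca, child)
        tree = base.make(_tree_seed(child)).fit(rotate(train.features, R), train.labels)
        members.append((R, tree))
    return ERTModel(
        members,
        n_features=train.n_features,
        meta={"method": "rurf", "M": M, "L": L, "fraction": fraction},
    )


def fit_bagging(
    train: LabeledDataset,
    M: int = 100,
    base: BaseLearnerSpec = BaseLearnerSpec(),
    rng: int | np.random.Generator | None = None,
) -> MajorityVoteEnsemble:
    """Bagging: M trees, each on a size-N bootstrap resample; majority vote."""
    _check_trainable(train, "fit_bagging")
    if M < 1:
        raise ValueError("M must be at least 1")
    N = train.n_examples
    master = as_rng(rng)
    members = []
    for child in master.spawn(M):
        idx = child.integers(0, N, size=N)
        tree = base.make(_tree_seed(child)).fit(train.features[idx], train.labels[idx])
        members.append((None, tree))
    return MajorityVoteEnsemble(
        members, n_features=train.n_features, meta={"method": "bagging", "M": M}
    )


def _adaboost_m1(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int,
    base: BaseLearnerSpec,
    rng: np.random.Generator,
) -> AdaBoostModel:
    """AdaBoost.M1 on (X, y) with sample-weighted weak trees.

    Per round: fit under the current weights, compute weighted error eps;
    stop early when eps = 0 (the weak learner is already perfect — it is
    kept with a large vote weight) or eps >= 1/2 (the round is discarded).
    Otherwise correct examples are downweighted by beta = eps/(1-eps),
    weights renormalise to sum 1, and the member votes with log(1/beta).
    """
    N = X.shape[0]
    w = np.full(N, 1.0 / N)
    trees: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    for _ in range(rounds):
        tree = base.make(_tree_seed(rng)).fit(X, y, sample_weight=w)
        pred = tree.predict(X)
        wrong = pred != y
        eps = float(w[wrong].sum())
        if eps == 0.0:
            trees.append(tree)
            alphas.append(np.log(1.0 / np.finfo(float).eps))
            break
        if eps >= 0.5:
            break
        beta = eps / (1.0 - eps)
        trees.append(tree)
        alphas.append(float(np.log(1.0 / beta)))
        w = np.where(wrong, w, w * beta)
        w /= w.sum()
    if not trees:  # first weak learner no better than chance: keep it anyway
        tree = base.make(_tree_seed(rng)).fit(X, y, sample_weight=np.full(N, 1.0 / N))
        trees, alphas = [tree], [1.0]
    return AdaBoostModel(trees=trees, alphas=alphas, n_features=X.shape[1])


def fit_adaboost(
    train: LabeledDataset,
    rounds: int = 10,
    base: BaseLearnerSpec = BaseLearnerSpec(),
    rng: int | np.random.Generator | None = None,
) -> AdaBoostModel:
    """AdaBoost.M1 on the raw training set."""
    _check_trainable(train, "fit_adaboost")
    return _adaboost_m1(train.features, train.labels, rounds, base, as_rng(rng))


def fit_easyensemble(
    train: LabeledDataset,
    T_subsets: int = 10,
    rounds: int = 10,
    base: BaseLearnerSpec = WEAK_LEARNER,
    rng: int | np.random.Generator | None = None,
) -> WeightedVoteEnsemble:
    """EasyEnsemble: one AdaBoost per balanced undersample, all weak trees pooled.

    T_subsets independent balanced samples are drawn from the normal
    class; an AdaBoost.M1 with ``rounds`` weak trees is fitted on each
    (T = rounds = 10 gives the standard 100-tree configuration).  The
    final decision sums every weak learner's weighted vote.
    """
    _check_trainable(train, "fit_easyensemble")
    split = class_split(train)
    if split.n_normal < split.n_abnormal:
        raise DataError("normal class smaller than abnormal class")
    master = as_rng(rng)
    subensembles = []
    for child in master.spawn(T_subsets):
        bal = make_balanced(split, child)
        subensembles.append(_adaboost_m1(bal.X, bal.y, rounds, base, child))
    return WeightedVoteEnsemble(
        subensembles,
        n_features=train.n_features,
        meta={"method": "easyensemble", "T": T_subsets, "rounds": rounds},
    )


def fit_balancecascade(
    train: LabeledDataset,
    T_subsets: int = 10,
    rounds: int = 10,
    base: BaseLearnerSpec = WEAK_LEARNER,
    rng: int | np.random.Generator | None = None,
) -> WeightedVoteEnsemble:
    """BalanceCascade: EasyEnsemble with between-stage removal of easy normals.

    After each stage, normal-pool examples that the cascade built so far
    classifies correctly are removed in decreasing confidence order, but
    never below N_a remaining (so the next stage can still be funded).
    Stops early with fewer stages if the pool is exhausted.
    """
    _check_trainable(train, "fit_balancecascade")
    split = class_split(train)
    n_a = split.n_abnormal
    if split.n_normal < n_a:
        raise DataError("normal class smaller than abnormal class")
    master = as_rng(rng)
    pool = np.arange(split.n_normal)  # indices into X_n
    subensembles: list[AdaBoostModel] = []
    pool_sizes: list[int] = []
    for child in master.spawn(T_subsets):
        if pool.size < n_a:
            break
        pool_sizes.append(int(pool.size))
        chosen = np.sort(child.choice(pool.size, size=n_a, replace=False))
        X_stage = np.vstack([split.X_a, split.X_n[pool[chosen]]])
        y_stage = np.concatenate(
            [np.full(n_a, ABNORMAL, dtype=int), np.full(n_a, NORMAL, dtype=int)]
        )
        subensembles.append(_adaboost_m1(X_stage, y_stage, rounds, base, child))
        # cascade-so-far predictions on the remaining normal pool
        cascade = WeightedVoteEnsemble(subensembles, n_features=train.n_features)
        result = cascade.vote(split.X_n[pool])
        correct = result.labels == NORMAL
        max_remove = pool.size - n_a
        if max_remove <= 0 or not correct.any():
            continue
        # remove the most confidently-correct normals first (lowest abnormal score)
        candidates = np.flatnonzero(correct)
        order = candidates[np.argsort(result.score[candidates], kind="stable")]
        drop = order[:max_remove]
        keep = np.ones(pool.size, dtype=bool)
        keep[drop] = False
        pool = pool[keep]
    model = WeightedVoteEnsemble(
        subensembles,
        n_features=train.n_features,
        meta={
            "method": "balancecascade",
            "T": T_subsets,
            "rounds": rounds,
            "pool_sizes": pool_sizes,
        },
    )
    return model


def fit_c45_single(
    train: LabeledDataset, base: BaseLearnerSpec = BaseLearnerSpec()
) -> MajorityVoteEnsemble:
    """A single entropy decision tree on the raw training set (no resampling)."""
    _check_trainable(train, "fit_c45_single")
    tree = base.make(0).fit(train.features, train.labels)
    return MajorityVoteEnsemble(
        [(None, tree)], n_features=train.n_features, meta={"method": "c45"}
    )


def default_methods(
    members: int = 100,
    L: int = 3,
    fraction: float = 0.5,
    T_subsets: int = 10,
    rounds: int = 10,
    base: BaseLearnerSpec = BaseLearnerSpec(),
    weak_base: BaseLearnerSpec = WEAK_LEARNER,
):
    """The standard comparison roster as name -> fit(train, rng) callables.

    Defaults follow the usual benchmark configuration: 100 trees for ERT,
    RURF and Bagging; 10 x 10 weak learners for EasyEnsemble and
    BalanceCascade; one raw tree.
    """
    return {
        "ert": lambda tr, rng: fit_ert(tr, M=members, L=L, base=base, fraction=fraction, rng=rng),
        "rurf": lambda tr, rng: fit_rurf(tr, M=members, L=L, base=base, fraction=fraction, rng=rng),
        "easyensemble": lambda tr, rng: fit_easyensemble(
            tr, T_subsets=T_subsets, rounds=rounds, base=weak_base, rng=rng
        ),
        "balancecascade": lambda tr, rng: fit_balancecascade(
            tr, T_subsets=T_subsets, rounds=rounds, base=weak_base, rng=rng
        ),
        "bagging": lambda tr, rng: fit_bagging(tr, M=members, base=base, rng=rng),
        "c45": lambda tr, rng: fit_c45_single(tr, base=base),
    }
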