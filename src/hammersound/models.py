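"""The six discriminative model configurations.

All six are built from the same base learner — an L2-regularised logistic
regression (inverse regularisation strength C = 0.1) — and differ in how the
training data are split and whether features are reduced to 10 components by
truncated SVD first:

====== =============================== ===========
model  training split                  tSVD (k=10)
====== =============================== ===========
A      single learner, all data        no
B      single learner, all data        yes
C      random subdata, one per learner no
D      random subdata, one per learner yes
E      one learner per operation       no
F      one learner per operation       yes
====== =============================== ===========

For C–F the number of weak learners equals the number of training operations
(K - 1 in a leave-one-operation-out fold), and the ensemble prediction is
the plain arithmetic mean of the learners' predicted probabilities
(probability voting).  Per-operation training (E/F) stratifies away the
between-operation acoustic heterogeneity (patient, stem design, theatre).

Each weak learner standardises features on its own training subset by
default; truncated SVD, when used, is fit per learner on its own (already
standardised) subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import TruncatedSVD
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

log = logging.getLogger(__name__)

MODEL_IDS = ("A", "B", "C", "D", "E", "F")

_TSVD_MODELS = frozenset({"B", "D", "F"})
_RANDOM_SPLIT_MODELS = frozenset({"C", "D"})
_OPERATION_SPLIT_MODELS = frozenset({"E", "F"})

DEFAULT_L2_C = 0.1
DEFAULT_TSVD_K = 10

_LR_TOL = 1e-8
_LR_MAX_ITER = 100_000


class SingleClassError(ValueError):
    """Training labels contain only one class."""


class ModelTrainingError(RuntimeError):
    """Model could not be trained (e.g. every weak learner was skipped)."""


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one of the six model variants."""

    model_id: str
    l2_C: float = DEFAULT_L2_C
    tsvd_k: int = DEFAULT_TSVD_K
    seed: int = 0
    feature_transform: str = "log_power"
    standardize: bool = True
    tsvd_scope: str = "per_learner"  # or "global" (sensitivity variant)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if self.l2_C <= 0 or self.tsvd_k <= 0:
            raise ValueError("l2_C and tsvd_k must be positive")
        if self.tsvd_scope not in ("per_learner", "global"):
            raise ValueError("tsvd_scope must be 'per_learner' or 'global'")

    @property
    def uses_tsvd(self) -> bool:
        return self.model_id in _TSVD_MODELS

    @property
    def is_ensemble(self) -> bool:
        return self.model_id not in ("A", "B")


@dataclass
class WeakLearner:
    """One standardize -> (tSVD) -> logistic-regression component."""

    lr: LogisticRegression
    projection: np.ndarray | None  # (k, d) right-singular-vector basis
    mean_: np.ndarray | None
    scale_: np.ndarray | None
    training_scope: str

    @property
    def lr_weights(self) -> tuple[np.ndarray, float]:
        return self.lr.coef_[0], float(self.lr.intercept_[0])

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is not None:
            X = (X - self.mean_) / self.scale_
        if self.projection is not None:
            X = X @ self.projection.T
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.lr.predict_proba(self._prepare(X))[:, 1]
        return p


@dataclass
class TrainedModel:
    config: ModelConfig
    learners: list[WeakLearner]
    n_features: int
    n_skipped: int = 0

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def fit_lr(X: np.ndarray, y: np.ndarray, l2_C: float = DEFAULT_L2_C) -> LogisticRegression:
    """Fit an L2-penalised logistic regression (deterministic lbfgs solve).

    Raises :class:`SingleClassError` when only one class is present and
    treats failure to converge as an error rather than a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise SingleClassError("training labels contain a single class")
    # L2 penalty (the sklearn default) with inverse strength C
    lr = LogisticRegression(
        C=l2_C, solver="lbfgs", tol=_LR_TOL, max_iter=_LR_MAX_ITER
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            lr.fit(X, y)
        except ConvergenceWarning as exc:  # pragma: no cover - defensive
            raise ModelTrainingError(f"logistic regression failed to converge: {exc}")
    return lr


def fit_tsvd(X: np.ndarray, k: int) -> np.ndarray:
    """Top-k right-singular-vector basis of X (no centering).

    Returns a (k_eff, d) array of orthonormal components; if rank(X) < k the
    basis is truncated to the rank with a logged warning.
    """
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    if k > min(n, d):
        raise ValueError(f"k={k} exceeds min(n, d)={min(n, d)}")
    if k < min(n, d):
        svd = TruncatedSVD(n_components=k, algorithm="arpack", random_state=0)
        svd.fit(X)
        components = svd.components_
        singular = svd.singular_values_
    else:
        _, singular, vt = np.linalg.svd(X, full_matrices=False)
        components = vt[:k]
        singular = singular[:k]
    tol = (singular[0] if len(singular) else 0.0) * 1e-10
    rank = int(np.sum(singular > tol))
    if rank < k:
        log.warning("fit_tsvd: rank %d < requested k=%d; truncating basis", rank, k)
        components = components[:rank]
    return components


def partition_subdata(
    y: np.ndarray,
    n_parts: int,
    seed: int,
    sort_key: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Random near-equal class-stratified partition into ``n_parts`` subsets.

    Indices of each class are shuffled and dealt round-robin from a random
    starting part, so part sizes differ by at most one and every part holds
    both classes whenever each class has at least ``n_parts`` members.
    ``sort_key`` optionally fixes a canonical example order before the seeded
    shuffle, making the partition invariant to the caller's row order.
    """
    y = np.asarray(y)
    n = len(y)
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    if n_parts > n:
        raise ValueError(f"n_parts={n_parts} exceeds n_examples={n}")
    order = np.arange(n) if sort_key is None else np.argsort(sort_key, kind="stable")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in range(n_parts)]
    cursor = int(rng.integers(n_parts))
    for cls in np.unique(y):
        idx = order[np.isin(order, np.flatnonzero(y == cls))]
        idx = rng.permutation(idx)
        for i in idx:
            parts[cursor % n_parts].append(int(i))
            cursor += 1
    return [np.asarray(sorted(p), dtype=int) for p in parts]


def group_by_operation(groups: np.ndarray | list[str]) -> list[np.ndarray]:
    """Index subsets per distinct operation id, in first-appearance order."""
    groups = np.asarray(groups)
    seen: dict = {}
    for i, g in enumerate(groups):
        seen.setdefault(g, []).append(i)
    return [np.asarray(v, dtype=int) for v in seen.values()]


def _standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    return mean, np.where(scale > 0, scale, 1.0)


def _fit_learner(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    scope: str,
    fixed_state: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> WeakLearner:
    """Fit one weak learner; ``fixed_state`` carries a shared (global)
    mean/scale/projection for the global-tSVD sensitivity variant."""
    mean = scale = projection = None
    if fixed_state is not None:
        mean, scale, projection = fixed_state
        if mean is not None:
            X = (X - mean) / scale
        X = X @ projection.T
    else:
        if config.standardize:
            mean, scale = _standardization(X)
            X = (X - mean) / scale
        if config.uses_tsvd:
            k = min(config.tsvd_k, min(X.shape))
            projection = fit_tsvd(X, k)
            X = X @ projection.T
    lr = fit_lr(X, y, config.l2_C)
    return WeakLearner(
        lr=lr, projection=projection, mean_=mean, scale_=scale, training_scope=scope
    )


def _canonical_sort_key(X: np.ndarray, seed: int) -> np.ndarray:
    # seeded random projection gives a row order independent of input order
    rng = np.random.default_rng(seed + 905)
    return X @ rng.standard_normal(X.shape[1])


def train(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | list[str],
) -> TrainedModel:
    """Train one of the six model configurations on grouped training data."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    if not (len(y) == X.shape[0] == len(groups)):
        raise ValueError("X, y and groups must align")
    op_subsets = group_by_operation(groups)
    n_ops = len(op_subsets)
    if config.is_ensemble and n_ops < 2:
        raise ModelTrainingError(
            f"model {config.model_id} needs >= 2 training operations, got {n_ops}"
        )

    if config.model_id in ("A", "B"):
        subsets = [(np.arange(len(y)), "all")]
    elif config.model_id in _RANDOM_SPLIT_MODELS:
        parts = partition_subdata(
            y, n_ops, config.seed, sort_key=_canonical_sort_key(X, config.seed)
        )
        subsets = [(p, f"subdata{i}") for i, p in enumerate(parts)]
    else:  # operation-wise
        subsets = [(p, str(groups[p[0]])) for p in op_subsets]

    fixed_state = None
    if config.uses_tsvd and config.is_ensemble and config.tsvd_scope == "global":
        mean = scale = None
        Xg = X
        if config.standardize:
            mean, scale = _standardization(X)
            Xg = (X - mean) / scale
        projection = fit_tsvd(Xg, min(config.tsvd_k, min(Xg.shape)))
        fixed_state = (mean, scale, projection)

    learners: list[WeakLearner] = []
    n_skipped = 0
    for idx, scope in subsets:
        if len(np.unique(y[idx])) < 2:
            log.warning(
                "train(%s): skipping single-class subset %r (%d examples)",
                config.model_id,
                scope,
                len(idx),
            )
            n_skipped += 1
            continue
        learners.append(_fit_learner(X[idx], y[idx], config, scope, fixed_state))
    if not learners:
        raise ModelTrainingError(
            f"model {config.model_id}: every training subset was single-class"
        )
    return TrainedModel(
        config=config, learners=learners, n_features=X.shape[1], n_skipped=n_skipped
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Ensemble probability vote: arithmetic mean of learner probabilities."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {X.shape}"
        )
    probs = np.stack([ln.predict_proba(X) for ln in model.learners])
    return probs.mean(axis=0)
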