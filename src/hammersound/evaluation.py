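"""Leave-one-operation-out cross-validation and ROC-AUC summaries.

Because strikes within one surgery share the patient, stem design, operator
and theatre acoustics, examples are never split within an operation: each
fold holds out every strike of exactly one operation and trains on all the
others.  Per-fold discrimination is measured by ROC-AUC (the probability a
random positive outscores a random negative, ties counted one half) and a
model x dataset configuration is summarised by the median AUC over folds.
Folds whose held-out operation has a single class (e.g. an operation whose
rasp sequence had one size) have no defined AUC; they are recorded as
undefined and excluded from the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .dataset_builder import Dataset, DatasetSpec, OperationData, build_dataset
from .models import MODEL_IDS, ModelConfig, TrainedModel, predict, train

log = logging.getLogger(__name__)


class UndefinedAUCError(ValueError):
    """ROC-AUC is undefined because the labels contain a single class."""


class EvaluationError(RuntimeError):
    """Cross-validation could not produce any usable fold."""


@dataclass
class Fold:
    """One leave-one-operation-out split (indices into the dataset)."""

    test_operation_id: str
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVResult:
    """Per-fold AUCs and their median for one (dataset, model) pair."""

    dataset_name: str
    model_id: str
    per_fold_auc: dict[str, float | None]
    median_auc: float
    n_folds_used: int  # folds with a defined AUC
    n_folds_total: int

    def defined_aucs(self) -> list[float]:
        return [a for a in self.per_fold_auc.values() if a is not None]


def make_folds(ds: Dataset) -> list[Fold]:
    """One fold per distinct operation id, covering every operation once."""
    groups = ds.groups()
    op_ids = list(dict.fromkeys(ds.operation_ids))  # stable order
    if len(op_ids) < 2:
        raise EvaluationError("leave-one-operation-out needs >= 2 operations")
    folds = []
    for op in op_ids:
        test = np.flatnonzero(groups == op)
        train_ = np.flatnonzero(groups != op)
        folds.append(Fold(test_operation_id=op, train_idx=train_, test_idx=test))
    return folds


def roc_auc(scores, labels) -> float:
    """ROC-AUC in its Mann-Whitney form (ties counted one half)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("ROC-AUC undefined: labels contain one class")
    return float(roc_auc_score(labels, scores))


def evaluate(
    cohort: list[OperationData],
    spec: DatasetSpec,
    config: ModelConfig,
) -> CVResult:
    """Run exhaustive leave-one-operation-out CV for one (dataset, model)."""
    ds = build_dataset(cohort, spec)
    return evaluate_dataset(ds, config)


def evaluate_dataset(ds: Dataset, config: ModelConfig) -> CVResult:
    folds = make_folds(ds)
    per_fold: dict[str, float | None] = {}
    for fold in folds:
        y_test = ds.y[fold.test_idx]
        if len(np.unique(y_test)) < 2:
            log.info(
                "evaluate(%s/%s): fold %s has a single test class; AUC undefined",
                ds.spec.name,
                config.model_id,
                fold.test_operation_id,
            )
            per_fold[fold.test_operation_id] = None
            continue
        groups_train = [ds.operation_ids[i] for i in fold.train_idx]
        model = train(config, ds.X[fold.train_idx], ds.y[fold.train_idx], groups_train)
        scores = predict(model, ds.X[fold.test_idx])
        per_fold[fold.test_operation_id] = roc_auc(scores, y_test)
    defined = [a for a in per_fold.values() if a is not None]
    if not defined:
        raise EvaluationError(
            f"dataset {ds.spec.name}, model {config.model_id}: no usable folds"
        )
    return CVResult(
        dataset_name=ds.spec.name,
        model_id=config.model_id,
        per_fold_auc=per_fold,
        median_auc=float(np.median(defined)),
        n_folds_used=len(defined),
        n_folds_total=len(folds),
    )


def results_table(results: list[CVResult]) -> pd.DataFrame:
    """Model x dataset median-AUC table (NaN marks missing combinations)."""
    datasets = sorted({r.dataset_name for r in results})
    table = pd.DataFrame(index=list(MODEL_IDS), columns=datasets, dtype=float)
    for r in results:
        table.loc[r.model_id, r.dataset_name] = r.median_auc
    table.index.name = "model"
    return table


def results_long(results: list[CVResult]) -> pd.DataFrame:
    """Per-fold AUCs in long format (dataset, model, operation_id, auc)."""
    rows = []
    for r in results:
        for op, auc in r.per_fold_auc.items():
            rows.append(
                {
                    "dataset": r.dataset_name,
                    "model": r.model_id,
                    "operation_id": op,
                    "auc": np.nan if auc is None else auc,
                }
            )
    return pd.DataFrame(rows, columns=["dataset", "model", "operation_id", "auc"])


def audit_group_integrity(ds: Dataset, folds: list[Fold] | None = None) -> bool:
    """Verify that no fold's test operation contributes training examples."""
    if folds is None:
        folds = make_folds(ds)
    groups = ds.groups()
    for fold in folds:
        if np.any(groups[fold.train_idx] == fold.test_operation_id):
            return False
        if not np.all(groups[fold.test_idx] == fold.test_operation_id):
            return False
    covered = np.concatenate([f.test_idx for f in folds])
    return len(covered) == ds.n_examples and len(np.unique(covered)) == ds.n_examples
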