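"""Labeling rules and dataset assembly for binary classification.

Within one operation the rasp sizes ascend to the final implanted size.
Strikes made while rasping the final size are the positive class — the sound
of a seated stem.  Two negative definitions are used:

* negative A — strikes during *minimum*-size rasping (the first, smallest
  rasp of that operation): the acoustically most distant undersized sound;
* negative B — strikes during *all* undersized rasping: a harder contrast,
  since the penultimate size sounds close to the final one.

Three datasets are assembled from a cohort: A (single stem design
[Accolade2], negative A), B (same stem filter, negative B) and C (all stem
designs, negative B).  Dataset C mixes stem designs and is the hardest.
Operations flagged for post-operative stem subsidence are excluded from all
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import STATUS_KEPT, Annotation
from .signal_extraction import StrikeEvent

log = logging.getLogger(__name__)

ROLE_POSITIVE = "positive"
ROLE_NEGATIVE_A = "negativeA"
ROLE_NEGATIVE_B = "negativeB"
ROLES = (ROLE_POSITIVE, ROLE_NEGATIVE_A, ROLE_NEGATIVE_B)

NEGATIVE_DEFINITIONS = (ROLE_NEGATIVE_A, ROLE_NEGATIVE_B)


class DatasetError(ValueError):
    """Raised when a dataset cannot be assembled under its spec."""


@dataclass(frozen=True)
class DatasetSpec:
    """One of the three binary-classification dataset definitions."""

    name: str
    stem_filter: frozenset[str] | None  # None = all stem types
    negative_definition: str

    def admits_stem(self, stem_type: str) -> bool:
        return self.stem_filter is None or stem_type in self.stem_filter


#: The three standard dataset specifications.
DATASET_SPECS: dict[str, DatasetSpec] = {
    "A": DatasetSpec("A", frozenset({"Accolade2"}), ROLE_NEGATIVE_A),
    "B": DatasetSpec("B", frozenset({"Accolade2"}), ROLE_NEGATIVE_B),
    "C": DatasetSpec("C", None, ROLE_NEGATIVE_B),
}


@dataclass
class OperationData:
    """Curated, featurized strikes of one operation.

    ``events``, ``roles`` and the rows of ``features`` are aligned 1:1 and
    contain only kept strikes that received a role.
    """

    annotation: Annotation
    events: list[StrikeEvent]
    roles: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.events)
        if not (len(self.roles) == n and self.features.shape[0] == n):
            raise ValueError("events, roles and feature rows must align 1:1")


@dataclass
class LabeledExample:
    """One strike as a classification example."""

    features: np.ndarray
    y: int
    role: str
    operation_id: str
    stem_type: str
    size_index: int


@dataclass
class Dataset:
    """Assembled binary-classification dataset with operation grouping."""

    X: np.ndarray
    y: np.ndarray
    roles: list[str]
    operation_ids: list[str]
    stem_types: list[str]
    size_indices: list[int]
    events: list[StrikeEvent]
    spec: DatasetSpec

    @property
    def n_examples(self) -> int:
        return len(self.y)

    def groups(self) -> np.ndarray:
        return np.asarray(self.operation_ids)


def label_strikes(
    ann: Annotation, strikes: list[StrikeEvent]
) -> list[tuple[StrikeEvent, str]]:
    """Assign dataset roles to curated strikes.

    Kept strikes at the final size are positive; at the minimum rasped size,
    negative A (which is also an undersized size, hence implicitly negative
    B); at any other size below the final, negative B.  Deleted and
    overlap-excluded strikes get no role.
    """
    ann.validate()
    min_size = ann.rasp_sequence[0]
    final = ann.final_size
    if len(ann.rasp_sequence) == 1:
        log.info(
            "label_strikes(%s): single-size rasp sequence; operation yields "
            "positives only",
            ann.operation_id,
        )
    out: list[tuple[StrikeEvent, str]] = []
    for ev in strikes:
        if ev.status != STATUS_KEPT or ev.size_index is None:
            continue
        if ev.size_index == final:
            out.append((ev, ROLE_POSITIVE))
        elif ev.size_index == min_size:
            out.append((ev, ROLE_NEGATIVE_A))
        elif ev.size_index < final:
            out.append((ev, ROLE_NEGATIVE_B))
    return out


def _role_is_negative(role: str, negative_definition: str) -> bool:
    if negative_definition == ROLE_NEGATIVE_A:
        return role == ROLE_NEGATIVE_A
    # negative B = all undersized strikes, which includes the minimum size
    return role in (ROLE_NEGATIVE_A, ROLE_NEGATIVE_B)


def build_dataset(cohort: list[OperationData], spec: DatasetSpec) -> Dataset:
    """Assemble one dataset from per-operation labeled features.

    Operations flagged ``subsidence_excluded`` are dropped; the stem filter
    then applies; each remaining operation contributes whatever positive and
    negative examples it has.
    """
    if spec.negative_definition not in NEGATIVE_DEFINITIONS:
        raise DatasetError(
            f"unknown negative definition {spec.negative_definition!r}"
        )
    X_rows, y, roles, op_ids, stems, sizes, events = [], [], [], [], [], [], []
    for op in cohort:
        ann = op.annotation
        if ann.subsidence_excluded:
            log.info("build_dataset: dropping %s (subsidence exclusion)", ann.operation_id)
            continue
        if not spec.admits_stem(ann.stem_type):
            continue
        for ev, role, row in zip(op.events, op.roles, op.features):
            if role == ROLE_POSITIVE:
                label = 1
            elif _role_is_negative(role, spec.negative_definition):
                label = 0
            else:
                continue
            X_rows.append(row)
            y.append(label)
            roles.append(role)
            op_ids.append(ann.operation_id)
            stems.append(ann.stem_type)
            sizes.append(int(ev.size_index))
            events.append(ev)
    if not X_rows:
        raise DatasetError(f"dataset {spec.name}: no examples after filtering")
    if len(set(op_ids)) < 2:
        raise DatasetError(
            f"dataset {spec.name}: needs at least 2 operations, "
            f"got {len(set(op_ids))}"
        )
    return Dataset(
        X=np.vstack(X_rows),
        y=np.asarray(y, dtype=int),
        roles=roles,
        operation_ids=op_ids,
        stem_types=stems,
        size_indices=sizes,
        events=events,
        spec=spec,
    )


def dataset_summary(ds: Dataset) -> dict:
    """Bookkeeping counts per role, per operation and per stem type."""
    n = ds.n_examples
    per_role = {r: 0 for r in ROLES}
    for r in ds.roles:
        per_role[r] += 1
    n_pos = int(np.sum(ds.y == 1)) if n else 0
    summary = {
        "dataset": ds.spec.name,
        "n_examples": n,
        "n_positive": n_pos,
        "n_negative": n - n_pos,
        "per_role": per_role,
        "n_operations": len(set(ds.operation_ids)),
    }
    if n:
        df = pd.DataFrame(
            {
                "operation_id": ds.operation_ids,
                "stem_type": ds.stem_types,
                "y": ds.y,
            }
        )
        summary["per_operation"] = (
            df.groupby("operation_id")["y"].agg(n_pos="sum", n_total="count")
        )
        summary["per_stem"] = (
            df.groupby("stem_type")["y"].agg(n_pos="sum", n_total="count")
        )
    else:
        summary["per_operation"] = pd.DataFrame(columns=["n_pos", "n_total"])
        summary["per_stem"] = pd.DataFrame(columns=["n_pos", "n_total"])
    return summary
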