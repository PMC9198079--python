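"""End-to-end orchestration: cohort -> strikes -> features -> CV results.

These functions tie the stages together in memory; the command-line layer in
:mod:`hammersound.cli` is a thin wrapper that adds on-disk artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import CANONICAL_RATE, Annotation, Recording, resample
from .dataset_builder import (
    DATASET_SPECS,
    DatasetSpec,
    OperationData,
    build_dataset,
    dataset_summary,
    label_strikes,
)
from .evaluation import CVResult, evaluate, results_long, results_table
from .models import MODEL_IDS, ModelConfig
from .signal_extraction import (
    DEFAULT_FRAME,
    DEFAULT_HOP,
    DEFAULT_MIN_SEPARATION_S,
    DEFAULT_THRESHOLD_K,
    StrikeEvent,
    curate,
    detect_strikes,
    extract_window,
)
from .spectral_features import FULL_BAND, featurize

log = logging.getLogger(__name__)


@dataclass
class ExtractionParams:
    """Onset-detection knobs (defaults tuned for metallic impacts)."""

    frame: int = DEFAULT_FRAME
    hop: int = DEFAULT_HOP
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S
    threshold_k: float = DEFAULT_THRESHOLD_K
    refine: bool = True


def extract_operation(
    rec: Recording, ann: Annotation, params: ExtractionParams | None = None
) -> list[StrikeEvent]:
    """Detect, curate and status-resolve all strikes of one recording."""
    params = params or ExtractionParams()
    if rec.sample_rate != CANONICAL_RATE:
        rec = resample(rec, CANONICAL_RATE)
    onsets = detect_strikes(
        rec,
        frame=params.frame,
        hop=params.hop,
        min_separation=params.min_separation_s,
        threshold_k=params.threshold_k,
        refine=params.refine,
    )
    return curate(onsets, ann, sample_rate=rec.sample_rate)


def process_operation(
    rec: Recording,
    ann: Annotation,
    params: ExtractionParams | None = None,
    band: tuple[float, float] = FULL_BAND,
    transform: str = "log_power",
) -> OperationData:
    """Full per-operation front end: extraction, labeling, featurisation."""
    if rec.sample_rate != CANONICAL_RATE:
        rec = resample(rec, CANONICAL_RATE)
    events = extract_operation(rec, ann, params)
    labeled = label_strikes(ann, events)
    if not labeled:
        return OperationData(
            annotation=ann, events=[], roles=[], features=np.empty((0, 0))
        )
    windows = [extract_window(rec, ev) for ev, _ in labeled]
    X, _ = featurize(windows, band=band, transform=transform)
    return OperationData(
        annotation=ann,
        events=[ev for ev, _ in labeled],
        roles=[role for _, role in labeled],
        features=X,
    )


def process_cohort(
    pairs: list[tuple[Recording, Annotation]],
    params: ExtractionParams | None = None,
    band: tuple[float, float] = FULL_BAND,
    transform: str = "log_power",
) -> list[OperationData]:
    cohort = []
    for rec, ann in pairs:
        op = process_operation(rec, ann, params, band, transform)
        log.info(
            "processed %s: %d labeled strikes (%s)",
            ann.operation_id,
            len(op.events),
            ann.stem_type,
        )
        cohort.append(op)
    return cohort


def strike_table(cohort: list[OperationData]) -> pd.DataFrame:
    """Long-format table of every labeled strike in a processed cohort."""
    rows = []
    for op in cohort:
        for ev, role in zip(op.events, op.roles):
            rows.append(
                {
                    "operation_id": ev.operation_id,
                    "time_s": ev.onset_time,
                    "size_index": ev.size_index,
                    "status": ev.status,
                    "role": role,
                }
            )
    return pd.DataFrame(
        rows, columns=["operation_id", "time_s", "size_index", "status", "role"]
    )


def run_grid(
    cohort: list[OperationData],
    dataset_names: tuple[str, ...] = ("A", "B", "C"),
    model_ids: tuple[str, ...] = MODEL_IDS,
    seed: int = 0,
    l2_C: float = 0.1,
    tsvd_k: int = 10,
    standardize: bool = True,
) -> tuple[list[CVResult], pd.DataFrame, pd.DataFrame]:
    """Evaluate every (dataset, model) combination by LOOCV.

    Returns the raw :class:`CVResult` list, the per-fold long table and the
    model x dataset median-AUC summary table.
    """
    results: list[CVResult] = []
    for ds_name in dataset_names:
        spec = DATASET_SPECS[ds_name]
        for model_id in model_ids:
            config = ModelConfig(
                model_id=model_id,
                l2_C=l2_C,
                tsvd_k=tsvd_k,
                seed=seed,
                standardize=standardize,
            )
            res = evaluate(cohort, spec, config)
            log.info(
                "dataset %s, model %s: median AUC %.3f over %d/%d folds",
                ds_name,
                model_id,
                res.median_auc,
                res.n_folds_used,
                res.n_folds_total,
            )
            results.append(res)
    return results, results_long(results), results_table(results)
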