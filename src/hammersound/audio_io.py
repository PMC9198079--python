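"""Reading, writing and normalising intraoperative audio recordings.

A recording is a mono waveform captured by a sound-level meter in the
operating theatre while the femoral canal is rasped.  Alongside each WAV file
lives a pair of sidecar files holding the human-curation products for that
operation: which automatically detected onsets are genuine hammer strikes
(and at which rasp size), which were spurious, and which time intervals are
contaminated by conversation or other noise.

The pipeline's canonical sampling convention is 44.1 kHz, 16-bit mono; any
other-rate input is band-limited resampled on ingest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

#: Canonical pipeline sample rate in Hz.  The strike analysis window of 4096
#: samples corresponds to 4096/44100 ~ 0.093 s at this rate, and the Nyquist
#: frequency is 22.05 kHz.
CANONICAL_RATE = 44100

#: Recognised cementless stem designs.
STEM_TYPES = ("Accolade2", "TaperlocCM", "Twinsys", "Optimys", "other")

#: Onset curation statuses stored in the sidecar / strike tables.
STATUS_KEPT = "kept"
STATUS_DELETED = "deleted"
STATUS_EXCLUDED = "excluded_overlap"

ANNOTATION_SCHEMA_VERSION = 1

_INT16_FULL_SCALE = 32767.0


class AnnotationError(ValueError):
    """Raised when an annotation sidecar violates its schema."""


@dataclass
class Recording:
    """A mono audio recording of one operation.

    Parameters
    ----------
    operation_id:
        Identifier of the surgery the audio belongs to.
    samples:
        1-D float array of dimensionless amplitudes, nominally in [-1, 1].
    sample_rate:
        Sampling rate in Hz.
    """

    operation_id: str
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording.samples must be 1-D (mono)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording.samples contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class Annotation:
    """Human-curation sidecar for one recording.

    ``kept_onsets`` are the verified hammer strikes with their rasp-size
    labels; ``deleted_onsets`` are detected events judged not to be strikes
    (monitor beeps, clatter); ``noise_intervals`` are spans contaminated by
    conversation or other noise, used downstream to exclude overlapped
    strikes from featurisation.
    """

    operation_id: str
    stem_type: str
    rasp_sequence: list[int]
    final_size: int
    kept_onsets: list[tuple[float, int]] = field(default_factory=list)
    deleted_onsets: list[float] = field(default_factory=list)
    noise_intervals: list[tuple[float, float]] = field(default_factory=list)
    subsidence_excluded: bool = False
    schema_version: int = ANNOTATION_SCHEMA_VERSION

    def validate(self, duration: float | None = None) -> None:
        """Check schema invariants; raise :class:`AnnotationError` naming the field."""
        if self.stem_type not in STEM_TYPES:
            raise AnnotationError(
                f"stem_type: {self.stem_type!r} not one of {STEM_TYPES}"
            )
        if not self.rasp_sequence:
            raise AnnotationError("rasp_sequence: must be non-empty")
        if any(
            b <= a for a, b in zip(self.rasp_sequence, self.rasp_sequence[1:])
        ):
            raise AnnotationError(
                f"rasp_sequence: must be strictly ascending, got {self.rasp_sequence}"
            )
        if self.final_size != self.rasp_sequence[-1]:
            raise AnnotationError(
                f"final_size: {self.final_size} != last rasped size "
                f"{self.rasp_sequence[-1]}"
            )
        sizes = set(self.rasp_sequence)
        for t, size in self.kept_onsets:
            if size not in sizes:
                raise AnnotationError(
                    f"kept_onsets: size index {size} at t={t:.3f}s not in "
                    f"rasp_sequence {self.rasp_sequence}"
                )
            if t < 0:
                raise AnnotationError(f"kept_onsets: negative time {t}")
        for a, b in self.noise_intervals:
            if not a < b:
                raise AnnotationError(
                    f"noise_intervals: start {a} must precede end {b}"
                )
            if a < 0:
                raise AnnotationError(f"noise_intervals: negative start {a}")
            if duration is not None and b > duration + 1e-9:
                raise AnnotationError(
                    f"noise_intervals: end {b} beyond recording duration "
                    f"{duration:.3f}s"
                )


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Convert raw PCM sample dtype to float64 in [-1, 1]."""
    if samples.dtype == np.int16:
        return samples.astype(np.float64) / _INT16_FULL_SCALE
    if samples.dtype == np.int32:
        return samples.astype(np.float64) / 2147483647.0
    if samples.dtype == np.uint8:
        return (samples.astype(np.float64) - 128.0) / 127.0
    return samples.astype(np.float64)


def read_recording(
    wav_path: str | Path, annotation_path: str | Path | None = None
) -> tuple[Recording, Annotation | None]:
    """Read a WAV file (and optionally its annotation sidecar).

    Multichannel audio is mean-downmixed to mono.  The recording is returned
    at the file's native rate; call :func:`resample` to bring it to the
    canonical 44.1 kHz convention.
    """
    wav_path = Path(wav_path)
    if not wav_path.exists():
        raise FileNotFoundError(wav_path)
    rate, raw = wavfile.read(str(wav_path))
    samples = _to_float(np.asarray(raw))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    rec = Recording(operation_id=wav_path.stem, samples=samples, sample_rate=int(rate))
    ann = None
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        ann.validate(duration=rec.duration)
        rec.operation_id = ann.operation_id
    return rec, ann


def write_recording(rec: Recording, wav_path: str | Path) -> Path:
    """Write a recording as 16-bit PCM WAV, clipping out-of-range amplitudes."""
    wav_path = Path(wav_path)
    wav_path.parent.mkdir(parents=True, exist_ok=True)
    x = rec.samples
    peak = np.max(np.abs(x)) if len(x) else 0.0
    if peak > 1.0:
        log.warning(
            "write_recording(%s): %d samples exceed full scale (peak %.3f); clipping",
            rec.operation_id,
            int(np.sum(np.abs(x) > 1.0)),
            peak,
        )
        x = np.clip(x, -1.0, 1.0)
    pcm = np.round(x * _INT16_FULL_SCALE).astype(np.int16)
    wavfile.write(str(wav_path), int(rec.sample_rate), pcm)
    return wav_path


def resample(rec: Recording, target_rate: int) -> Recording:
    """Band-limited resampling to ``target_rate`` (polyphase)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sample_rate:
        return rec
    g = math.gcd(int(target_rate), int(rec.sample_rate))
    up, down = target_rate // g, rec.sample_rate // g
    samples = resample_poly(rec.samples, up, down)
    return replace(rec, samples=samples, sample_rate=int(target_rate))


# --- annotation sidecar (JSON metadata + CSV onset table) -------------------


def _onsets_csv_path(json_path: Path) -> Path:
    name = json_path.name
    if name.endswith(".annotations.json"):
        stem = name[: -len(".annotations.json")]
    else:
        stem = json_path.stem
    return json_path.with_name(stem + ".onsets.csv")


def write_annotation(ann: Annotation, json_path: str | Path) -> Path:
    """Write the sidecar pair ``<stem>.annotations.json`` + ``<stem>.onsets.csv``."""
    ann.validate()
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": ann.schema_version,
        "operation_id": ann.operation_id,
        "stem_type": ann.stem_type,
        "rasp_sequence": list(map(int, ann.rasp_sequence)),
        "final_size": int(ann.final_size),
        "subsidence_excluded": bool(ann.subsidence_excluded),
        "noise_intervals": [[float(a), float(b)] for a, b in ann.noise_intervals],
    }
    json_path.write_text(json.dumps(meta, indent=1))
    rows = [
        {"time_s": float(t), "size_index": int(s), "status": STATUS_KEPT}
        for t, s in ann.kept_onsets
    ] + [
        {"time_s": float(t), "size_index": "", "status": STATUS_DELETED}
        for t in ann.deleted_onsets
    ]
    df = pd.DataFrame(rows, columns=["time_s", "size_index", "status"])
    df.sort_values("time_s", inplace=True, kind="stable")
    df.to_csv(_onsets_csv_path(json_path), index=False)
    return json_path


def read_annotation(json_path: str | Path) -> Annotation:
    json_path = Path(json_path)
    if not json_path.exists():
        raise FileNotFoundError(json_path)
    try:
        meta = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed annotation JSON: {exc}") from exc
    required = {"operation_id", "stem_type", "rasp_sequence", "final_size"}
    missing = required - set(meta)
    if missing:
        raise AnnotationError(f"annotation missing fields: {sorted(missing)}")
    kept: list[tuple[float, int]] = []
    deleted: list[float] = []
    csv_path = _onsets_csv_path(json_path)
    if csv_path.exists():
        df = pd.read_csv(csv_path)
        for col in ("time_s", "status"):
            if col not in df.columns:
                raise AnnotationError(f"onsets table missing column {col!r}")
        for row in df.itertuples(index=False):
            if row.status == STATUS_KEPT:
                if pd.isna(row.size_index):
                    raise AnnotationError(
                        f"kept onset at t={row.time_s} lacks size_index"
                    )
                kept.append((float(row.time_s), int(row.size_index)))
            elif row.status == STATUS_DELETED:
                deleted.append(float(row.time_s))
            else:
                raise AnnotationError(
                    f"status: unknown onset status {row.status!r}"
                )
    ann = Annotation(
        operation_id=str(meta["operation_id"]),
        stem_type=str(meta["stem_type"]),
        rasp_sequence=[int(s) for s in meta["rasp_sequence"]],
        final_size=int(meta["final_size"]),
        kept_onsets=kept,
        deleted_onsets=deleted,
        noise_intervals=[tuple(iv) for iv in meta.get("noise_intervals", [])],
        subsidence_excluded=bool(meta.get("subsidence_excluded", False)),
        schema_version=int(meta.get("schema_version", ANNOTATION_SCHEMA_VERSION)),
    )
    ann.validate()
    return ann
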