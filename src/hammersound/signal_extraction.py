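"""Strike extraction: onset detection, curation, and fixed-length windows.

The raw theatre audio contains hammer strikes interleaved with conversation,
monitor sounds and background noise.  Extraction proceeds in four steps:

1. automatic onset detection (spectral flux + adaptive threshold),
2. curation against the human-made annotation sidecar (non-strike onsets are
   deleted; the annotation is ground truth),
3. a fixed 4096-sample analysis window from each kept onset
   (4096/44100 ~ 0.093 s),
4. exclusion of strikes whose window overlaps an annotated noise interval.

Only ``kept`` strikes ever reach featurisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .audio_io import (
    STATUS_DELETED,
    STATUS_EXCLUDED,
    STATUS_KEPT,
    Annotation,
    Recording,
)

log = logging.getLogger(__name__)

#: Analysis window length in samples; at 44.1 kHz this spans ~0.093 s from
#: each onset, long enough to capture the ring-down of a metallic impact.
WINDOW_LEN = 4096

#: STFT geometry for the onset-strength envelope.  Metallic impacts ring for
#: ~50-150 ms, so a 1024-sample frame (23 ms) with 256-sample hop resolves
#: individual strikes comfortably.
DEFAULT_FRAME = 1024
DEFAULT_HOP = 256

#: Adaptive-threshold multiplier (moving median + k * moving MAD).
DEFAULT_THRESHOLD_K = 4.0

#: Minimum inter-onset interval; strikes arrive slower than ~6/s.
DEFAULT_MIN_SEPARATION_S = 0.150

#: Curation matching tolerance between detections and annotated onsets.
MATCH_TOLERANCE_S = 0.010


@dataclass
class OnsetEnvelope:
    """Half-wave-rectified spectral-flux envelope of a recording."""

    values: np.ndarray
    frame_rate: float  # envelope frames per second (= sample_rate / hop)
    hop: int
    frame_len: int
    sample_rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("onset envelope must be nonnegative")

    def times(self) -> np.ndarray:
        """Time, per envelope frame, where that frame's new content begins.

        Frame k spans samples [k*hop, k*hop + frame_len); relative to frame
        k-1 its novel content is the trailing ``hop`` samples, so a flux rise
        at frame k places the onset near sample k*hop + frame_len - hop.
        """
        k = np.arange(len(self.values))
        return (k * self.hop + self.frame_len - self.hop) / self.sample_rate


@dataclass
class StrikeEvent:
    """One curated hammer impact."""

    operation_id: str
    onset_time: float
    onset_sample: int
    size_index: int | None
    status: str

    @classmethod
    def at(
        cls,
        operation_id: str,
        onset_time: float,
        sample_rate: int,
        size_index: int | None,
        status: str,
    ) -> "StrikeEvent":
        return cls(
            operation_id=operation_id,
            onset_time=float(onset_time),
            onset_sample=int(round(onset_time * sample_rate)),
            size_index=size_index,
            status=status,
        )


@dataclass
class StrikeWindow:
    """The 4096-sample waveform of one kept strike (zero-padded at file end)."""

    samples: np.ndarray
    source_event: StrikeEvent
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if len(self.samples) != WINDOW_LEN:
            raise ValueError(
                f"StrikeWindow must hold exactly {WINDOW_LEN} samples, "
                f"got {len(self.samples)}"
            )


def onset_strength(
    rec: Recording, frame: int = DEFAULT_FRAME, hop: int = DEFAULT_HOP
) -> OnsetEnvelope:
    """Half-wave-rectified spectral-flux onset envelope.

    Magnitude spectra are taken over rectangular frames (a taper would
    attenuate a transient entering at the frame edge); the envelope value at
    frame k is the summed positive magnitude increment from frame k-1.
    """
    if not frame >= hop > 0:
        raise ValueError("require frame >= hop > 0")
    x = rec.samples
    if len(x) < frame:
        raise ValueError(
            f"recording shorter than one frame ({len(x)} < {frame} samples)"
        )
    n_frames = -(-len(x) // hop)  # ceil
    padded = np.zeros((n_frames - 1) * hop + frame)
    padded[: len(x)] = x
    frames = np.lib.stride_tricks.sliding_window_view(padded, frame)[::hop]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    flux = np.empty(n_frames)
    # no predecessor frame exists for k=0; a magnitude sum there would dwarf
    # genuine flux, so the first value is defined as zero (an onset inside
    # the very first frame is not detectable)
    flux[0] = 0.0
    np.sum(np.clip(np.diff(mags, axis=0), 0.0, None), axis=1, out=flux[1:])
    return OnsetEnvelope(
        values=flux,
        frame_rate=rec.sample_rate / hop,
        hop=hop,
        frame_len=frame,
        sample_rate=rec.sample_rate,
    )


def detect_onsets(
    env: OnsetEnvelope,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    floor_frac: float = 0.1,
) -> list[float]:
    """Pick onset times from an envelope with a moving median + MAD threshold.

    Peaks must exceed (moving median + k * scaled moving MAD) over a ~1 s
    context window and additionally ``floor_frac`` of the envelope maximum
    (impacts dominate the envelope by an order of magnitude, so the floor
    rejects noise-flux excursions in long quiet gaps where the local MAD band
    is tight).  Peaks closer together than ``min_separation`` are greedily
    pruned keeping the larger.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    v = env.values
    if len(v) == 0 or np.all(v == 0):
        return []
    w = int(round(env.frame_rate))  # ~1 s of envelope frames
    w = max(3, w | 1)  # odd
    med = median_filter(v, size=w, mode="nearest")
    mad = median_filter(np.abs(v - med), size=w, mode="nearest")
    # 1.4826 scales the MAD to sigma units (robust z-score), so threshold_k
    # is a robust sigma multiple
    thr = np.maximum(med + threshold_k * 1.4826 * mad, floor_frac * v.max())
    peaks, _ = find_peaks(v)
    peaks = peaks[v[peaks] > thr[peaks]]
    if len(peaks) == 0:
        return []
    # greedy pruning: strongest first, keep if far enough from all kept
    min_gap = min_separation * env.frame_rate
    order = peaks[np.argsort(v[peaks])[::-1]]
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= min_gap for q in kept):
            kept.append(p)
    kept.sort()
    times = env.times()
    return [float(times[p]) for p in kept]


def refine_onsets(
    rec: Recording,
    times: list[float],
    frame: int = DEFAULT_FRAME,
    hop: int = DEFAULT_HOP,
    rel_threshold: float = 0.25,
) -> list[float]:
    """Refine envelope-resolution onset times to sample accuracy.

    Around each coarse time the onset is re-placed at the first sample whose
    smoothed absolute amplitude exceeds ``rel_threshold`` of the local
    maximum — for an impact that decays from its attack this lands within a
    fraction of a period of the true onset.
    """
    x = np.abs(rec.samples)
    sr = rec.sample_rate
    refined = []
    for t in times:
        n0 = int(round(t * sr))
        lo = max(0, n0 - hop)
        hi = min(len(x), n0 + frame)
        seg = x[lo:hi]
        if len(seg) == 0:
            refined.append(t)
            continue
        peak = seg.max()
        if peak <= 0:
            refined.append(t)
            continue
        idx = int(np.argmax(seg > rel_threshold * peak))
        refined.append((lo + idx) / sr)
    return refined


def detect_strikes(
    rec: Recording,
    frame: int = DEFAULT_FRAME,
    hop: int = DEFAULT_HOP,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    refine: bool = True,
) -> list[float]:
    """Convenience: envelope -> peak picking -> sample-level refinement."""
    env = onset_strength(rec, frame=frame, hop=hop)
    times = detect_onsets(env, min_separation=min_separation, threshold_k=threshold_k)
    if refine:
        times = refine_onsets(rec, times, frame=frame, hop=hop)
    return times


def _window_overlaps(onset_sample: int, interval: tuple[float, float], sr: int) -> bool:
    a, b = interval
    return onset_sample < b * sr and onset_sample + WINDOW_LEN > a * sr


def curate(
    onsets: list[float], ann: Annotation, sample_rate: int = 44100
) -> list[StrikeEvent]:
    """Reconcile automatic detections with the human annotation.

    Detections within ±10 ms of an annotated kept onset inherit its rasp-size
    label; unmatched detections and annotation-deleted onsets become
    ``deleted``.  A kept annotation onset with no detection nearby is
    synthesised from the annotation time (the annotation is ground truth) with
    a logged warning.  Finally any kept strike whose 4096-sample window
    intersects an annotated noise interval is marked ``excluded_overlap``.
    """
    ann.validate()
    det = np.asarray(sorted(onsets), dtype=float)
    used = np.zeros(len(det), dtype=bool)
    events: list[StrikeEvent] = []

    for t_ann, size in sorted(ann.kept_onsets):
        onset_t = None
        free = np.flatnonzero(~used)
        if len(free):
            j = free[np.argmin(np.abs(det[free] - t_ann))]
            if abs(det[j] - t_ann) <= MATCH_TOLERANCE_S:
                onset_t = float(det[j])
                used[j] = True
        if onset_t is None:
            log.warning(
                "curate(%s): kept onset at %.3fs had no detection within "
                "±%.0f ms; using annotated time",
                ann.operation_id,
                t_ann,
                MATCH_TOLERANCE_S * 1000,
            )
            onset_t = t_ann
        events.append(
            StrikeEvent.at(ann.operation_id, onset_t, sample_rate, size, STATUS_KEPT)
        )

    # unmatched detections are non-strike sounds the curator deleted
    for j in np.flatnonzero(~used):
        events.append(
            StrikeEvent.at(
                ann.operation_id, float(det[j]), sample_rate, None, STATUS_DELETED
            )
        )
    # annotation-deleted onsets that no detection covered still appear, deleted
    covered = det[~used] if len(det) else np.empty(0)
    for t_del in ann.deleted_onsets:
        if not (len(covered) and np.min(np.abs(covered - t_del)) <= MATCH_TOLERANCE_S):
            events.append(
                StrikeEvent.at(
                    ann.operation_id, float(t_del), sample_rate, None, STATUS_DELETED
                )
            )

    for ev in events:
        if ev.status == STATUS_KEPT and any(
            _window_overlaps(ev.onset_sample, iv, sample_rate)
            for iv in ann.noise_intervals
        ):
            ev.status = STATUS_EXCLUDED

    events.sort(key=lambda e: e.onset_time)
    return events


def extract_window(rec: Recording, ev: StrikeEvent) -> StrikeWindow:
    """Slice the 4096-sample analysis window starting at a kept onset."""
    if ev.status != STATUS_KEPT:
        raise ValueError(f"cannot extract window for status {ev.status!r}")
    s = ev.onset_sample
    if s >= rec.n_samples:
        raise ValueError(
            f"onset sample {s} beyond end of recording ({rec.n_samples} samples)"
        )
    w = np.zeros(WINDOW_LEN)
    avail = min(WINDOW_LEN, rec.n_samples - s)
    w[:avail] = rec.samples[s : s + avail]
    if avail < WINDOW_LEN:
        log.info(
            "extract_window(%s @ %.3fs): zero-padded %.1f%% of window",
            ev.operation_id,
            ev.onset_time,
            100.0 * (WINDOW_LEN - avail) / WINDOW_LEN,
        )
    return StrikeWindow(samples=w, source_event=ev, sample_rate=rec.sample_rate)
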