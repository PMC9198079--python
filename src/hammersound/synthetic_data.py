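"""Synthetic surgical-audio cohorts with known ground truth.

Real intraoperative recordings of femoral rasping are not publicly
available, so every pipeline stage is exercised on simulated cohorts that
emulate the relevant structure of the real data:

* an ascending rasp-size sequence per operation, several hammer strikes per
  size, with the final size judged seated;
* per-operation acoustic heterogeneity — each operation draws its own
  stem-femur resonance (lognormal base frequency) further scaled by a
  stem-design multiplier, standing in for patient anatomy, implant design and
  theatre acoustics;
* a seating effect: as the rasp approaches its final seated state the
  stem-femur complex rings as one stiffer object, modelled as a fractional
  shift ``beta`` of the modal frequencies (and ring-down times) that grows
  with the seating fraction ``s`` (0 at the first rasp, 1 at the final);
* contamination: stationary background noise at a configurable SNR,
  monitor-beep transients (which the curator deletes) and band-limited
  conversation bursts recorded as noise intervals (which exclude overlapped
  strikes).

Each strike is a sum of three exponentially damped sinusoids — the simplest
waveform with controllable modal frequency and damping structure, consistent
with reports of prominent impact energy near 1 kHz and 7 kHz.  With
``beta = 0`` the strike waveform distribution is identical across seating
fractions, giving an exact null for pipeline calibration.

All randomness flows from a single seed through named substreams, so cohorts
are bit-reproducible and any stage can be replayed in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import CANONICAL_RATE, STEM_TYPES, Annotation, Recording

log = logging.getLogger(__name__)

#: Strike ring-down length in seconds (metallic impacts ring ~50-150 ms).
STRIKE_DURATION_S = 0.150

#: Modal structure of one impact: frequency ratios to the fundamental,
#: relative amplitudes, and base ring-down time constants (seconds).
MODE_RATIOS = (1.0, 2.7, 6.3)
MODE_AMPS = (1.0, 0.5, 0.25)
MODE_DECAYS_S = (0.030, 0.012, 0.006)

#: Per-stem-design multiplier on the operation's base resonance; different
#: implant geometries (taper-wedge, full-HA triple taper, short stem) ring
#: at systematically different frequencies, which is what makes the
#: mixed-stem dataset C harder than the single-stem datasets A and B.
STEM_FREQ_MULTIPLIER = {
    "Accolade2": 1.00,   # taper-wedge proximally coated (reference)
    "TaperlocCM": 1.15,  # similar class, slightly different geometry
    "Twinsys": 0.78,     # longer full-HA triple taper rings lower
    "Optimys": 1.45,     # short stem, much stiffer effective length
    "other": 1.0,
}

DEFAULT_STEM_MIX = {
    "Accolade2": 0.55,
    "TaperlocCM": 0.15,
    "Twinsys": 0.15,
    "Optimys": 0.15,
}


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults describe a plausible 29-operation cohort: 3-5 rasp sizes per
    operation, 5-10 strikes per size, a lognormal stem-femur fundamental with
    median 2 kHz and sigma 0.25 across operations, a seating-induced
    fractional modal shift ``seating_shift`` of 0.4 between first and final
    rasp, strikes 20 dB above the noise bed, and an 8% chance that a strike
    is overlapped by a conversation burst.
    """

    n_operations: int = 29
    stem_mix: dict = field(default_factory=lambda: dict(DEFAULT_STEM_MIX))
    strikes_per_size: tuple[int, int] = (5, 10)
    sizes_per_operation: tuple[int, int] = (3, 5)
    base_freq_median_hz: float = 2000.0
    base_freq_sigma: float = 0.25
    seating_shift: float = 0.4
    snr_db: float = 20.0
    contamination_rate: float = 0.08
    beep_rate: float = 2.0  # expected monitor beeps per recording
    strike_interval_s: tuple[float, float] = (0.35, 0.70)
    stage_gap_s: tuple[float, float] = (1.2, 2.0)
    lead_in_s: float = 0.8
    sample_rate: int = CANONICAL_RATE
    seed: int = 0

    def validate(self) -> None:
        if self.n_operations < 1:
            raise ValueError("n_operations must be >= 1")
        if abs(sum(self.stem_mix.values()) - 1.0) > 1e-9:
            raise ValueError("stem_mix proportions must sum to 1")
        if not set(self.stem_mix) <= set(STEM_TYPES):
            raise ValueError(f"unknown stem types in stem_mix: {set(self.stem_mix)}")
        for name in ("strikes_per_size", "sizes_per_operation"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"{name} range must satisfy 1 <= lo <= hi")
        if self.seating_shift < 0:
            raise ValueError("seating_shift must be >= 0")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must be in [0, 1]")
        lo, hi = self.strike_interval_s
        if lo < 0.2:
            raise ValueError("strike intervals below 0.2 s violate ground-truth spacing")


@dataclass
class OperationParams:
    """Per-operation acoustic parameters of the strike model."""

    base_freq_hz: float
    beta: float
    sample_rate: int = CANONICAL_RATE
    freq_jitter: float = 0.01  # per-strike lognormal sigma on mode frequencies
    amp_jitter: float = 0.25  # per-strike lognormal sigma on mode amplitudes


@dataclass
class OperationTruth:
    """Generator-side ground truth for one operation."""

    operation_id: str
    stem_type: str
    base_freq_hz: float
    rasp_sequence: list[int]
    final_size: int
    strike_times: np.ndarray
    strike_sizes: np.ndarray
    seating: np.ndarray  # per-strike seating fraction s in [0, 1]
    contaminated: np.ndarray  # per-strike bool: overlapped by a noise burst
    beep_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.strike_times) < 0.2):
            raise ValueError("ground-truth strikes must be >= 200 ms apart")
        if np.any(np.diff(self.seating) < -1e-12):
            raise ValueError("seating fraction must be nondecreasing")


GroundTruth = list[OperationTruth]


def synth_strike_wave(
    s: float, op: OperationParams, rng: np.random.Generator
) -> np.ndarray:
    """One strike waveform: three damped sinusoids, peak-normalised to 1.

    The modal frequencies and ring-down times are scaled by ``1 + beta * s``
    where ``s`` is the seating fraction; with ``beta = 0`` the waveform
    distribution does not depend on ``s`` at all.
    """
    if not 0 <= s <= 1:
        raise ValueError("seating fraction s must be in [0, 1]")
    n = int(round(STRIKE_DURATION_S * op.sample_rate))
    t = np.arange(n) / op.sample_rate
    shift = 1.0 + op.beta * s
    wave = np.zeros(n)
    for ratio, amp, tau in zip(MODE_RATIOS, MODE_AMPS, MODE_DECAYS_S):
        f = op.base_freq_hz * ratio * shift
        f *= np.exp(rng.normal(0.0, op.freq_jitter))
        f = min(f, 0.45 * op.sample_rate)  # keep modes below Nyquist
        a = amp * np.exp(rng.normal(0.0, op.amp_jitter))
        phase = rng.uniform(0, 2 * np.pi)
        wave += a * np.exp(-t / (tau * shift)) * np.sin(2 * np.pi * f * t + phase)
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def _rasp_sequence(n_sizes: int, rng: np.random.Generator) -> list[int]:
    # ascending sizes starting at 0; occasionally a size is skipped
    steps = rng.choice([1, 2], size=n_sizes - 1, p=[0.8, 0.2]) if n_sizes > 1 else []
    return [0, *np.cumsum(steps).tolist()]


def _conversation_burst(
    n: int, sample_rate: int, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited (100-1000 Hz) noise standing in for conversation."""
    sos = butter(4, [100.0, 1000.0], btype="band", fs=sample_rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    x *= rms / max(np.sqrt(np.mean(x**2)), 1e-12)
    return x


def _beep(sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """A short monitor-beep transient (sharp attack so the detector fires)."""
    dur = rng.uniform(0.05, 0.09)
    n = int(dur * sample_rate)
    t = np.arange(n) / sample_rate
    f = rng.uniform(2400.0, 3200.0)
    env = np.exp(-t / (dur / 3))
    return 0.5 * env * np.sin(2 * np.pi * f * t)


def _generate_operation(
    op_id: str,
    stem_type: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    rasp_sequence: list[int] | None = None,
    strikes_per_size: list[int] | None = None,
    contaminate_strikes: list[int] | None = None,
) -> tuple[OperationTruth, Recording, Annotation]:
    """Render one operation.  The optional overrides pin the session layout
    (used by :func:`worked_example_fixture`); by default layout is random."""
    sr = cfg.sample_rate
    if rasp_sequence is None:
        n_sizes = int(rng.integers(cfg.sizes_per_operation[0], cfg.sizes_per_operation[1] + 1))
        rasp_sequence = _rasp_sequence(n_sizes, rng)
    n_stages = len(rasp_sequence)
    if strikes_per_size is None:
        strikes_per_size = [
            int(rng.integers(cfg.strikes_per_size[0], cfg.strikes_per_size[1] + 1))
            for _ in range(n_stages)
        ]

    base = cfg.base_freq_median_hz * np.exp(rng.normal(0.0, cfg.base_freq_sigma))
    base *= STEM_FREQ_MULTIPLIER[stem_type]
    op = OperationParams(base_freq_hz=base, beta=cfg.seating_shift, sample_rate=sr)

    # schedule strikes: stages separated by gaps, strikes by short intervals
    times, sizes, seating = [], [], []
    extra_gap = 1.0  # clearance around contaminated strikes so a burst
    # flags only its own strike
    t = cfg.lead_in_s
    strike_no = 0
    contaminated_set = set(contaminate_strikes or [])
    explicit_contamination = contaminate_strikes is not None
    contaminated_flags = []
    for stage, (size, n_strikes) in enumerate(zip(rasp_sequence, strikes_per_size)):
        s = stage / (n_stages - 1) if n_stages > 1 else 1.0
        for _ in range(n_strikes):
            if explicit_contamination:
                contam = strike_no in contaminated_set
            else:
                contam = bool(rng.random() < cfg.contamination_rate)
            if contam:
                t += extra_gap
            times.append(t)
            sizes.append(size)
            seating.append(s)
            contaminated_flags.append(contam)
            t += rng.uniform(*cfg.strike_interval_s)
            if contam:
                t += extra_gap
            strike_no += 1
        t += rng.uniform(*cfg.stage_gap_s)

    times = np.asarray(times)
    sizes = np.asarray(sizes, dtype=int)
    seating = np.asarray(seating)
    contaminated = np.asarray(contaminated_flags, dtype=bool)
    duration = times[-1] + 1.0
    n = int(round(duration * sr))

    # render strikes on a silent canvas first to calibrate the noise bed
    canvas = np.zeros(n)
    strike_rms = []
    for ti, si in zip(times, seating):
        w = synth_strike_wave(si, op, rng) * rng.uniform(0.45, 0.75)
        i0 = int(round(ti * sr))
        i1 = min(n, i0 + len(w))
        canvas[i0:i1] += w[: i1 - i0]
        strike_rms.append(np.sqrt(np.mean(w**2)))
    noise_sigma = float(np.mean(strike_rms)) / 10 ** (cfg.snr_db / 20.0)
    x = canvas + rng.normal(0.0, noise_sigma, n)

    # monitor beeps in inter-stage gaps (>= 0.3 s away from any strike)
    beep_times = []
    n_beeps = rng.poisson(cfg.beep_rate)
    for _ in range(n_beeps):
        for _attempt in range(20):
            tb = rng.uniform(0.3, duration - 0.3)
            if np.min(np.abs(times - tb)) > 0.4:
                beep_times.append(tb)
                b = _beep(sr, rng)
                i0 = int(round(tb * sr))
                i1 = min(n, i0 + len(b))
                x[i0:i1] += b[: i1 - i0]
                break
    beep_times = np.asarray(sorted(beep_times))

    # conversation bursts over the flagged strikes
    noise_intervals = []
    for ti in times[contaminated]:
        dur = rng.uniform(0.4, 0.8)
        a = max(0.0, ti - rng.uniform(0.05, 0.15))
        b_end = min(duration, a + dur)
        nb = int((b_end - a) * sr)
        burst = _conversation_burst(nb, sr, rms=0.3 * float(np.mean(strike_rms)), rng=rng)
        i0 = int(round(a * sr))
        x[i0 : i0 + nb] += burst
        noise_intervals.append((float(a), float(b_end)))

    peak = np.max(np.abs(x))
    if peak > 0.99:
        x *= 0.99 / peak

    rec = Recording(operation_id=op_id, samples=x, sample_rate=sr)
    ann = Annotation(
        operation_id=op_id,
        stem_type=stem_type,
        rasp_sequence=list(map(int, rasp_sequence)),
        final_size=int(rasp_sequence[-1]),
        kept_onsets=[(float(ti), int(si)) for ti, si in zip(times, sizes)],
        deleted_onsets=[float(tb) for tb in beep_times],
        noise_intervals=noise_intervals,
    )
    ann.validate(duration=rec.duration)
    truth = OperationTruth(
        operation_id=op_id,
        stem_type=stem_type,
        base_freq_hz=float(base),
        rasp_sequence=list(map(int, rasp_sequence)),
        final_size=int(rasp_sequence[-1]),
        strike_times=times,
        strike_sizes=sizes,
        seating=seating,
        contaminated=contaminated,
        beep_times=beep_times,
    )
    return truth, rec, ann


def generate_cohort(
    cfg: SimConfig,
) -> tuple[GroundTruth, list[tuple[Recording, Annotation]]]:
    """Generate a full cohort of recordings, annotations and ground truth."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_operations + 1)
    rng_cohort = np.random.default_rng(children[0])
    stems = list(cfg.stem_mix)
    probs = np.asarray([cfg.stem_mix[s] for s in stems])
    truths: GroundTruth = []
    pairs: list[tuple[Recording, Annotation]] = []
    for i in range(cfg.n_operations):
        stem = str(rng_cohort.choice(stems, p=probs))
        rng_op = np.random.default_rng(children[i + 1])
        truth, rec, ann = _generate_operation(f"OP{i:03d}", stem, cfg, rng_op)
        truths.append(truth)
        pairs.append((rec, ann))
    return truths, pairs


def worked_example_fixture(
    seed: int = 0,
) -> tuple[GroundTruth, list[tuple[Recording, Annotation]]]:
    """Single-operation cohort matching the canonical worked example.

    One Optimys operation rasped through size indices [0, 2, 3, 4] with final
    size 4; detected strike counts per size are 9/5/7/10 and exactly one
    strike at each of sizes 0, 3 and 4 is overlapped by a conversation burst.
    After curation (overlap exclusion) and labeling this yields 9 positive,
    8 negative-A and 19 negative-B examples.
    """
    cfg = SimConfig(n_operations=1, seed=seed, contamination_rate=0.0, snr_db=25.0)
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rasp_sequence = [0, 2, 3, 4]
    strikes_per_size = [9, 5, 7, 10]
    # one contaminated strike in the middle of sizes 0, 3 and 4
    # (flat strike numbering: size0 -> 0..8, size2 -> 9..13, size3 -> 14..20,
    #  size4 -> 21..30)
    contaminate = [4, 17, 25]
    truth, rec, ann = _generate_operation(
        "OP-EX",
        "Optimys",
        cfg,
        rng,
        rasp_sequence=rasp_sequence,
        strikes_per_size=strikes_per_size,
        contaminate_strikes=contaminate,
    )
    return [truth], [(rec, ann)]
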