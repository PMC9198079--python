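"""FFT power-spectrum features of strike windows.

Each 4096-sample strike window is transformed with a plain (untapered) DFT;
the squared magnitude over all 4096 bins is the raw feature object.  Because
the input is real the spectrum is Hermitian-redundant, so classification
features are taken from the one-sided bins at or below the Nyquist frequency
(22.05 kHz at the canonical 44.1 kHz rate), optionally restricted to a
narrower band and optionally log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_extraction import WINDOW_LEN, StrikeEvent, StrikeWindow

#: Additive floor inside the log transform, ln(power + LOG_EPS).
LOG_EPS = 1e-12

TRANSFORMS = ("raw_power", "log_power")

#: Full one-sided band under the Nyquist frequency at 44.1 kHz.
FULL_BAND = (0.0, 22050.0)


@dataclass
class PowerSpectrum:
    """Squared DFT magnitude of one strike window over all 4096 bins."""

    power: np.ndarray
    bin_hz: float
    nyquist_hz: float

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if len(self.power) != WINDOW_LEN:
            raise ValueError(f"power spectrum must have {WINDOW_LEN} bins")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def n_onesided(self) -> int:
        """Number of non-redundant bins (DC through Nyquist inclusive)."""
        return WINDOW_LEN // 2 + 1

    def bin_centers(self) -> np.ndarray:
        return np.arange(self.n_onesided) * self.bin_hz


@dataclass
class FeatureVector:
    """Band-restricted (optionally log) power features of one strike."""

    values: np.ndarray
    band: tuple[float, float]
    transform: str


def power_spectrum(w: StrikeWindow) -> PowerSpectrum:
    """Full-length FFT power |DFT(w)[k]|^2, k = 0..4095, no taper, no scaling."""
    x = w.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("strike window contains non-finite samples")
    spec = np.fft.fft(x)
    power = (spec.real**2 + spec.imag**2)
    bin_hz = w.sample_rate / WINDOW_LEN
    return PowerSpectrum(power=power, bin_hz=bin_hz, nyquist_hz=w.sample_rate / 2)


def band_bin_indices(ps: PowerSpectrum, f_lo: float, f_hi: float) -> np.ndarray:
    """One-sided bin indices whose centers fall in [f_lo, f_hi]."""
    if not (0 <= f_lo < f_hi <= ps.nyquist_hz):
        raise ValueError(
            f"band must satisfy 0 <= f_lo < f_hi <= {ps.nyquist_hz}, "
            f"got ({f_lo}, {f_hi})"
        )
    centers = ps.bin_centers()
    idx = np.flatnonzero((centers >= f_lo) & (centers <= f_hi))
    if len(idx) == 0:
        raise ValueError(
            f"no bin center falls inside band ({f_lo}, {f_hi}) Hz; "
            f"bin spacing is {ps.bin_hz:.2f} Hz"
        )
    return idx


def select_band(
    ps: PowerSpectrum,
    f_lo: float = FULL_BAND[0],
    f_hi: float = FULL_BAND[1],
    transform: str = "log_power",
) -> FeatureVector:
    """Restrict to one-sided bins in [f_lo, f_hi]; optionally log-transform."""
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    idx = band_bin_indices(ps, f_lo, f_hi)
    values = ps.power[idx]
    if transform == "log_power":
        values = np.log(values + LOG_EPS)
    return FeatureVector(values=values, band=(f_lo, f_hi), transform=transform)


def featurize(
    windows: list[StrikeWindow],
    band: tuple[float, float] = FULL_BAND,
    transform: str = "log_power",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Batch-featurize strike windows.

    Returns a (n_windows, n_bins) matrix whose rows align 1:1 with the input
    windows, plus a row index describing each strike's provenance.
    """
    if not windows:
        raise ValueError("featurize requires at least one window")
    rows = []
    index = []
    for w in windows:
        fv = select_band(power_spectrum(w), band[0], band[1], transform)
        rows.append(fv.values)
        ev: StrikeEvent = w.source_event
        index.append(
            {
                "operation_id": ev.operation_id,
                "time_s": ev.onset_time,
                "size_index": ev.size_index,
                "status": ev.status,
            }
        )
    X = np.vstack(rows)
    return X, pd.DataFrame(index)
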