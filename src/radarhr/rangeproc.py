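"""Range-FFT, static clutter removal and slow-time phase extraction.

The fast-time FFT converts each chirp into a range profile; the complex
value of a range bin evolves over frames (slow time) with the phase
4*pi*d(t)/lambda_c of any scatterer in that bin.  Phase unwrapping,
inter-frame differencing and impulse suppression turn that bin's slow-time
trajectory into a vital-sign series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from radarhr.sim import RadarCube


@dataclass
class RangeMatrix:
    """Complex range profiles, frames x channels x range_bins."""

    values: np.ndarray
    bin_spacing: float  # m
    frame_rate: float   # Hz

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (frames, channels, bins)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("range matrix contains non-finite values")


@dataclass
class PhaseMatrix:
    """Unwrapped slow-time phase, radians, frames x channels x range_bins.

    `power` optionally carries the magnitude-squared of the underlying
    complex bins (same shape).  Downstream bin selection uses it to gate out
    noise-only bins, whose unwrapped phase is an unbounded random walk and
    would otherwise dominate any phase-energy criterion.
    """

    values: np.ndarray
    frame_rate: float
    power: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]


def range_fft(cube: RadarCube, fft_size: int | None = None,
              chirp: int = 0) -> RangeMatrix:
    """Zero-padded fast-time DFT of one chirp per frame and channel."""
    cfg = cube.config
    if fft_size is None:
        fft_size = cfg.range_fft_size
    if fft_size < cfg.adc_samples_per_chirp:
        raise ValueError("fft_size must be >= adc_samples_per_chirp")
    data = cube.adc[:, chirp, :, :]                 # frames x ch x fast
    values = np.fft.fft(data, n=fft_size, axis=-1)
    spacing = (299_792_458.0 * cfg.adc_samples_per_chirp
               / (2.0 * cfg.bandwidth * fft_size))
    return RangeMatrix(values=values, bin_spacing=spacing,
                       frame_rate=cfg.frame_rate)


def remove_static_clutter(rm: RangeMatrix) -> RangeMatrix:
    """Subtract the slow-time mean per (channel, bin).

    Static scatterers (walls, furniture) contribute a constant complex value
    per bin; removing the mean over the processed group of frames leaves
    only the micro-motion around it.
    """
    if rm.values.shape[0] < 2:
        warnings.warn("single frame: static clutter removal is a no-op")
        return RangeMatrix(rm.values.copy(), rm.bin_spacing, rm.frame_rate)
    out = rm.values - rm.values.mean(axis=0, keepdims=True)
    return RangeMatrix(out, rm.bin_spacing, rm.frame_rate)


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Remove 2*pi jumps so consecutive differences lie in (-pi, pi]."""
    wrapped = np.asarray(wrapped, dtype=float)
    if np.any(np.isnan(wrapped)):
        raise ValueError("NaN in wrapped phase")
    return np.unwrap(wrapped)


def phase_difference(unwrapped: np.ndarray) -> np.ndarray:
    """Inter-frame phase difference; removes any static phase offset."""
    unwrapped = np.asarray(unwrapped, dtype=float)
    return np.diff(unwrapped)


def suppress_impulses(series: np.ndarray, threshold_scale: float = 6.0) -> np.ndarray:
    """Hampel-style impulse removal.

    Samples deviating from the series median by more than
    ``threshold_scale`` times the median absolute deviation are replaced by
    the median of their 5-sample neighbourhood.  With MAD = 0 (constant
    series) only exact outliers are touched, so an all-constant series
    passes through unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 5:
        raise ValueError("series must have at least 5 samples")
    med = np.median(series)
    mad = np.median(np.abs(series - med))
    flagged = np.abs(series - med) > threshold_scale * mad
    if not np.any(flagged):
        return series.copy()
    out = series.copy()
    n = series.size
    for i in np.nonzero(flagged)[0]:
        lo = max(0, i - 2)
        hi = min(n, i + 3)
        out[i] = np.median(series[lo:hi])
    return out


def phase_matrix(rm: RangeMatrix) -> PhaseMatrix:
    """Unwrapped slow-time phase of every (channel, bin) trajectory."""
    phase = np.unwrap(np.angle(rm.values), axis=0)
    return PhaseMatrix(values=phase, frame_rate=rm.frame_rate,
                       power=np.abs(rm.values) ** 2)
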