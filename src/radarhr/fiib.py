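"""Fast iterative interpolated beamforming (FIIB) frequency estimation.

FIIB estimates L complex-exponential components from N samples at near-FFT
cost using an estimate-and-subtract loop.  The coarse stage picks, for each
component, the strongest FFT bin of the spectrum with the leakage of all
other current estimates subtracted.  The fine stage interpolates two
leakage-compensated Fourier coefficients taken half a bin either side of the
current estimate:

    delta = 0.5 * Re[(X_{+1/2} + X_{-1/2}) / (X_{+1/2} - X_{-1/2})]

and moves the estimate by delta/N.  After every component update the complex
amplitude is re-fit with the leakage of the other components removed.  A
real sinusoid is a conjugate pair of exponentials, so L counts exponentials:
L=4 covers two real tones.

All frequencies are normalized, f in [0, 1) cycles/sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FiibConfig:
    """Estimator parameters.

    n_components
        Number of complex exponentials L (a real tone uses two).
    n_iterations
        Maximum number of refinement sweeps Q.
    convergence_eps
        Stop early when every component's frequency moves by less than
        convergence_eps / N (normalized) in a sweep.
    search_band
        Optional (low, high) normalized-frequency interval restricting the
        coarse-stage peak search.
    """

    n_components: int = 4
    n_iterations: int = 10
    convergence_eps: float = 1e-3
    search_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.convergence_eps <= 0:
            raise ValueError("convergence_eps must be positive")


@dataclass
class Component:
    """One estimated exponential: normalized frequency and complex amplitude."""

    frequency: float        # cycles/sample, in [0, 1)
    amplitude: complex
    order_found: int
    flagged: bool = False

    def frequency_hz(self, fs: float) -> float:
        return self.frequency * fs


class NoInBandComponentError(ValueError):
    """No estimated component falls in the requested physical band."""

    def __init__(self, components: list):
        self.components = components
        super().__init__("no component in the heart-rate band")


def dtft_coeff(x: np.ndarray, f) -> complex | np.ndarray:
    """Fractional-frequency DFT coefficient sum_k x(k) e^{-j2*pi*k*f}.

    At f = m/N this equals the m-th N-point DFT coefficient.  `f` may be a
    scalar or an array of normalized frequencies.
    """
    x = np.asarray(x)
    k = np.arange(x.size)
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    out = np.exp(-2j * np.pi * np.outer(f_arr, k)) @ x
    return out[0] if np.isscalar(f) or np.ndim(f) == 0 else out


def leakage_coeff(f_source, f_eval, n: int):
    """Spectral leakage of a unit exponential at f_source evaluated at f_eval.

    The geometric series sum_{k=0}^{N-1} e^{j2*pi*k*(f_source - f_eval)}
    in closed form, with the removable singularity at f_source = f_eval
    (mod 1) evaluated as N.  Accepts scalars or broadcastable arrays.
    """
    delta = np.asarray(f_source, dtype=float) - np.asarray(f_eval, dtype=float)
    delta = np.atleast_1d(delta)
    num = 1.0 - np.exp(2j * np.pi * n * delta)
    den = 1.0 - np.exp(2j * np.pi * delta)
    singular = np.abs(den) < 1e-12
    out = np.empty(delta.shape, dtype=complex)
    out[singular] = n
    np.divide(num, den, out=out, where=~singular)
    if np.ndim(f_source) == 0 and np.ndim(f_eval) == 0:
        return complex(out.reshape(-1)[0])
    return out


def _leakage_sum(components: list, skip: int, f_eval, n: int):
    """Sum of A_i * S_i(f_eval) over active components i != skip."""
    f_eval = np.asarray(f_eval, dtype=float)
    total = np.zeros(f_eval.shape, dtype=complex) if f_eval.ndim else 0.0 + 0.0j
    for i, c in enumerate(components):
        if i == skip or c is None:
            continue
        total = total + c.amplitude * leakage_coeff(c.frequency, f_eval, n)
    return total


def fiib_estimate(x: np.ndarray, cfg: FiibConfig) -> list[Component]:
    """Estimate cfg.n_components exponentials from `x`.

    Components are returned in the order they were found (strongest first at
    the coarse stage); use :func:`reorder_components` for the magnitude-first
    ordering used by the heart-rate readout.
    """
    x = np.asarray(x, dtype=complex)
    n = x.size
    L = cfg.n_components
    if n < 2 * L:
        raise ValueError("need at least 2L samples")

    band_lo, band_hi = cfg.search_band if cfg.search_band else (0.0, 1.0)
    bins = np.arange(n)
    band_mask = (bins / n >= band_lo) & (bins / n <= band_hi)
    if not np.any(band_mask):
        raise ValueError("search_band excludes every FFT bin")

    if not np.any(x):
        warnings.warn("all-zero input: returning zero components")
        return [Component(band_lo, 0.0 + 0.0j, l, flagged=True)
                for l in range(L)]

    X = np.fft.fft(x)
    comps: list[Component | None] = [None] * L
    eps_norm = cfg.convergence_eps / n
    dup_tol = 0.25 / n       # two components this close are redundant

    def coarse_seat(l: int) -> Component:
        """Strongest residual bin with other components' leakage removed."""
        resid = X - _leakage_sum(comps, l, bins / n, n)
        power = np.abs(resid) ** 2
        power[~band_mask] = -1.0
        for i, c in enumerate(comps):
            if i == l or c is None:
                continue
            m = round(c.frequency * n)
            for t in (m - 1, m, m + 1):
                power[t % n] = -1.0
        return Component(int(np.argmax(power)) / n, 0.0 + 0.0j, l)

    def collapsed(l: int) -> bool:
        """l sits on top of a stronger component (redundant duplicate)."""
        c = comps[l]
        for i, other in enumerate(comps):
            if i == l or other is None:
                continue
            dist = abs(c.frequency - other.frequency)
            dist = min(dist, 1.0 - dist)
            if dist < dup_tol and abs(other.amplitude) >= abs(c.amplitude):
                return True
        return False

    def starved(l: int) -> bool:
        """An unmodelled residual peak dwarfs component l's own height."""
        c = comps[l]
        resid = X - np.array(
            [ci.amplitude * leakage_coeff(ci.frequency, bins / n, n)
             for ci in comps if ci is not None]).sum(axis=0)
        resid_peak = np.max(np.abs(resid[band_mask]))
        return resid_peak > 2.0 * abs(c.amplitude) * n

    for q in range(cfg.n_iterations):
        max_shift = 0.0
        for l in range(L):
            if q == 0:
                # coarse: strongest bin of the leakage-subtracted spectrum
                resid = X - _leakage_sum(comps, l, bins / n, n)
                power = np.abs(resid) ** 2
                power[~band_mask] = -1.0
                taken = {round(c.frequency * n) % n
                         for c in comps if c is not None}
                for t in taken:                    # no duplicate coarse bins
                    if 0 <= t < n:
                        power[t] = -1.0
                m_hat = int(np.argmax(power))
                comps[l] = Component(m_hat / n, 0.0 + 0.0j, l)
            else:
                if q >= 2 and (collapsed(l) or starved(l)):
                    # redundant duplicate of a stronger component, or a
                    # component dwarfed by an unmodelled residual peak:
                    # re-seat on the strongest remaining residual
                    # (RELAX-style refresh)
                    comps[l] = coarse_seat(l)
                c = comps[l]
                f_half = np.array([c.frequency + 0.5 / n,
                                   c.frequency - 0.5 / n])
                xp = dtft_coeff(x, f_half)
                xt = xp - _leakage_sum(comps, l, f_half, n)
                denom = xt[0] - xt[1]
                if np.abs(denom) < 1e-300:
                    delta = 0.0
                else:
                    delta = 0.5 * np.real((xt[0] + xt[1]) / denom)
                if not -0.5 <= delta <= 0.5:
                    # outside the interpolator's derivation domain:
                    # re-anchor to the nearest bin and clamp
                    comps[l] = Component(np.round(c.frequency * n) / n,
                                         c.amplitude, c.order_found)
                    c = comps[l]
                    delta = float(np.clip(delta, -0.5, 0.5))
                new_f = (c.frequency + delta / n) % 1.0
                max_shift = max(max_shift, abs(delta / n))
                comps[l] = Component(new_f, c.amplitude, c.order_found)
            # amplitude re-fit with other components' leakage removed
            c = comps[l]
            amp = (dtft_coeff(x, c.frequency)
                   - _leakage_sum(comps, l, c.frequency, n)) / n
            comps[l] = Component(c.frequency, complex(amp), c.order_found)
        if q >= 1 and max_shift < eps_norm:
            break
    return [c for c in comps if c is not None]


def reorder_components(components: list[Component]) -> list[Component]:
    """Stable magnitude-first ordering (largest |amplitude| first)."""
    mags = np.array([abs(c.amplitude) for c in components])
    order = np.argsort(-mags, kind="stable")
    return [components[i] for i in order]


def components_to_csv(components: list[Component], path, fs: float) -> None:
    """Write an estimate list as CSV
    (order_found,freq_norm,freq_hz,amp_abs,amp_phase)."""
    import pandas as pd

    pd.DataFrame([{
        "order_found": c.order_found, "freq_norm": c.frequency,
        "freq_hz": c.frequency * fs, "amp_abs": abs(c.amplitude),
        "amp_phase": np.angle(c.amplitude),
    } for c in components]).to_csv(path, index=False)


def hr_from_components(components: list[Component], fs: float,
                       hr_band: tuple[float, float] = (0.8, 2.0)) -> float:
    """Heart rate in bpm from the strongest in-band component.

    Components are reordered magnitude-first; the first one whose physical
    frequency (considering only the positive half, f in (0, 0.5)) lies in
    `hr_band` Hz is read out as 60 * f * fs.
    """
    if not components:
        raise NoInBandComponentError([])
    for c in reorder_components(components):
        if not 0.0 < c.frequency < 0.5:
            continue
        f_hz = c.frequency * fs
        if hr_band[0] <= f_hz <= hr_band[1]:
            return 60.0 * f_hz
    raise NoInBandComponentError(list(components))
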