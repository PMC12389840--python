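"""Variational mode decomposition (VMD) and heartbeat-mode selection.

VMD splits a signal into K narrowband intrinsic mode functions (IMFs) by
minimising the summed bandwidth of the analytic modes subject to the modes
reconstructing the input.  The augmented Lagrangian is solved by ADMM: each
mode spectrum is a Wiener-filtered residual centred on its current
frequency, the centre frequency is the spectral centroid of the mode, and an
optional Lagrange multiplier enforces exact reconstruction.  Updates run on
the one-sided spectrum; modes are reconstructed by Hermitian symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VmdConfig:
    """ADMM parameters for the decomposition.

    n_modes
        Number of IMFs K.
    penalty
        Bandwidth penalty alpha; larger values give narrower modes.
    lagrange_step
        Multiplier ascent step (0 disables the multiplier, which is the
        noise-robust choice: reconstruction is then only approximate).
    tolerance
        Relative change of the mode spectra at which iteration stops.
    """

    n_modes: int = 4
    penalty: float = 1000.0
    lagrange_step: float = 0.0
    tolerance: float = 1e-6
    max_iterations: int = 500
    mirror_extend: bool = True
    init: str = "uniform"       # or "random"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ModeSet:
    """Decomposition result: K real modes and their centre frequencies (Hz)."""

    modes: np.ndarray               # K x n_samples
    center_frequencies: np.ndarray  # Hz, in [0, fs/2]
    n_iterations_used: int
    converged: bool
    fs: float

    def energies(self) -> np.ndarray:
        return np.sum(self.modes ** 2, axis=1)


def vmd_decompose(signal: np.ndarray, fs: float, cfg: VmdConfig) -> ModeSet:
    """Decompose `signal` into cfg.n_modes IMFs.

    The signal is mirror-extended by half its length on both sides (and
    cropped after reconstruction) to suppress boundary artefacts; disable
    with cfg.mirror_extend=False.
    """
    signal = np.asarray(signal, dtype=float)
    n0 = signal.size
    K = cfg.n_modes
    if n0 < 2 * K:
        raise ValueError("signal too short for the requested mode count")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")

    if cfg.mirror_extend:
        half = n0 // 2
        f = np.concatenate([signal[:half][::-1], signal, signal[n0 - half:][::-1]])
    else:
        f = signal
    n = f.size

    # one-sided spectrum on the normalized grid omega in [0, 0.5]
    f_hat = np.fft.fft(f)
    n_pos = n // 2 + 1
    f_plus = f_hat[:n_pos].copy()
    omega_grid = np.arange(n_pos) / n               # cycles/sample

    if cfg.init == "random":
        rng = np.random.default_rng(cfg.init_seed)
        omega = np.sort(rng.uniform(0.0, 0.5, size=K))
    else:
        omega = (np.arange(K) + 0.5) / (2 * K)      # uniform over (0, 0.5)
    u = np.zeros((K, n_pos), dtype=complex)
    lam = np.zeros(n_pos, dtype=complex)
    alpha = cfg.penalty

    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        u_prev = u.copy()
        sum_u = u.sum(axis=0)
        for k in range(K):
            sum_u -= u[k]
            residual = f_plus - sum_u + lam / 2.0
            u[k] = residual / (1.0 + 2.0 * alpha * (omega_grid - omega[k]) ** 2)
            power = np.abs(u[k]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float(np.dot(omega_grid, power) / denom)
            sum_u += u[k]
        if cfg.lagrange_step != 0.0:
            lam = lam + cfg.lagrange_step * (f_plus - sum_u)
        num = np.sum(np.abs(u - u_prev) ** 2)
        den = np.sum(np.abs(u_prev) ** 2)
        if den > 0 and num / den <= cfg.tolerance:
            converged = True
            break
        if den == 0 and num == 0:                   # zero signal fixed point
            converged = True
            break

    # Hermitian reconstruction of real modes
    modes = np.empty((K, n))
    for k in range(K):
        full = np.zeros(n, dtype=complex)
        full[:n_pos] = u[k]
        full[-(n_pos - 1):] = np.conj(u[k][1:][::-1])
        if n % 2 == 0:                               # Nyquist bin is shared
            full[n // 2] = u[k][n // 2].real
        full[0] = u[k][0].real
        modes[k] = np.fft.ifft(full).real
    if cfg.mirror_extend:
        half = n0 // 2
        modes = modes[:, half:half + n0]

    order = np.argsort(omega)
    return ModeSet(modes=modes[order],
                   center_frequencies=omega[order] * fs,
                   n_iterations_used=it, converged=converged, fs=fs)


def select_heartbeat_mode(ms: ModeSet,
                          band: tuple[float, float] = (0.8, 2.0)
                          ) -> tuple[np.ndarray, int, bool]:
    """Pick the heartbeat IMF.

    Among modes whose centre frequency lies in `band` (Hz), the one with the
    largest energy wins.  If no mode is in band, the mode whose centre
    frequency is closest to the band is returned with ``out_of_band=True``.

    Returns ``(mode, index, out_of_band)``.
    """
    if ms.modes.shape[0] == 0:
        raise ValueError("empty mode set")
    cf = ms.center_frequencies
    in_band = (cf >= band[0]) & (cf <= band[1])
    if np.any(in_band):
        energies = np.where(in_band, ms.energies(), -np.inf)
        idx = int(np.argmax(energies))
        return ms.modes[idx], idx, False
    dist = np.maximum(band[0] - cf, 0) + np.maximum(cf - band[1], 0)
    idx = int(np.argmin(dist))
    return ms.modes[idx], idx, True
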