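"""Multi-dimensional coherent accumulation (MDCA).

Frames are processed in non-overlapping groups of J (default 128).  Per
group, the (channel, bin) pair with the largest mean-removed phase energy is
the reference; spatial-domain coherent accumulation (SDCA) then adds the one
other channel whose unwrapped phase correlates best with the reference —
provided the Pearson coefficient clears the threshold gamma (default 0.8),
otherwise the reference phase is doubled.  Temporal accumulation repeats
SDCA at the more energetic of the two bins adjacent to the reference bin and
sums both bin signals.  The accumulated phase is differenced and
impulse-filtered to yield the vital-sign series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from radarhr.rangeproc import PhaseMatrix, phase_difference, suppress_impulses

#: spectral_snr sentinel when the out-of-peak band power underflows
SNR_SENTINEL_DB = 300.0


@dataclass
class GroupSelection:
    """Bookkeeping of the per-group channel/bin choices (0-based indices)."""

    group_index: int
    reference_channel: int
    reference_bin: int
    optimal_channel: int | None
    correlation: float
    adjacent_bin: int | None
    doubled: bool


@dataclass
class VitalSignal:
    """Accumulated differential phase, J-1 samples per group, concatenated."""

    values: np.ndarray
    frame_rate: float
    selections: list = field(default_factory=list)

    def selections_to_csv(self, path) -> None:
        """Write the per-group selection log (group,k0,i0,l,rho,i1,doubled)."""
        import pandas as pd

        pd.DataFrame([{
            "group": s.group_index, "k0": s.reference_channel,
            "i0": s.reference_bin, "l": s.optimal_channel,
            "rho": s.correlation, "i1": s.adjacent_bin,
            "doubled": s.doubled,
        } for s in self.selections]).to_csv(path, index=False)


def phase_energy(pm: PhaseMatrix, channel: int, bin_: int,
                 frame_window: slice) -> float:
    """Mean-removed phase energy sum(x^2) of one (channel, bin) over a group."""
    x = pm.values[frame_window, channel, bin_]
    if x.size == 0:
        raise ValueError("empty frame window")
    x = x - x.mean()
    return float(np.sum(x ** 2))


def _energy_table(pm: PhaseMatrix, frame_window: slice) -> np.ndarray:
    """Energies for all (channel, bin) pairs at once; [channels, bins]."""
    x = pm.values[frame_window]                     # frames x ch x bins
    if x.shape[0] == 0:
        raise ValueError("empty frame window")
    x = x - x.mean(axis=0, keepdims=True)
    return np.sum(x ** 2, axis=0)


#: candidate range bins must carry at least this fraction of the strongest
#: bin's slow-time power before their phase energy is compared (-3 dB,
#: i.e. bins within the main lobe of the strongest reflection)
MAGNITUDE_GATE_REL = 0.5


def select_reference(pm: PhaseMatrix, frame_window: slice) -> tuple[int, int]:
    """(channel, bin) with maximum phase energy; ties -> smallest bin, then channel.

    When the phase matrix carries bin powers, the phase-energy search is
    restricted to bins within :data:`MAGNITUDE_GATE_REL` of the strongest
    bin: the unwrapped phase of a noise-only bin is a random walk whose
    energy is unbounded, so comparing raw phase energies across all bins
    would systematically select empty bins.
    """
    energy = _energy_table(pm, frame_window)
    if pm.power is not None:
        mean_power = pm.power[frame_window].mean(axis=0)   # ch x bins
        gate = mean_power.max(axis=0) >= MAGNITUDE_GATE_REL * mean_power.max()
        energy = np.where(gate[None, :], energy, -np.inf)
    best = np.max(energy)
    cands = np.argwhere(energy == best)             # (channel, bin) rows
    order = np.lexsort((cands[:, 0], cands[:, 1]))  # bin primary, channel secondary
    ch, bin_ = cands[order[0]]
    return int(ch), int(bin_)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient cov(x, y)/(sigma_x sigma_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2))
    sy = np.sqrt(np.sum(yc ** 2))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance series has no correlation")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def sdca(pm: PhaseMatrix, bin_: int, frame_window: slice, gamma: float,
         reference_channel: int | None = None
         ) -> tuple[np.ndarray, int, int | None, float, bool]:
    """Spatial-domain coherent accumulation at one range bin.

    Returns ``(series, k0, l, rho, doubled)``: the accumulated phase over
    the group, the reference channel, the accumulated channel (or None),
    the winning correlation, and whether the fallback doubling branch ran.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    energy = _energy_table(pm, frame_window)[:, bin_]
    if reference_channel is None:
        k0 = int(np.argmax(energy))                 # ties -> smallest index
    else:
        k0 = reference_channel
    ref = pm.values[frame_window, k0, bin_]
    n_ch = pm.n_channels
    if n_ch < 2:
        return 2.0 * ref, k0, None, 1.0, True
    rhos = np.full(n_ch, -np.inf)
    for ch in range(n_ch):
        if ch == k0:
            continue
        try:
            rhos[ch] = pearson(ref, pm.values[frame_window, ch, bin_])
        except ValueError:
            rhos[ch] = -np.inf                      # flat channel: unusable
    l = int(np.argmax(rhos))
    rho_l = float(rhos[l])
    if rho_l >= gamma:
        return ref + pm.values[frame_window, l, bin_], k0, l, rho_l, False
    return 2.0 * ref, k0, None, rho_l, True


def select_adjacent_bin(pm: PhaseMatrix, i0: int, frame_window: slice) -> int:
    """Neighbour of i0 (i0-1 or i0+1) with the higher channel-summed energy.

    With bin powers attached, "energy" is the slow-time reflected power: a
    neighbour dominated by noise has the larger *phase* energy of the two
    precisely because it carries no signal, so the phase criterion is only
    used when no magnitude information exists.
    """
    if pm.power is not None:
        energy = pm.power[frame_window].mean(axis=0).sum(axis=0)
    else:
        energy = _energy_table(pm, frame_window).sum(axis=0)
    n_bins = energy.shape[0]
    cands = [b for b in (i0 - 1, i0 + 1) if 0 <= b < n_bins]
    if not cands:
        raise ValueError("no adjacent bin exists")
    # ties -> smaller index (listed first)
    return int(max(cands, key=lambda b: (energy[b], -b)))


def run_mdca(pm: PhaseMatrix, group_frames: int = 128, gamma: float = 0.8,
             mode: str = "mdca", threshold_scale: float = 6.0,
             lock_reference_channel: bool = False,
             impulse_filter: bool = True) -> VitalSignal:
    """Accumulate, difference and impulse-filter the phase matrix per group.

    ``mode`` selects the accumulation scheme: ``single`` (reference channel
    and bin only), ``egc`` (equal-gain sum of all channels at the reference
    bin), ``sdca`` (spatial accumulation only), ``mdca`` (spatial plus
    adjacent-bin accumulation).
    """
    if mode not in ("single", "egc", "sdca", "mdca"):
        raise ValueError(f"unknown accumulation mode {mode!r}")
    n_frames = pm.n_frames
    if n_frames < group_frames:
        raise ValueError("fewer frames than one group")
    n_groups = n_frames // group_frames
    if n_frames % group_frames:
        warnings.warn(
            f"dropping trailing {n_frames % group_frames} frames "
            f"(< one group of {group_frames})")
    pieces = []
    selections = []
    for g in range(n_groups):
        win = slice(g * group_frames, (g + 1) * group_frames)
        k0, i0 = select_reference(pm, win)
        if mode == "single":
            s = pm.values[win, k0, i0]
            sel = GroupSelection(g, k0, i0, None, 1.0, None, False)
        elif mode == "egc":
            s = pm.values[win, :, i0].sum(axis=1)
            sel = GroupSelection(g, k0, i0, None, 1.0, None, False)
        else:
            s, k0b, l, rho, doubled = sdca(pm, i0, win, gamma,
                                           reference_channel=k0)
            i1 = None
            if mode == "mdca":
                i1 = select_adjacent_bin(pm, i0, win)
                ref1 = k0 if lock_reference_channel else None
                s1, *_ = sdca(pm, i1, win, gamma, reference_channel=ref1)
                s = s + s1
            sel = GroupSelection(g, k0, i0, l, rho, i1, doubled)
        d = phase_difference(s)
        if impulse_filter:
            d = suppress_impulses(d, threshold_scale)
        pieces.append(d)
        selections.append(sel)
    return VitalSignal(values=np.concatenate(pieces),
                       frame_rate=pm.frame_rate, selections=selections)


def spectral_snr(signal: np.ndarray, fs: float,
                 band: tuple[float, float] = (0.8, 2.0)) -> float:
    """Frequency-domain SNR of the strongest in-band peak, dB.

    The peak is the largest DFT magnitude inside the heart-rate band; its
    energy (peak bin +/- 2 bins, clipped to the band) is compared with the
    remaining band energy: SNR = 10*log10(peak energy / rest of band).
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < fs * 2.5:
        raise ValueError("signal too short to resolve the heart-rate band")
    X = np.fft.fft(signal)
    df = fs / n
    k1 = int(band[0] / df)
    k2 = min(int(band[1] / df), n // 2)
    if k2 <= k1:
        raise ValueError("frequency band is empty at this resolution")
    p = np.abs(X[k1:k2 + 1]) ** 2
    kpeak = k1 + int(np.argmax(p))
    lo = max(k1, kpeak - 2)
    hi = min(k2, kpeak + 2)
    peak_energy = float(np.sum(np.abs(X[lo:hi + 1]) ** 2))
    total = float(np.sum(p))
    rest = total - peak_energy
    if rest <= 1e-12 * total:
        warnings.warn("all band energy in the peak; SNR saturated")
        return SNR_SENTINEL_DB
    return 10.0 * np.log10(peak_energy / rest)
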