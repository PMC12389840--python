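"""Synthetic FMCW radar data for vital-sign processing.

Generates IF-signal data cubes (frames x chirps x channels x fast-time
samples) for a single seated subject whose chest wall moves with a
respiration and a heartbeat component, plus the real-valued dual-tone
benchmark series used to characterise frequency estimators.

The IF model for a point scatterer at instantaneous range d(t) is a
fast-time complex exponential at the beat frequency f_b = 2*B*d/(c*T) whose
slow-time phase is phi(t) = 4*pi*d(t)/lambda_c.  Chest displacement is
x(t) = x_r(t) + x_h(t): a respiration sinusoid (with optional harmonics)
plus a heartbeat sinusoid, riding on the nominal range d0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

C_LIGHT = 299_792_458.0  # m/s


@dataclass(frozen=True)
class RadarConfig:
    """FMCW chirp and frame geometry.

    Defaults follow a 77 GHz automotive-grade vital-sign setup: 3.99 GHz
    sweep, 20 Hz frame rate, 200 ADC samples per chirp, two chirps per
    frame, four receive channels, 256-point range FFT.
    """

    start_frequency: float = 77e9        # Hz, fc (chirp start)
    bandwidth: float = 3.99e9            # Hz, B
    chirp_duration: float = 50e-6        # s, T (active sweep)
    frame_period: float = 50e-3          # s
    adc_samples_per_chirp: int = 200
    chirps_per_frame: int = 2
    rx_channels: int = 4
    range_fft_size: int = 256

    def __post_init__(self) -> None:
        for name in ("start_frequency", "bandwidth", "chirp_duration",
                     "frame_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("adc_samples_per_chirp", "chirps_per_frame",
                     "rx_channels", "range_fft_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.range_fft_size < self.adc_samples_per_chirp:
            raise ValueError("range_fft_size must be >= adc_samples_per_chirp")

    @property
    def frame_rate(self) -> float:
        """Slow-time sampling rate fs = 1/frame_period, Hz."""
        return 1.0 / self.frame_period

    @property
    def wavelength(self) -> float:
        """Operating wavelength lambda_c = c/fc, m."""
        return C_LIGHT / self.start_frequency

    @property
    def adc_sample_rate(self) -> float:
        """Fast-time sampling rate, Hz."""
        return self.adc_samples_per_chirp / self.chirp_duration

    @property
    def range_bin_spacing(self) -> float:
        """Range covered by one bin of the zero-padded range FFT, m."""
        return C_LIGHT * self.adc_samples_per_chirp / (
            2.0 * self.bandwidth * self.range_fft_size)

    @property
    def max_unambiguous_range(self) -> float:
        """Range at which the beat frequency reaches Nyquist, m."""
        return C_LIGHT * self.adc_samples_per_chirp / (4.0 * self.bandwidth)

    def beat_frequency(self, distance: float) -> float:
        """Beat frequency of a scatterer at `distance` metres, Hz."""
        return 2.0 * self.bandwidth * distance / (C_LIGHT * self.chirp_duration)


@dataclass(frozen=True)
class VitalParams:
    """Subject motion, channel diversity, clutter and noise.

    Displacement amplitudes default to typical chest-wall values:
    respiration 2 mm, heartbeat 0.2 mm.  Channel gains model four receive
    antennas with unequal magnitudes and phases; each channel additionally
    carries independent noise and a small independent multiplicative phase
    distortion so that inter-channel correlation is realistic (high but not
    perfect).  A second scatterer one range bin beyond the torso front,
    sharing the same motion, spreads vital energy over adjacent bins.
    """

    nominal_range: float = 1.0           # m, d0
    respiration_rate: float = 0.25       # Hz
    respiration_amplitude: float = 2e-3  # m
    heart_rate: float = 1.3              # Hz
    heart_amplitude: float = 2e-4        # m
    respiration_harmonic_weights: tuple = (1.0, 0.2)
    channel_gains: tuple = (
        1.0 + 0.0j,
        0.85 * np.exp(0.5j),
        0.70 * np.exp(1.0j),
        0.55 * np.exp(1.5j),
    )
    channel_noise_std: float | tuple = 6.0
    channel_distortion_std: float = 0.05  # rad, per-frame residual phase jitter
    #: fraction of the chest displacement seen by each receive channel:
    #: antennas at different aspect angles are dominated by different body
    #: patches, so off-axis channels see attenuated (lower-quality) motion
    channel_motion_scale: tuple = (1.0, 0.9, 0.7, 0.5)
    scatterer_jitter_m: float = 2e-5      # independent surface micro-motion
    clutter_amplitude: float = 1.0
    clutter_range: float = 2.0           # m, static background scatterer
    second_scatterer_amplitude: float = 0.8
    second_scatterer_bin_offset: float = 1.0  # range bins from d0
    #: reflection phase of the second scatterer relative to the first;
    #: None draws it uniformly per seed (patch separation is never an exact
    #: half-wavelength multiple, so the relative phase is arbitrary)
    second_scatterer_phase: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.respiration_rate <= 0 or self.heart_rate <= 0:
            raise ValueError("vital-sign rates must be positive")
        if self.respiration_amplitude < 0 or self.heart_amplitude < 0:
            raise ValueError("displacement amplitudes must be non-negative")
        if self.nominal_range <= 0:
            raise ValueError("nominal_range must be positive")

    def noise_std_per_channel(self, n_channels: int) -> np.ndarray:
        std = np.asarray(self.channel_noise_std, dtype=float)
        if std.ndim == 0:
            std = np.full(n_channels, float(std))
        if std.shape != (n_channels,):
            raise ValueError("channel_noise_std must be scalar or one per channel")
        return std


@dataclass(frozen=True)
class ToneSpec:
    """Real dual-tone benchmark series x(n) = a1 cos + a2 cos + AWGN."""

    fs: float = 20.0
    n_samples: int = 200
    amplitudes: tuple = (0.2, 0.15)
    frequencies: tuple = (1.05, 1.20)   # Hz
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.amplitudes) != len(self.frequencies):
            raise ValueError("amplitudes and frequencies must pair up")
        for f in self.frequencies:
            if not 0 < f < self.fs / 2:
                raise ValueError("tone frequencies must lie in (0, fs/2)")

    def replace(self, **kw) -> "ToneSpec":
        return dataclasses.replace(self, **kw)


def random_subject(seed: int, heart_rate_hz: float | None = None) -> VitalParams:
    """Draw one synthetic subject with physiological variability.

    Heart rate uniform in [1.0, 1.67] Hz (60-100 bpm) unless given,
    respiration 0.20-0.33 Hz at 1.5-2.5 mm, heartbeat 0.15-0.30 mm,
    nominal range 0.8-1.2 m.  Noise and channel diversity keep their
    defaults; the same seed drives the cube generation.
    """
    rng = np.random.default_rng(seed)
    if heart_rate_hz is None:
        heart_rate_hz = rng.uniform(1.0, 100.0 / 60.0)
    return VitalParams(
        nominal_range=rng.uniform(0.8, 1.2),
        respiration_rate=rng.uniform(0.20, 0.33),
        respiration_amplitude=rng.uniform(1.5e-3, 2.5e-3),
        heart_rate=heart_rate_hz,
        heart_amplitude=rng.uniform(1.5e-4, 3.0e-4),
        seed=seed,
    )


def gen_displacement(params: VitalParams, config: RadarConfig,
                     n_frames: int) -> np.ndarray:
    """Chest-wall displacement x(t) = x_r(t) + x_h(t) at the frame rate.

    Respiration is a sinusoid with optional harmonic content (weights
    relative to the fundamental); the heartbeat is a pure sinusoid.
    Deterministic: no noise enters the displacement itself.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    t = np.arange(n_frames) * config.frame_period
    xr = np.zeros(n_frames)
    for h, w in enumerate(params.respiration_harmonic_weights, start=1):
        xr += w * np.sin(2 * np.pi * h * params.respiration_rate * t)
    xr *= params.respiration_amplitude
    xh = params.heart_amplitude * np.sin(2 * np.pi * params.heart_rate * t)
    return xr + xh


def gen_radar_cube(config: RadarConfig, params: VitalParams,
                   n_frames: int) -> "RadarCube":
    """Simulate the IF data cube for one subject.

    Each frame/channel holds fast-time samples of a complex exponential
    whose beat frequency tracks d0 + x(t) and whose slow-time phase is
    4*pi*(d0 + x(t))/lambda_c, scaled by the channel gain.  A second
    scatterer sharing the same motion sits one range bin further out, a
    static clutter scatterer sits at `clutter_range`, and complex AWGN is
    added per channel.  Bit-reproducible for a fixed seed.
    """
    if params.nominal_range >= config.max_unambiguous_range:
        raise ValueError(
            f"nominal_range {params.nominal_range} m is beyond the "
            f"unambiguous range {config.max_unambiguous_range:.2f} m")
    rng = np.random.default_rng(params.seed)
    n_ch = config.rx_channels
    n_adc = config.adc_samples_per_chirp
    gains = np.asarray(params.channel_gains, dtype=complex)
    if gains.shape[0] < n_ch:
        raise ValueError("need one complex gain per receive channel")
    gains = gains[:n_ch]
    noise_std = params.noise_std_per_channel(n_ch)

    x = gen_displacement(params, config, n_frames)
    lam = config.wavelength
    n_fast = np.arange(n_adc)
    fs_adc = config.adc_sample_rate

    def scatterer(dist: np.ndarray | float, amp: float,
                  ref_dist: float | None = None) -> np.ndarray:
        """[frames, fast] response of one scatterer at distance dist(t).

        The beat frequency is set by the nominal range ref_dist (micro-motion
        is orders of magnitude below the range resolution); the slow-time
        phase 4*pi*dist(t)/lambda carries the motion.
        """
        dist = np.atleast_1d(np.asarray(dist, dtype=float))
        if ref_dist is None:
            ref_dist = float(np.mean(dist))
        fb = 2.0 * config.bandwidth * ref_dist / (C_LIGHT * config.chirp_duration)
        fast = np.exp(2j * np.pi * fb * n_fast / fs_adc)
        slow = np.exp(4j * np.pi * dist / lam)
        return amp * fast[None, :] * slow[:, None]

    def motion_jitter() -> np.ndarray:
        # incoherent micro-motion of a distinct body patch, common to all
        # channels (it is real displacement) but independent per scatterer
        if params.scatterer_jitter_m <= 0:
            return np.zeros(n_frames)
        return rng.normal(0.0, params.scatterer_jitter_m, size=n_frames)

    jit1 = motion_jitter()
    jit2 = motion_jitter()
    psi = (rng.uniform(0.0, 2 * np.pi)
           if params.second_scatterer_phase is None
           else params.second_scatterer_phase)
    motion_scale = np.asarray(params.channel_motion_scale, dtype=float)
    if motion_scale.shape[0] < n_ch:
        raise ValueError("need one motion scale per receive channel")
    if params.clutter_amplitude > 0:
        clut = scatterer(params.clutter_range, params.clutter_amplitude)[0]
    else:
        clut = np.zeros(n_adc, dtype=complex)

    adc = np.empty((n_frames, config.chirps_per_frame, n_ch, n_adc),
                   dtype=complex)
    for ch in range(n_ch):
        d_ch = params.nominal_range + motion_scale[ch] * x
        sig = scatterer(d_ch + jit1, 1.0, ref_dist=params.nominal_range)
        if params.second_scatterer_amplitude > 0:
            off = params.second_scatterer_bin_offset * config.range_bin_spacing
            sig = sig + np.exp(1j * psi) * scatterer(
                d_ch + jit2 + off, params.second_scatterer_amplitude,
                ref_dist=params.nominal_range + off)
        if params.channel_distortion_std > 0:
            jitter = np.exp(1j * rng.normal(
                0.0, params.channel_distortion_std, size=n_frames))
        else:
            jitter = np.ones(n_frames)
        chan = gains[ch] * sig * jitter[:, None] + clut[None, :]
        noise = noise_std[ch] / np.sqrt(2.0) * (
            rng.standard_normal((n_frames, n_adc))
            + 1j * rng.standard_normal((n_frames, n_adc)))
        # both chirps of a frame see the same slow-time phase
        adc[:, :, ch, :] = (chan + noise)[:, None, :]
    return RadarCube(adc=adc, config=config)


@dataclass
class RadarCube:
    """IF samples, frames x chirps x channels x fast-time, with metadata."""

    adc: np.ndarray
    config: RadarConfig

    def __post_init__(self) -> None:
        if self.adc.ndim != 4:
            raise ValueError("adc must be 4-D (frames, chirps, channels, samples)")

    @property
    def n_frames(self) -> int:
        return self.adc.shape[0]

    def save(self, path) -> None:
        """Write the cube to an HDF5 container (dataset 'adc' + config attrs)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("adc", data=self.adc, track_times=False)
            for fld in dataclasses.fields(RadarConfig):
                f.attrs[fld.name] = getattr(self.config, fld.name)

    @classmethod
    def load(cls, path) -> "RadarCube":
        import h5py

        with h5py.File(path, "r") as f:
            adc = f["adc"][...]
            int_fields = {"adc_samples_per_chirp", "chirps_per_frame",
                          "rx_channels", "range_fft_size"}
            kw = {}
            for fld in dataclasses.fields(RadarConfig):
                v = f.attrs[fld.name]
                kw[fld.name] = int(v) if fld.name in int_fields else float(v)
            return cls(adc=adc, config=RadarConfig(**kw))


def gen_dual_tone(spec: ToneSpec) -> np.ndarray:
    """Real dual-tone series with AWGN at the requested SNR.

    SNR is defined on the total two-tone power (a1^2 + a2^2)/2 over the
    noise variance.  snr_db=+inf returns the noiseless series.
    """
    if np.isneginf(spec.snr_db):
        raise ValueError("snr_db of -inf is not meaningful")
    n = np.arange(spec.n_samples)
    ts = 1.0 / spec.fs
    x = np.zeros(spec.n_samples)
    for a, f in zip(spec.amplitudes, spec.frequencies):
        x += a * np.cos(2 * np.pi * f * n * ts)
    if np.isposinf(spec.snr_db):
        return x
    sig_power = sum(a ** 2 for a in spec.amplitudes) / 2.0
    noise_var = sig_power / 10.0 ** (spec.snr_db / 10.0)
    rng = np.random.default_rng(spec.seed)
    return x + np.sqrt(noise_var) * rng.standard_normal(spec.n_samples)


def add_awgn(series: np.ndarray, snr_db: float, seed: int) -> np.ndarray:
    """Add white Gaussian noise at `snr_db` relative to the series power."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("empty series")
    if np.isposinf(snr_db):
        return series.copy()
    power = float(np.mean(np.abs(series) ** 2))
    if power == 0.0:
        raise ValueError("cannot set an SNR on an all-zero series")
    noise_var = power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    if np.iscomplexobj(series):
        noise = np.sqrt(noise_var / 2.0) * (
            rng.standard_normal(series.shape)
            + 1j * rng.standard_normal(series.shape))
    else:
        noise = np.sqrt(noise_var) * rng.standard_normal(series.shape)
    return series + noise
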