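# Methods

`radarhr` implements a complete non-contact heart-rate (HR) estimation chain
for multi-channel frequency-modulated continuous-wave (FMCW) radar, together
with the synthetic-data generator and Monte-Carlo benchmarks used to
characterise it. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Signal model

An FMCW radar transmits linear chirps of bandwidth B and duration T starting
at carrier fc. Mixing the echo of a scatterer at range d with the transmit
chirp yields an intermediate-frequency (IF) tone at the beat frequency
f_b = 2Bd/(cT) whose phase carries the range at carrier scale,
φ = 4πd/λc with λc = c/fc. For a seated subject at nominal range d0, chest
displacement x(t) = x_r(t) + x_h(t) (respiration plus heartbeat) modulates
the slow-time phase:

    φ(t) = 4π d0/λc + 4π x(t)/λc.

Respiration moves the chest by millimetres (several radians at 77 GHz, i.e.
multiple phase wraps); the heartbeat moves it by a few hundred micrometres
(tenths of a radian). Because x(t) is four orders of magnitude below the
range resolution (≈3 cm), the beat frequency is modelled as fixed at the
scatterer's nominal range; motion enters only through the slow-time phase.
This is the standard small-displacement model and it makes the simulator's
phase law exact, which the tests exploit.

## Synthetic data generator

`radarhr.sim` emits IF data cubes (frames × chirps × channels × fast-time
samples) for a default radar matching a 77 GHz automotive-class device:
3.99 GHz sweep, 20 Hz frame rate, 200 ADC samples per chirp, two chirps per
frame (identical slow-time phase), four receive channels, 256-point range
FFT. Default subject and interference parameters, chosen once from
chest-reflection realism:

| parameter | default | rationale |
|---|---|---|
| respiration | 0.25 Hz, 2 mm, 2nd harmonic at 0.2 weight | typical adult breathing |
| heartbeat | 1.3 Hz (78 bpm), 0.2 mm | typical chest-wall heart displacement |
| channel gains | magnitudes 1.0/0.85/0.70/0.55, distinct phases | unequal antenna illumination |
| channel motion scale | 1.0/0.9/0.7/0.5 | off-axis antennas are dominated by different body patches and see attenuated motion |
| thermal noise | complex AWGN, σ = 6 per channel per ADC sample | places the single-channel spectral SNR near the operating point where accumulation matters (around −7…0 dB after range-FFT gain) |
| channel phase jitter | 0.05 rad/frame | residual per-channel oscillator/LO distortion |
| second scatterer | amplitude 0.8 at +1 range bin, random reflection phase per seed | torso reflections span adjacent bins with comparable strength; patch separation is never an exact half-wavelength multiple, so the relative phase is arbitrary |
| scatterer micro-motion | 20 µm white, independent per scatterer | distinct body patches jitter incoherently |
| static clutter | unit amplitude at 2 m | background furniture/wall |

`random_subject(seed)` draws per-subject variability (HR 60–100 bpm,
respiration 0.20–0.33 Hz at 1.5–2.5 mm, heartbeat 0.15–0.30 mm, range
0.8–1.2 m) for the parameter-recovery studies.

What the generator does **not** emulate: body motion artefacts, multiple
people, antenna array geometry and angle effects, range migration,
non-sinusoidal cardiac waveforms, and real clutter statistics. Passing the
synthetic recovery suites therefore demonstrates that the processing chain
is correct and self-consistent under the stated model, not that it meets
any particular accuracy on real radar recordings.

The dual-tone benchmark series is x(n) = a1 cos(2πf1 nTs) + a2 cos(2πf2 nTs)
plus AWGN, with SNR defined on the total two-tone power (a1²+a2²)/2 over the
noise variance (the definition is recorded here because it is a convention,
not a law; a per-tone definition would shift all SNR axes by a constant).

## Range processing

A zero-padded fast-time FFT of chirp 0 gives the range profile per frame and
channel. Static clutter removal subtracts the slow-time mean per (channel,
bin) over the processed window. Phase is extracted as the argument of the
complex bin value, unwrapped along slow time, differenced between frames
(which also removes any static phase and attenuates respiration relative to
the heartbeat by the differencing gain |2 sin(πf/fs)|), and cleaned by a
Hampel-style impulse rule: samples more than 6 median-absolute-deviations
from the series median are replaced by their 5-sample neighbourhood median.
With MAD = 0 only exact outliers are touched, so constant series pass
through.

## Multi-dimensional coherent accumulation (MDCA)

Frames are processed in non-overlapping groups of J = 128. Per group:

1. **Reference selection** — the (channel, bin) pair with the largest
   mean-removed unwrapped-phase energy Σx² is the reference. The phase
   energy of a *noise-only* bin is an unbounded random walk, so when the
   phase matrix carries bin powers the comparison is restricted to bins
   within −3 dB of the strongest slow-time reflection (the main lobe of the
   subject's echo). Without this gate the criterion systematically selects
   empty bins; with it, the pure phase-energy rule still decides among the
   gated candidates and among channels.
2. **Spatial accumulation (SDCA)** — among the other channels, the one whose
   unwrapped phase has the highest Pearson correlation with the reference is
   added if the correlation clears γ = 0.8; otherwise the reference phase is
   doubled ("fewer but better": a poorly correlated partner would inject
   interference).
3. **Temporal accumulation** — the adjacent bin (i0±1) with the higher
   energy is accumulated the same way and the two bin signals are summed.
   Adjacent-bin "energy" uses slow-time reflected power when available, for
   the same noise-random-walk reason as the gate.
4. The summed phase is differenced and impulse-filtered; groups are
   concatenated and every selection is logged.

Modes `single`, `egc` (equal-gain sum of all channels), `sdca` and `mdca`
expose the ablation ladder. The frequency-domain SNR metric compares the
strongest in-band (0.8–2 Hz) DFT peak (±2 bins, clipped to the band) with
the remaining band energy; a saturated ratio returns a 300 dB sentinel with
a warning.

## Variational mode decomposition (VMD)

VMD splits the vital signal into K narrowband intrinsic mode functions by
ADMM: each mode spectrum is the Wiener-filtered residual
(f̂ − Σ_{i≠k} û_i + λ̂/2)/(1 + 2α(ω − ω_k)²), each centre frequency is the
spectral centroid of its mode, and an optional Lagrange multiplier enforces
exact reconstruction. Updates run on the one-sided spectrum (the analytic
reading of the bandwidth functional); real modes are reconstructed by
Hermitian symmetry. Defaults: K = 4, α = 1000, multiplier off (τ = 0,
noise-robust; reconstruction is then approximate, ≈4% relative error on the
clean two-tone test and smaller for looser α), tolerance 1e-6, 500
iterations max, uniform centre-frequency initialisation over (0, fs/2),
mirror extension by half the signal length against boundary artefacts
(all switchable). α = 1000 was chosen as the narrowest penalty that keeps
the reconstruction error of the two-tone test under 5%.

The heartbeat IMF is the highest-energy mode whose centre frequency lies in
the HR band (0.8–2 Hz); if none qualifies, the mode nearest the band is
returned with an out-of-band flag. This selection rule is this package's
choice; the band+energy rule is the simplest one consistent with how the
band is used elsewhere in the chain.

Because inter-frame differencing amplifies noise toward Nyquist, the
pipeline low-passes the accumulated signal (zero-phase 4th-order
Butterworth, 3 Hz cutoff, configurable) before decomposition; without it
the broadband tail above the physiological band captures most modes and no
mode lands on the heartbeat. The cutoff sits above the HR band and the
relevant respiration harmonics, so it does not affect what VMD has to
separate.

## FIIB frequency estimation

The fast iterative interpolated beamforming estimator models the signal as
L complex exponentials (a real tone is a conjugate pair, so L = 4 covers two
real tones; the HR readout uses only f ∈ (0, 0.5)). One N-point FFT seeds
the loop:

- **Coarse stage (first sweep)** — for each component, the leakage of all
  other current estimates, A_i·S(f_i, k/N) with the closed-form Dirichlet
  kernel S(f_src, f_eval) = (1 − e^{j2πN Δ})/(1 − e^{j2πΔ}), Δ = f_src −
  f_eval (value N at the removable singularity), is subtracted from the FFT
  and the strongest remaining bin is taken. Already-taken bins are excluded
  exactly (radius 0): tones half a bin apart legitimately occupy adjacent
  bins, so any wider exclusion would destroy exactly the sub-bin resolution
  the estimator exists for.
- **Fine stage** — two leakage-compensated Fourier coefficients X̃_{±1/2}
  half a bin either side of the estimate give the offset
  δ = ½·Re[(X̃_{+} + X̃_{−})/(X̃_{+} − X̃_{−})], clamped to its derivation
  domain [−0.5, 0.5] (a raw δ outside it re-anchors the estimate to the
  nearest bin first). The amplitude is re-fit after every component update
  as (1/N)[X(f̂_l) − Σ_{i≠l} A_i S(f_i, f̂_l)].
- **Component refresh** — from the second fine sweep, a component that has
  collapsed within 0.25 bins of a stronger one, or whose own spectral
  height is dwarfed (more than 2×) by an unmodelled residual peak, is
  re-seated on the strongest residual bin. The estimate-subtract design
  needs this: the half-bin error of a coarse seat leaves a residual that
  can out-compete a genuinely distinct second tone, so without a refresh
  all components can pile onto one tone. The 0.25-bin discrimination point
  sits safely below the smallest spacing the resolution claims cover
  (0.4 bins) and far above the noise-induced frequency jitter at the
  benchmark SNR.
- **Stopping** — sweeps stop when every component's frequency moves by less
  than ε/N (ε = 0.001, normalized) or after Q sweeps. The pipeline default
  is Q = 10, which suffices for the well-separated components of a
  VMD-isolated heartbeat. The *close-tone benchmarks* run to the
  convergence criterion with a 60-sweep cap instead: at half-bin spacing
  the sequential leakage-subtraction loop contracts at roughly 0.9 per
  sweep, so a 10-sweep run is convergence-limited (≈0.009 Hz residual bias)
  while the converged estimator reaches the exact two-tone Cramér–Rao
  bound. Accuracy there is a property of the fixed point, not of the sweep
  budget.

After estimation, components are sorted magnitude-first (stable sort); the
HR readout takes the first component whose physical frequency lies in the
HR band, as 60·f·fs bpm. The magnitude-first reordering protects against
reading out a spectrally-leaked interference peak that happened to be found
first.

## Benchmarks and their bounds

`evalbench` provides the dual-tone Monte-Carlo machinery: per SNR point and
trial, estimates are matched to the true tones by nearest distinct
assignment; a missing in-band estimate is charged the worst in-band error
rather than dropped (no survivorship bias). The frequency CRB used is the
asymptotic real-tone bound var(f̂) ≥ 24σ²fs²/((2π)²A²N(N²−1)) — the
factor-24 (not 12) form, since a real sinusoid carries half the energy of a
complex exponential of the same amplitude; it is verified against a numeric
Fisher-information inversion in the tests.

Two bound-driven facts shape what the benchmarks can show:

- At 0.5× FFT-resolution spacing, the exact 6-parameter two-tone CRB at
  20 dB (total-power SNR) is σ(f1) ≈ 0.0011 Hz, σ(f2) ≈ 0.0016 Hz. The
  converged estimator lands within ~1.3× of this; no unbiased estimator can
  do better, whatever the iteration budget.
- At low SNR a detection threshold is intrinsic: at −6 dB the weak tone's
  spectral peak stands only ≈4σ above the Rayleigh noise floor, so a few
  percent of trials are lost to noise peaks and the penalised MSE departs
  the CRB sharply. The MSE/CRB ratio reaches ≤4 only from about −1 dB
  (strong tone) under the total-power SNR convention.

The resolution study counts a trial as resolved when both tone errors are
below half the spacing; the FFT baseline picks the two largest separated
periodogram maxima.

## Pipeline

`run_pipeline` slides 26 s windows with 1 s steps over the recording
(matching a 20-volunteer protocol: 35 windows over a 60 s record), and per
window runs clutter removal → phase extraction → MDCA (4 groups of 128
frames per window, remainder dropped) → low-pass → VMD → heartbeat-mode
selection → FIIB → magnitude-first HR readout. A window with no in-band
component is gap-marked (NaN plus a flag) and the run continues; HR outside
48–120 bpm is clamped with a flag rather than silently reported. Reports
carry per-window component lists, per-group selection logs, and the
spectral SNR of the accumulated versus single-channel signal.

Problem sizes used throughout the test-suite studies — 5000 trials for the
20 dB accuracy study, 500 trials per SNR point for the MSE curve, 200
trials per spacing for the resolution study, 20 subjects × 60 s for the
recovery/ablation study — are the package's standard benchmark settings.

## Known limitations

- The phase-energy selection criteria (reference bin/channel) reward noise
  unless magnitude-gated; the gate needs the complex range matrix, so
  phase-only workflows fall back to the ungated rule.
- VMD mode count K = 4 is not adaptive; strongly non-sinusoidal breathing
  with many in-band harmonics can exhaust the mode budget.
- The FIIB duplicate threshold (0.25 bins) means two genuine tones closer
  than a quarter bin are treated as one; the resolution claims stop at 0.4
  bins.
- Real-data effects (body motion, multipath, posture changes) are out of
  the generator's scope; synthetic RMSE figures do not transfer to
  hardware recordings.
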