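# radarhr

Non-contact heart-rate estimation from multi-channel FMCW radar.

A 77 GHz frequency-modulated continuous-wave radar pointed at a seated
person records, in the phase of its intermediate-frequency signal, the
chest-wall displacement caused by breathing (millimetres) and by the
heartbeat (a few hundred micrometres). Recovering the heart rate from that
phase is hard for three reasons: the heartbeat component is weak and spread
over several receive channels and range bins; respiration harmonics and
cross-modulation products sit right next to the cardiac line; and a plain
FFT over a 26 s window has only ~0.04 Hz (2.3 bpm) of resolution.

`radarhr` implements a processing chain that addresses all three:

- **MDCA** (multi-dimensional coherent accumulation): per group of 128
  frames, the strongest (channel, range-bin) phase signal is combined with
  the best-correlated other channel (Pearson ρ ≥ γ = 0.8, else the
  reference is doubled) and with the more energetic adjacent range bin,
  raising the vital-sign SNR before any spectral analysis.
- **VMD** (variational mode decomposition): ADMM-based separation of the
  accumulated differential phase into narrowband modes
  û_k = (f̂ − Σ_{i≠k}û_i + λ̂/2)/(1 + 2α(ω − ω_k)²), with the heartbeat mode
  selected by centre frequency (0.8–2 Hz) and energy.
- **FIIB** (fast iterative interpolated beamforming): an estimate-and-
  subtract super-resolution frequency estimator. For each of L complex
  exponentials it subtracts the closed-form spectral leakage
  S(f_i, f) = (1 − e^{j2πN(f_i−f)})/(1 − e^{j2π(f_i−f)}) of the other
  components, interpolates two Fourier coefficients half a bin either side
  of the current estimate, δ = ½·Re[(X̃₊½+X̃₋½)/(X̃₊½−X̃₋½)], and refines
  iteratively — resolving tones at half the FFT resolution at near-FFT
  cost. A magnitude-first reordering picks the final heart-rate component.

A synthetic radar-cube generator (IF signal model, per-channel gains and
noise, adjacent-bin energy spread, static clutter) makes the whole chain
testable without hardware, and a benchmark module provides the Monte-Carlo
MSE-versus-SNR and close-tone resolution studies against the Cramér–Rao
bound.

## Worked example

Simulate a 60 s recording of a subject at 1 m with a heart rate of 78 bpm
(1.3 Hz), run the full pipeline, and read the per-window estimates:

```python
import numpy as np
from radarhr import RadarConfig, VitalParams, gen_radar_cube, run_pipeline

cube = gen_radar_cube(RadarConfig(), VitalParams(seed=3), n_frames=1200)
report = run_pipeline(cube)

est = report.hr_series.estimates          # bpm, one per 26 s window
print(f"windows: {est.size}, gaps: {int(np.isnan(est).sum())}")
print(f"median HR: {np.nanmedian(est):.1f} bpm")
print(f"RMSE vs truth: {np.sqrt(np.nanmean((est - 78.0) ** 2)):.2f} bpm")
print(f"median MDCA SNR gain: "
      f"{np.nanmedian(report.snr_mdca_db - report.snr_single_db):.1f} dB")
```

```
windows: 35, gaps: 0
median HR: 78.4 bpm
RMSE vs truth: 0.44 bpm
median MDCA SNR gain: 4.2 dB
```

The 35 windows are the 26 s sliding windows (1 s step) over the 60 s
record. The pipeline recovers the simulated 78 bpm heart rate to well under
a beat per minute, and the accumulated signal's frequency-domain SNR in the
0.8–2 Hz band is several dB above the single-channel signal — the gain that
makes the difference between the cardiac line and a spurious peak being the
strongest in-band component.

The same chain is available from the shell:

```sh
radarhr simulate --seed 3 --duration-s 60 --heart-rate-bpm 78 --out cube.h5
radarhr estimate cube.h5 --out hr.csv --report report.json
radarhr benchmark --trials 500 --out benchmark.csv
```

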