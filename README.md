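# mvnradar

Noncontact heart-rate estimation from frequency-modulated continuous-wave
(FMCW) radar, for researchers in radar-based vital-sign monitoring who
need a fully reproducible, simulation-backed reference pipeline.

A 77 GHz radar pointed at a seated person receives chest echoes whose
phase tracks the millimetric chest displacement: `φ(p) = 4π(l_chest +
h(p))/λ_c`, where `h(p)` superposes respiration (with harmonics) and the
much weaker heartbeat. The package implements the complete chain:

1. **Simulation** — IF frame cubes from a physics-based signal model
   (beat frequency `f_b = 2Bl/(cT_c)`, range resolution `l_res = c/2B`)
   with chest kinematics, static clutter, DC offset, noise, and per-frame
   ground-truth heart rate;
2. **Localization** — Hanning-windowed range FFT, mean reduction
   (`du'_ij = du_ij − mean_i du_ij` per range bin over slow time) to cancel
   DC and static clutter, peak search for the subject bin;
3. **Phase preprocessing** — four-quadrant phase extraction, ±2π
   unwrapping, first differencing `φ_dif(p) = φ(p+1) − φ(p)` (suppresses
   baseline drift and respiration), inward interpolation of jump samples;
4. **MVN** — a masked autoencoder (40% token masking, asymmetric
   8-layer/128-dim encoder and 5-layer/64-dim decoder) pretrained
   self-supervised on unlabeled phase windows, then a 5-layer/64-dim
   vision-transformer head regressing per-window heart rate from the
   frozen encoder's class vector (trained with Adam on MSE; built on the
   package's own numpy autodiff — no deep-learning framework required);
5. **Evaluation** — MSE and average absolute error percentage
   `AAEP = 100·mean(|f − F|/F)`, a classic band-limited spectral-peak
   baseline, and an 8:2 ablation/label-density experiment harness.

See `docs/methods.md` for the model, parameter defaults, and an honest
characterization of what the desk-scale configuration can and cannot do.

## Worked example

```python
from mvnradar import (RadarConfig, SceneSpec, VitalSignProfile,
                      synthesize_recording, range_fft, mean_reduce,
                      locate_subject, select_bins, preprocess_bins,
                      spectral_hr_baseline, window_truth)

config = RadarConfig(duration=60.0)          # 77 GHz, B=3.99 GHz, 50 Hz frames
scene = SceneSpec(subject_distance=0.75,     # chest at 0.75 m
                  static_clutter=((0.60, 5.0),),   # stronger static reflector
                  dc_offset=0.3 + 0.2j, snr_db=10.0)
profile = VitalSignProfile(heart_rate=1.25, heart_drift_std=0.0)

rec = synthesize_recording(config, scene, profile, seed=42)
print("frames:", rec.data.shape[0])

reduced = mean_reduce(range_fft(rec))
bin_idx = locate_subject(reduced)
print(f"subject bin: {bin_idx} ({bin_idx * reduced.bin_spacing:.3f} m)")

phase = preprocess_bins(select_bins(reduced, bin_idx, 5))
est = spectral_hr_baseline(phase[:256, 2], config.frame_rate)
ref = window_truth(rec.truth, 0, 257)
print(f"spectral estimate over 5.12 s: {est:.1f} BPM (reference {ref:.1f} BPM)")
```

Output:

```
frames: 3000
subject bin: 20 (0.751 m)
spectral estimate over 5.12 s: 74.3 BPM (reference 75.0 BPM)
```

The 60 s recording holds exactly 3000 frames; mean reduction lets the
moving chest win the peak search even though the clutter reflector at
0.60 m is five times stronger; and the band-limited spectral peak of the
differenced phase recovers the programmed 75 BPM to within a fraction of
a beat per minute at 10 dB SNR.

Training the network end to end (simulate → preprocess → pretrain →
finetune → evaluate) at smoke scale:

```sh
mvnradar run-all --seed 0 --n-recordings 4 --duration 30 --out runs/demo
```

or via the experiment harness (`mvnradar.evaluation.run_ablation`) for
the full/no-pretraining/linear-head/spectral-baseline comparison at
chosen window length and label density.

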