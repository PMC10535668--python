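# Methods

`mvnradar` implements a complete noncontact heart-rate estimation chain for
frequency-modulated continuous-wave (FMCW) radar: a physics-based signal
simulator, subject localization in range, phase preprocessing, a
masked-autoencoder (MAE) network pretrained self-supervised on unlabeled
phase windows and transferred to heart-rate regression through a vision
transformer (ViT) with a frozen encoder, a classic spectral-peak baseline,
and an experiment harness. This note records the model assumptions, the
parameters that matter, and the numerical/design choices that were
genuinely open.

## Radar signal model

A chirp of bandwidth `B` and duration `T_c` starting at carrier `f_c`
produces, after mixing with the echo of a point reflector at distance `l`,
a complex intermediate-frequency (IF) tone

    y(t) = r · exp( j·2π·f_b·t + j·4π·l/λ_c ),   f_b = 2·B·l / (c·T_c),

so the fast-time DFT concentrates each reflector in the range bin nearest
`l / l_res` with `l_res = c/(2B)` (≈ 3.76 cm at B = 3.99 GHz), independent
of `T_c`. Chest motion `h(t)` is millimetric — four orders of magnitude
below `l_res` — so it is modelled in the **phase term only**:

    φ(t) = 4π (l_chest + h(t)) / λ_c ,

with the beat frequency evaluated at the static chest distance. This
small-displacement approximation is what the entire phase-based method
rests on; it also gives the simulator an exact closed form against which
the pipeline is tested (noise-free subject-bin phase matches `φ(t)` to
float precision). The alternative — letting `h(t)` also modulate the beat
frequency — adds a deterministic term ≈ `2πB·h/c`, about 2.6% of the main
one; it is omitted deliberately so that the closed form is exact.

Default chirp/frame parameters: 77 GHz start frequency, 3.99 GHz
bandwidth, 256 ADC samples, 50 Hz frame rate, 60 s recordings
(3000 frames). One chirp is synthesized per frame: the downstream method
uses exactly one phase sample per frame, so additional chirp loops would
only be averaged away. `T_c` defaults to 64 µs; nothing downstream depends
on it.

## Chest kinematics (what the generator emulates)

    h(t) = A_r · Σ_k a_k · sin(2π k f_r t + θ_k)  +  A_h · sin(Θ_h(t))

* respiration: fundamental `f_r` ~ U[0.2, 0.4] Hz, amplitude `A_r` ~
  U[1, 5] mm, two harmonics with relative amplitudes `a_k = 0.3^k`
  (k = 2, 3) — resting physiology in which respiration dominates the
  displacement by one to two orders of magnitude;
* heartbeat: `A_h` ~ U[0.1, 0.5] mm, rate `f_h` ~ U[1.0, 1.7] Hz with a
  bounded random-walk drift (0.005 Hz·s^-1/2, reflected at the band edges)
  so that windows within one recording carry non-constant labels. The
  heart phase `Θ_h` is the running integral of the instantaneous
  frequency, which reduces to `2π f_h t + θ_h` when the drift is off; the
  per-frame frequency path is stored as ground truth and a window's
  reference label is 60 × its mean over the window.

Scenes add static point clutter, a constant complex DC offset, and
circular complex Gaussian noise whose power is set relative to the subject
echo power (`snr_db`; +∞ disables it). All stochastic draws of a recording
flow from one seeded generator, so recordings are bit-reproducible.

What the generator does **not** emulate: body motion other than chest
kinematics, non-sinusoidal heartbeat waveforms, multipath, antenna
patterns, and multi-channel (MIMO) reception. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
performance on real human data.

## Localization and phase preprocessing

Each frame is Hanning-windowed and DFT-ed; rows of the resulting
range/slow-time matrix are frames. Subtracting each range bin's complex
slow-time mean ("mean reduction") cancels anything constant over slow time
— DC and static clutter — while the periodically moving chest survives.
The subject bin is the one with the largest mean residual magnitude inside
a configurable search range (default 0.3–2.0 m, bin 0 excluded; a
slow-time-variance statistic is available as an alternative). Five bins
centred on the subject (clamped at matrix edges) feed the network.

Per bin: four-quadrant angle → sequential ±2π unwrapping (a step larger
than +π subtracts 2π from the rest of the series, and conversely) → first
difference (removes baseline drift and attenuates any component at
frequency `f` by `2·sin(πf/f_s)`, i.e. low-frequency respiration much more
than the heartbeat) → inward interpolation of jump samples: an interior
sample whose magnitude exceeds a threshold is replaced by the mean of its
two *original* neighbours in one left-to-right pass. The threshold
defaults to 3× the median absolute deviation of the series, which is
scale-free across SNRs; a fixed value and a step-based trigger are
available. The one-argument arctan is deliberately replaced by the
four-quadrant angle: without quadrant recovery the wrapped phase never
spans (−π, π] and unwrapping cannot work.

Windows of 2.56 s or 5.12 s (128/256 frames at 50 Hz) are cut from the
differenced series with a default stride of half a window and z-scored per
window (mean 0, SD 1 over the whole 5×W block). The z-score stabilizes
transformer training across SNR regimes at the cost of absolute-amplitude
information, which carries no rate information.

## The MVN network

Tokens are non-overlapping time patches of `patch_len = 8` frames × 5 bins
flattened to 40-dim vectors (0.16 s per token, below one heartbeat
period; 8 divides both window lengths). The full-size configuration
follows the reference architecture: 8 encoder layers at width 128, 5
decoder layers at width 64, 5 ViT layers at width 64, 16 heads,
feed-forward width 2048, 40% masking, Adam at 5·10⁻⁵. Blocks are
pre-norm transformer encoder layers with a final layer normalization per
stack; positional embeddings are learnable everywhere; the class token is
never masked. The decoder re-inserts a learnable mask token at each masked
position (by original order) and reconstructs the full patch grid through
a linear head; reconstruction MSE is computed on masked tokens only (the
MAE convention; a flag switches to all tokens). During transfer the
encoder runs un-masked and frozen (enforced to bit-identity), a learned
linear projection maps its outputs to the ViT width, and an MLP head reads
the class vector into a single scalar; the regression target is BPM/200 so
targets lie in (0, 1).

Checkpoint selection, not epoch count, is the training contract: both
stages keep the parameters with the lowest held-out loss (10% random
held-out windows for pretraining; for finetuning the held-out split is
group-aware when recording ids are supplied, so overlapping windows of one
recording never sit on both sides and the selected checkpoint reflects
cross-recording error).

### Desk-scale profile

The full-size network is impractical on one CPU, so experiments and tests
use a reduced profile (`MVNConfig.desk_scale()`): 4 encoder layers at
width 32, 2 decoder and 2 ViT layers at width 32, 4 heads, feed-forward
width 64, Adam at 1·10⁻³ (3·10⁻³ for pretraining), 120 pretraining and
300 finetuning epochs, batch 64. The benchmark corpus is scaled
accordingly (see below).

## Baseline and metrics

The classic estimator band-limits the differenced-phase series to
0.8–2.5 Hz (48–150 BPM, covering resting rates) with a zero-phase
4th-order Butterworth band-pass, Hann-windows it, zero-pads the DFT to a
≤ 0.01 Hz grid and returns 60× the in-band argmax. The time-domain filter
matters: masking the spectrum instead leaves sidelobe leakage of the
respiration fundamental (an order of magnitude stronger than the heart
tone even after differencing) which measurably pulls the peak.

Accuracy is reported as MSE and as the average absolute error percentage,
AAEP = 100 · mean(|f − F| / F), over estimation windows.

## Experiment harness

Recordings are split 8:2 at recording level by default (window-level
splitting leaks overlapping windows across the split and is kept behind a
flag only for protocol fidelity); pretraining uses all training windows
unlabeled; a seeded fraction (32/24/16%) of training windows is labeled
for finetuning; AAEP/MSE are evaluated on all test windows. Variants:
`full` (pretrained frozen encoder + ViT head), `no_pretrain` (random
encoder trained jointly with the head — the from-scratch ablation),
`no_vit` (frozen pretrained encoder + single linear readout of the class
vector), `labeled_only` (pretraining restricted to the labeled fraction),
and `spectral_baseline`.

All learned variants receive the labeled set through an identical
frequency-preserving 4× augmentation (time reversal and sign flip, both of
which leave the magnitude spectrum and hence the label unchanged); this
measurably stabilizes finetuning when only a few dozen labeled windows are
available and can be disabled with ``augment=False``.

## Known limitations and honest characterization at desk scale

The central difficulty of this problem is that after differencing the
respiration residual is still several times stronger than the heart tone,
and its third harmonic (3·f_r ∈ 0.6–1.2 Hz) can fall inside the heart
band. Two consequences, both measured with this package:

1. **The spectral baseline is not consistent per window.** On noise-free
   recordings its median error is below one frequency-grid step, but when
   a respiratory harmonic approaches or exceeds the heart tone the peak is
   pulled or captured outright, producing multi-BPM outliers on a minority
   of windows. This is the failure mode that motivates the learned
   estimator, and it bounds what any band-limited peak picker can do.

2. **The desk-scale network only partially isolates the heart tone.**
   Controlled probes show the reduced network regresses the frequency of a
   *dominant* tone across unseen recordings to ~1% AAEP, but when the tone
   is buried under the respiration residual (the realistic composition) a
   width-32 model trained for a few hundred epochs on a few hundred
   windows does not reliably beat a predict-the-training-mean reference.
   The full-size configuration with orders of magnitude more data and
   epochs is outside a single-CPU budget; desk-scale AAEP figures should
   therefore be read as properties of the scaled-down study, not of the
   method at full scale.

Benchmark sizes used by the test suite and the acceptance script are
chosen to keep a complete run tractable on one CPU: corpora of 12
recordings of 60 s at 0 dB SNR per seed, 2.56 s windows at 1.28 s stride,
16% label density, 60 pretraining and 100 finetuning epochs of the
desk-scale profile, and three seeds for majority checks. Under these
conditions the full variant's held-out AAEP is typically 10–20%, it
consistently improves on both the from-scratch and the linear-head
ablations, and the spectral baseline (2–4% AAEP at 0 dB) remains the
stronger absolute estimator — at this scale the ablation *ordering*, not
the absolute error, is the meaningful result.
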