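# Methods

This note documents the models and procedures implemented in `eegcrypt`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic data can and cannot show.

## Synthetic EEG generator

The generator produces labelled multichannel windows with the spectral
structure the classifier relies on; it is a statistical surrogate, not a
biophysical simulation.

* **Background (all classes)**: a sum of 40 random-phase sinusoids with
  frequencies drawn uniformly in 0.5–45 Hz and amplitudes proportional to
  1/f, rescaled so the summed RMS equals `background_amp` (default 20 µV),
  plus a white-noise floor at 10% of that scale. This reproduces the
  canonical 1/f spectral decay of scalp EEG with seed-exact
  reproducibility.
* **Preictal**: background plus a sinusoidal rhythm drawn from 7–9 Hz at
  `preictal_drift_amp` (default 30 µV = 1.5× background), emulating a
  rhythmic buildup before onset.
* **Ictal**: background plus a ~3 Hz spike-wave train at
  `ictal_amp_ratio × background_amp` (default 5×, i.e. 100 µV peak). The
  waveform is a half-wave-rectified, cubed sinusoid (sharp positive spike)
  minus a slow after-wave on the negative lobe — a morphology surrogate
  with the spike-wave's harmonic comb, not a neural-mass model.

Channels are drawn independently (fresh phases and component frequencies
per channel). Per-segment sub-seeds come from `numpy.random.SeedSequence`
spawning, so a dataset is a pure function of its config.

Defaults: 256 Hz sampling, 4 channels, 4 s windows, 3 classes balanced.

**What passing tests do and do not show.** The three classes are separable
by construction (distinct spectral signatures at known bands and
amplitudes); a high cross-validated accuracy demonstrates that the
pipeline — energy transform, imaging, encryption, CNN, fusion — preserves
and exploits that structure end to end. It does not demonstrate clinical
seizure-detection performance: real EEG has artifacts (EMG, eye blinks,
electrode pops), patient-specific morphology, heavy class imbalance, and
non-stationary backgrounds, none of which are modelled.

## Teager–Kaiser energy operator

Discrete form: Ψ(g[n]) = g[n]² − g[n−1]·g[n+1], computed exactly on the
interior; the two boundary samples replicate the nearest interior value
(any fixed convention works — the spectrogram windowing makes the two edge
samples immaterial). For a pure sinusoid A·cos(ωn) the interior value is
the constant A²sin²(ω), which the tests use as a closed-form oracle.

Continuous form: Ψ(g) = ġ² − g·g̈, with ġ and g̈ from second-order central
differences (`numpy.gradient`); the four samples nearest the edges use the
replicate convention, and the valid range excludes two samples per side.

Note the ω-dependence: TKEO weights a component's energy by sin²(ω), so it
*amplifies* high-frequency content relative to low. For seizure imaging
this means the 3 Hz fundamental contributes little directly; the
discriminative signature survives as the spike train's harmonic comb and
the 3 Hz amplitude modulation of the energy envelope. The spectrogram
parameters below are chosen to keep that structure visible.

## Spectrogram imaging

Per channel: (optionally TKEO) → STFT magnitude (Hann window, default
window length `sampling_rate/2` samples, 75% overlap, FFT length the next
power of two ≥ window) → crop to 0–64 Hz → log₁₀(·+10⁻¹²) → min–max
normalization to integers in [0, 255] → bilinear resize to the square
classifier input (default 48).

Numerical choices, and why:

* **Window = sampling_rate/2** (2 Hz resolution at 256 Hz). A quarter-second
  window (4 Hz bins) cannot separate the ~3 Hz discharge fundamental and
  its harmonics from the neighbouring background bins; half a second is the
  shortest window that resolves them while keeping ≥ 5 frames in a 1 s
  segment.
* **0–64 Hz crop.** The clinically informative EEG bands sit below ~45 Hz,
  but TKEO's sin²(ω) weighting pushes energy upward, so the crop keeps a
  margin to 64 Hz. Without it, resizing the full 0–128 Hz axis into a
  48-pixel image allocates under 3 pixels to the entire 0–8 Hz range and
  the seizure comb is lost.
* **Flat-image guard**: if max = min after the log (e.g. an all-zero
  segment), the image is emitted as all zeros rather than dividing by zero.
* **TKEO placement**: the default pipeline transforms the TKEO series; a
  raw-signal spectrogram (`apply_tkeo=False`) is kept as an ablation
  switch.

## Chaotic permutation encryption

Two discretized chaotic maps act as pixel permutations of an N×N image:

* **Generalized baker map** with key (N, partition n₁…n_k, iterations):
  r′ = (N/nᵢ)(r − Nᵢ) + s mod (N/nᵢ), s′ = (nᵢ/N)(s − s mod (N/nᵢ)) + Nᵢ
  for r in the i-th vertical rectangle [Nᵢ, Nᵢ+nᵢ). Each nᵢ must divide N;
  this is enforced at key construction because it is exactly the condition
  under which the discretized map is a bijection of the grid (validated by
  brute-force enumeration for N ≤ 32 in the tests).
* **Arnold cat map** (x, y) → (x + y, x + 2y) mod N. On a finite grid the
  iterated map is periodic; `arnold_period(N)` brute-forces the period by
  iterating the full-grid permutation to identity (3 at N=2, 6 at N=8).

Conventions: 0-based (column r, row s) grid coordinates with the origin at
the bottom-left; image arrays are flipped to grid coordinates internally.
When both maps are requested the fixed composition order is baker first,
then Arnold. Keys serialize to JSON; there is no key-secrecy machinery —
this is a permutation cipher used as a pre-processing stage, and no
diffusion stage or security analysis (NPCR/UACI) is attempted. Encryption
conserves the pixel multiset exactly and decryption is the exact inverse
permutation, both asserted bit-exactly in the tests.

## Compact CNN and ensemble fusion

The classifier is built from the three layer operators — convolution
computed as cross-correlation (no kernel flipping), max pooling, and
elementwise activation (ReLU/sigmoid/tanh) — plus a fully connected
softmax head. The default architecture is two same-padded 3×3 conv blocks
(8 and 16 kernels) each followed by ReLU and 2×2 max pooling, then one
dense layer; with a 48×48 input this is ~45k parameters and trains in
seconds per fold on one CPU. The five large pretrained backbones (AlexNet
227, Darknet-19 256, GoogLeNet 224, ResNet-50 224, SqueezeNet 227) are an
optional transfer-learning hook: their native input sides are wired in,
but trained weights are never downloaded; without a local checkpoint the
hook falls back to the compact model (or raises, under `strict=True`).

Training: seeded minibatch SGD with classical momentum 0.9, learning rate
0.005, batch 32, cross-entropy loss, inputs scaled by 1/255 and then
standardized per image (zero mean, unit variance). Momentum and
standardization are load-bearing: without them the network fails to fit
even its training set on TKEO spectrograms (plain SGD stalls below the
accuracy of a linear baseline), and with a learning rate much above 0.01
training can collapse into a single-class fixed point. Backpropagation
uses im2col-style sliding windows and was verified against finite
differences.

Ensemble fusion is a weighted average of member probability vectors with
weights in [0, 1], divided by the weight sum (so weights need not sum to
one, matching the optimizer's box constraint), then renormalized. Members
in the default pipeline are two compact CNNs differing in width and
initialization seed.

## HSO (hybrid crow/sparrow swarm optimizer)

Population of m agents in a box (default [0,1]^d), minimization. Each
iteration, each agent takes one of two moves with probability ½ each
(the mixing rule was an open design point; a fair coin is the simplest
unbiased choice):

* **Corvid (crow-search)**: J ← J + λ·a·(Z_f − J), λ ~ U(0,1), flight
  length a (default 2), toward a random mate's memorized best Z_f; with
  probability 1 − Paw (default Paw = 0.85) the agent instead relocates
  uniformly in the box (awareness escape).
* **Gregarious (sparrow-search)**: an agent worse than the global best
  moves to J ← J′ + θ·(J − J′) with θ ~ U(0,1) and the velocity-augmented
  best J′ = J_best·(1 + v₁ω) + V; an agent at the global best is repelled
  from the global worst, J ← J + χ·|J − J_worst|/(j_e − j_ws + ε) with
  χ ~ U(−1,1) and ε = 10⁻¹² guarding the all-equal-fitness degenerate
  case. The shared velocity follows V ← ω·V + v₁·U(−1,1)^d, V₀ = 0
  (defaults ω = 0.7, v₁ = 0.05).

Candidates are clipped to the box. Position always moves to the (feasible)
candidate; an agent's memory is replaced only on *strict* fitness
improvement, so the global-best trace is monotonically non-increasing by
construction. Everything is driven by one seeded generator, making full
traces reproducible.

For fusion tuning the objective is 1 − fused validation accuracy; the
first k dimensions decode to member weights and any further dimensions
threshold at 0.5 into a feature mask. The initial population is seeded
with the k one-hot weight vectors, so the tuned fusion can never score
below the best single member on the validation set — recovering the
single-best-member solution is then a floor, not a hope.

On the 2-D sphere function (m = 20, 200 iterations) the median best
fitness over 20 seeds is ~10⁻⁹, and HSO beats a uniform random search with
the same evaluation budget in 20/20 seeds (both recomputed by the
acceptance script).

## Evaluation protocol

Stratified k-fold cross-validation (default k = 10, seeded shuffle;
per-fold class counts within one sample). Within each training fold, 20%
is split off (stratified) as an inner validation set for HSO fusion
tuning, so the test fold never influences the tuned weights. Metrics use
ictal as the positive class — one-vs-rest in 3-class runs — and are
reported per fold plus mean, median and sd across folds (labelled
explicitly, since "m ± sd" tables are ambiguous between mean and median
conventions). Undefined metrics (zero denominators) are reported as NaN
rather than silently zeroed. The Kruskal–Wallis H test (tie-corrected,
chi-square approximation, k − 1 df) compares per-fold metric values across
methods at α = 0.05 without multiple-testing correction — a documented
limitation, matching common usage. The degenerate all-identical case is
defined as H = 0, p = 1.

Default end-to-end conditions: 200 segments/class, 4 s windows, encrypted
images (baker partition (12, 24, 12) × 2 iterations, then Arnold × 3), two
CNN members, 20 epochs. One such run takes ~4–5 minutes on a single CPU
and reaches a mean ictal-vs-rest accuracy of ~92% across seeds; the
1 s and 2 s segment lengths run through the same path via
`PipelineConfig.segment_lengths_s`.

## Known limitations

* The synthetic classes are stationary and artifact-free; accuracy here is
  an upper bound on what the same pipeline would do on clinical data.
* The permutation cipher is not evaluated for cryptographic strength, and
  no pixel-value diffusion is implemented.
* The CNN is deliberately small and CPU-bound; no data augmentation,
  GPU path, or architecture search.
* The preictal horizon (how long before onset a window counts as
  preictal) is not modelled; preictal is defined purely by its spectral
  content.
* EDF output is classic EDF (not EDF+), 16-bit, one record per second,
  with per-channel physical ranges taken from the data; round-trip error
  is bounded by the 16-bit quantization step.
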