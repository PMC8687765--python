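# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limitations of the package, in the order of the
pipeline.

## Synthetic ECG generator

The generator produces what the classifier assumes about annotated
arrhythmia recordings: a continuous single-lead mV trace at a configurable
sampling rate (default 360 Hz), strictly increasing R-peak sample
indices, and one AAMI label per beat.

**Rhythm grammars.** Named rhythms are repeating label units — sinus
`(N)`, ventricular/atrial bigeminy `(N,V)`/`(N,S)`, ventricular/atrial
trigeminy `(N,N,V)`/`(N,N,S)`, ventricular/atrial tachycardia `(V)`/`(S)`
— truncated to the requested beat count; arbitrary custom units are
supported (the benchmark uses one for a tachycardia run ending in a
fusion beat, and one for paced rhythm).

**Beat morphology.** Each beat is a sum of Gaussian bumps for the P, Q,
R, S and T waves with class-specific centres, amplitudes and widths:
N has a P wave, narrow QRS and upright T; S shares the N QRS/T but has an
earlier, smaller P; V has no P, a wide QRS and inverted T; F is
parameter-wise intermediate between N and V; Q uses a pacing-spike-like
morphology (a stand-in — paced-beat morphology varies widely in
practice). Per-beat jitter (6% amplitude, 4% width, 4 ms centre sd)
prevents beats from being identical.

**Timing.** The base RR interval is `60/HR` seconds. Premature beat types
(S, V) arrive after 0.7× the base interval and are followed by a 1.3×
compensatory pause, so rhythm patterns carry genuine inter-beat timing
signal — prematurity is the defining clinical feature of ectopic beats.
Optional uniform rate jitter (default ±3%) perturbs every interval.

**Noise.** Additive: sinusoidal baseline wander (default 0.1 mV at
0.3 Hz), sinusoidal powerline interference (0.03 mV at 50 Hz), and white
Gaussian noise (0.05 mV sd) standing in for EMG. Beat morphology,
interval jitter and noise come from three independent child streams of
the record seed, so the identical record minus its noise is recoverable
exactly.

**The standard benchmark** (`make_benchmark`) cycles short records of all
the rhythms above with per-record heart rates drawn from 60–90 bpm, giving
class shares of roughly N 66%, V 13%, S 12%, Q 8%, F 0.6% — strongly
imbalanced, as in clinical Holter data, with F genuinely rare.

**What the generator does not emulate:** real morphological variability
within and across patients, lead placement effects, non-stationary noise
bursts, annotation errors, and the subtlety of real P-wave changes.
Passing tests therefore validate the pipeline's bookkeeping, equations,
optimisation and the qualitative behaviour of the method — not clinical
accuracy. The near-ceiling accuracies on the benchmark reflect its
separability.

## Wavelet denoising

Dyadic DWT with the Daubechies db6 wavelet (PyWavelets). Requested depth
8; the depth is clamped to `pywt.dwt_max_level` for short signals (an
error is raised only when the signal is shorter than the 12-tap filter).
Detail coefficients are soft-thresholded per level with the universal
threshold `σ √(2 ln n)`, `σ` estimated as MAD/0.6745 of that level's
coefficients (a hard-threshold variant is available); the deepest
approximation band — sub-Hz content at typical rates and depths — is
zeroed to remove baseline wander. Signal extension is symmetric to limit
edge artifacts; the reconstruction is trimmed to the input length.
A zero threshold (exactly zero coefficients) leaves the band untouched.

## Beats, segments, split

Beat windows are `round(0.25 fs)` samples before to `round(0.4 fs)` after
the annotated R peak, inclusive — 235 samples at 360 Hz with R at 0-based
index 90. Indexing is 0-based throughout; literature that counts from 1
will quote landmark positions one to three samples higher. Windows that
would cross a record boundary are dropped (padding would fabricate
morphology); drops are logged. Annotation symbols map to the five AAMI
classes by the standard table; non-beat symbols are excluded.

Segments are **non-overlapping** runs of `t` consecutive beats per
record, each beat keeping its own label (sequence labelling); a trailing
partial run is kept and flagged. Batches group segments of equal length,
so partial segments form their own small batches and no padding or loss
masking is ever needed — the loss is identical to masked padding without
the machinery. The train/test split is random at the **segment** level
(default 90/10, seed-deterministic); beat-level splitting would leak
segment context across the split.

## BiLSTM classifier

Pure NumPy, float64. Per direction the standard LSTM cell (input, forget,
output gates, candidate memory); the two directions are merged per
timestep by the weighted sum `H_t = W→ h→_t + W← h←_t + b` (the more
common concatenation merge is available via `combine_mode="concat"`).
A linear head and softmax give per-beat class probabilities; the loss is
mean per-beat categorical cross-entropy, optionally plus λ·L1, λ·L2, or
the tree penalty below.

Gradients are exact BPTT, tested against central finite differences at
1e-4 relative tolerance; optimisation is Adam (β₁ 0.9, β₂ 0.999).
Initialisation is uniform ±1/√fan-in with forget-gate biases at 1.
Defaults: hidden size 64, one layer, learning rate 1e-3, 30 epochs,
batch 64 segments, all exposed in `TrainConfig`. The scaled studies in
the tests use hidden 16, learning rate 3e-3 and 6–12 epochs (sizes chosen
as this package's benchmark conditions; they are stated with each study).

## Tree regularization

Every `distill_every` epochs (default 3):

1. the network's per-beat predictions are refreshed on a fixed subset of
   whole training segments (capped at `apl_sample_cap` beats, default
   5000, chosen once per run);
2. a CART tree (scikit-learn, `max_depth` 8, `min_samples_leaf` 20) is
   fit to **(beat samples, network predictions)** — ground truth never
   enters — and converted to an own array structure; fidelity (agreement
   with the network) and true APL are logged;
3. the surrogate dataset gains the checkpoint weight vector plus
   `n_perturbations` Gaussian perturbations (per-parameter sd = 0.1× the
   checkpoint's weight sd), each with its own distilled tree and true
   APL;
4. the surrogate MLP is refit on all pairs collected so far.

From the first fit onward the penalty `λ·Ω̃(W)` (default λ 10) joins the
loss; its gradient is the surrogate's analytic input gradient. APL counts
**internal decision nodes traversed** root→leaf (a single-leaf tree has
APL 0); counting edges would differ by a constant only.

**Surrogate.** One hidden layer of 25 tanh units, softplus output
(enforcing Ω̃ ≥ 0); inputs centred on the dataset mean and scaled by one
global sd. Trained full-batch with Adam on squared error plus ridge
`ε‖ξ‖²` over all surrogate parameters (ε default 1e-3); with ≥10 pairs a
20% holdout MSE is reported. The dataset-collection procedure
(trajectory checkpoints + perturbations) follows the original
tree-regularization recipe.

**Loop-order choices.** Distillation happens at epoch ends; the penalty
is inactive until the first surrogate exists (an implicit warm start).
The distillation/perturbation RNG stream is independent of the training
stream, so λ = 0 reproduces plain training bit-for-bit while still
measuring APL — the tests rely on this equivalence.

**Operating point.** The penalty only has a usable gradient while the
surrogate sees APL variation across weight space. If training converges
before the first distillation, checkpoints and their perturbations all
distil to near-identical trees, the surrogate fits a constant, and the
penalty exerts no pressure. The scaled tree-regularization study
therefore trains 6 epochs at batch 64 with distillation every 2 epochs,
where the penalty demonstrably simplifies the tree (median final APL 2.0
vs 6.3 without the penalty over five seeds on the 10,000-beat benchmark)
— at the cost of test accuracy at this strong λ, which is the expected
accuracy/simplicity trade-off of the penalty.

## Interpretability

Per-node class percentages normalise each node's class tallies by the
class totals (×100), so the root shows 100% per class and sibling
subtrees partition their parent's share; a class absent from the data is
NaN-marked. Feature ranking is normalised total Gini impurity decrease
per window sample point (ties break by ascending index; a split-count
mode exists because "importance" is not uniquely defined). The
reduced-feature experiment retrains the classifier on the top-k sample
points only and reports both evaluation reports; refitting on the reduced
inputs (rather than pruning the full tree) is the default reading.

## Evaluation

One-vs-rest TP/FP/TN/FN per class from the 5×5 confusion matrix
(rows = reference, columns = predicted, order N S V F Q); Se, Sp, +p and
per-class Acc as percentages; overall accuracy = trace/total.
Zero-denominator rates are NaN (undefined-marked) with a log warning and
are excluded from any averaging; percentages are rounded to 2 decimals
only in the reporting layer.

## File formats

WFDB-compatible single-signal format-16 records (`.hea`/`.dat`) and MIT
`.atr` annotations are read and written by an in-package codec (writer
and reader round-trip exactly up to the ADC step, default 1/1000 mV);
a plain CSV + JSON-sidecar fallback is provided. Datasets and model
checkpoints serialise to NumPy archives with JSON metadata.

## Known limitations

* The benchmark is nearly separable; absolute accuracies on it say
  nothing about MIT-BIH-scale performance.
* R peaks are taken from annotations; no peak detector is included.
* The split is intra-record (segment-level); inter-patient protocols are
  out of scope.
* Strong tree-penalty weights trade accuracy for tree simplicity; λ must
  be chosen per application (the sweep runner exposes it).
* Q-beat morphology is a synthetic stand-in, and the generator's S beats
  differ from N mainly by prematurity and a shifted P wave.
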