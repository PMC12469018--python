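# Methods

## Problem setting

The package analyzes subject-level ICA time courses from resting-state fMRI:
each subject is a matrix of T_total time points by C components (C = 53 in
the standard template), with a binary diagnostic label (0 = patient,
1 = healthy control) and a fixed assignment of each component to one of seven
functional networks (Subcortical, Auditory, Sensorimotor, Visual, Cognitive
Control, Default Mode, Cerebellar). The goal is twofold: classify patients
versus controls, and attribute the classifier's evidence back onto the seven
networks in an interpretable way.

## Time-reversal pretext task

Self-supervised pretraining doubles an unlabeled corpus by adding a
time-reversed copy X̃ = {x_T, …, x_1} of every subject series
X = {x_1, …, x_T} and trains the model to predict the direction label
(y = 0 original, y = 1 reversed) with binary cross-entropy

L = −E[ y·log f(X̃) + (1−y)·log f(X) ],

implemented as standard BCE over the augmented sample set, each sample
carrying its own label (the only reading consistent with a per-sample
direction classification). Predicted probabilities are clamped to
(1e−7, 1 − 1e−7) before the logarithm. Because folds are assigned by subject,
a subject's original and reversed copies always land on the same side of any
cross-validation split.

The task is informative only if the data are temporally asymmetric;
hemodynamic responses (fast rise, slow decay) provide exactly that asymmetry
in real BOLD-derived time courses, and the synthetic generator plants it
explicitly (below).

## Architecture

A hierarchical recurrent network with dual additive attention:

1. the series is cut into K = ⌊T_total/T⌋ contiguous windows of T = 20 time
   points (trailing remainder dropped — this preserves the 140 → 7 × 20
   arithmetic and avoids inventing imputation);
2. a unidirectional LSTM encoder (input C = 53, hidden D_enc = 256 at
   reference scale) processes each window independently;
3. window-level attention pools the T encoder states into one embedding per
   window: score_t = vᵀ tanh(W h_t + b), α = softmax over t, pooled =
   Σ α_t h_t;
4. a main unidirectional LSTM (hidden D_main = 200) runs over the K window
   embeddings, and a second (global) attention pools its states into the
   subject latent z ∈ R^200;
5. a linear decoder maps z to 2 logits. A 2-way softmax on the logit
   difference is equivalent to a sigmoid output in the binary case.

The attention scorer form is not determinable from the ancestor
architecture's description; additive scoring is the family default and
guarantees the probability-vector invariants (every attention row sums to 1)
that the attribution stage relies on. Both attention stages also record their
pre-softmax scores.

Since no GPU framework is assumed, the model and its training loop are built
on a small in-repo reverse-mode automatic-differentiation engine
(`neurolatent._autodiff`) over NumPy arrays: a tape of elementary operations
(matmul, gated nonlinearities, softmax pieces, reductions, slicing,
stacking) with float64 gradients and an Adam optimizer. The engine is
verified against central finite differences through the complete model graph.

## Training recipe

Adam with learning rate 7e−4, batch size 32, early stopping on validation
loss with patience 50 epochs and minimum delta 1e−4; the best-validation-loss
weights are restored. These are the package defaults (`TrainSpec`). An
improvement means undercutting the best seen loss by at least the delta;
training halts at the first epoch completing a full patience-length stretch
without one. Weight initialization is the standard uniform fan-in scheme,
seeded.

Pretraining runs five-fold cross-validation by subject: each fold trains on
4/5 of the corpus, early-stops on the held-out fifth, and yields one
checkpoint; transfer copies every weight except the decoder, which is
re-initialized for the diagnostic task (a scratch mode skips the copy — the
non-pretrained baseline arm). All layers fine-tune by default.

## Input standardization

Stored cohorts are kept raw; standardization happens when model inputs are
prepared. The default is cohort-level per-component z-scoring (mean/sd pooled
over subjects and time, fit on training subjects only). Per-subject
z-scoring is available but not the default: it erases each subject's own
amplitude, which removes precisely the between-subject amplitude differences
that constitute the clinically meaningful signal here; with it, desk-scale
training reduced to memorizing noise. The balancing stage always consumes
raw values, since its subject embedding is the time average that any
z-scoring would annihilate.

## Mahalanobis balancing

Severely imbalanced cohorts are balanced by embedding every subject as its
53-vector of time-averaged component activity, fitting the patient group's
mean μ and covariance Σ (with ridge λ = 1e−3 · trace(Σ)/C on the diagonal,
since patient counts can approach the dimensionality), and keeping the k
controls with the smallest distance √((x−μ)ᵀ Σ⁻¹ (x−μ)). Distance ties break
by subject id; patients always pass through; the combined cohort is
re-shuffled with a seed. Shipped presets keep 100 controls for the 433/66
imbalance profile and 261 for 651/172. Full covariance is the default; the
choice between full and diagonal covariance is genuinely open, and full +
ridge was preferred because the selection is then invariant under joint
rotations of the embedding space.

## Latent-feature statistics

Per latent dimension: a two-sided one-sample t-test against zero (is there
any signal?) and a two-sided two-sample Welch t-test between groups (is it
discriminative?). Welch rather than pooled-variance, because planted
amplitude effects (and real pathology) induce variance heterogeneity.
P-values are Benjamini–Hochberg adjusted (Benjamini–Yekutieli by flag) and
features with q < 0.05 are counted. Zero-variance columns are degenerate:
p = 1 when the column mean is 0, p = 0 for a constant nonzero column.
Exclusion of non-significant features from probing is available as an
optional mask but off by default, since the probe is specified over all
latent dimensions.

## Probing and attribution

A logistic-regression probe (L2, fixed C = 1 on z-scored latents — a fixed
default keeps grid cells comparable) is fit with internal stratified
five-fold cross-validation; coefficients are averaged over folds and the
probe AUC pools held-out decision scores. Probed latents come exclusively
from held-out subjects: `run_oof_cell` cross-fits the fine-tuning (two folds
at desk scale), so every subject's latent is produced by the model that did
not train on it, and the pooled matrix spans the whole cohort.

**Sign convention.** The probe's positive class is the patient group, so a
positive coefficient marks a pathology-associated feature. The network-level
consequence: a network whose activity is suppressed in patients receives a
negative importance score — its tracking features are weaker in patients,
hence carry negative patient-class coefficients and positive mapping
loadings — and an enhanced network a positive score. This is the convention
under which suppressed/enhanced planted signatures are recovered with the
expected sign end-to-end (verified in the acceptance suite); the opposite
coding is available via `positive_class="control"` and simply negates all
scores.

**Component-to-latent mapping.** The attribution matrix accumulates, over
windows k and time steps t,

M += (α_global[k] · W_main) @ (α_win[k,t] · W_enc),

where W_enc (D_enc × C) and W_main (D_main × D_enc) are single-matrix views
of the gated input-to-hidden weights. A gated cell has four input-weight
blocks; the default view takes the candidate-gate (cell-gate) block, the path
through which input activity actually enters the cell state, which preserves
the sign of a component's influence on the latent. The arithmetic mean over
the four blocks and the individual gates remain available
(`reduction=`); in controlled experiments the gate-mean view scrambled
attribution signs, which motivated the candidate-gate default.

Because every term of the double sum is the same product scaled by a scalar,
M = (Σ_k α_global[k] · Σ_t α_win[k,t]) · W_main @ W_enc — and when both
attention arrays are probability vectors (which the model guarantees) the
scalar is exactly 1, so M collapses to W_main @ W_enc and carries no
subject-level attention information. This algebraic fact is asserted
numerically in the tests. The `mapping="score"` variant substitutes the raw
pre-softmax attention scores, retaining attention dependence as a diagnostic;
the normalized variant remains the default.

Per-subject matrices are averaged element-wise over the probed subject set
(both classes); per-network importance is the mean over that network's
components of per_component[c] = Σ_f β[f]·M[f,c], with dispersion reported as
the sd of the per-network score recomputed from each probe fold's
coefficients (and across grid cells when aggregating). The exact formula
behind a "weighted mean coefficient" is a design choice of this package and
is declared in its reports. Cross-cohort consistency is the Pearson
correlation of two cohorts' seven-vectors of network scores.

## Synthetic data

Each component time course is a sparse event train (Bernoulli events at 8
per 100 time points, gamma(2,1) amplitudes) convolved with the
difference-of-exponentials kernel k(t) = e^(−t/τ_d) − e^(−t/τ_r)
(rise τ_r = 1, decay τ_d = 6 time steps), plus Gaussian noise (sd 0.5) — a
deliberate caricature of hemodynamic responses. Viewing the kernel as a
density, its moments are closed-form: mean τ_d + τ_r, variance τ_d² + τ_r²,
third central moment 2(τ_d³ + τ_r³) > 0, so the response is right-skewed and
time direction is statistically identifiable; the skewness of first
differences is already an above-chance direction classifier before any
training (the learnability oracle). A time-symmetric negative control corpus
(white noise under symmetric Gaussian smoothing — a stationary Gaussian
process, hence reversible in law) verifies that the pretext stays at chance
when no asymmetry exists.

Clinical cohorts plant disorder signatures in designated networks of the
patient group, applied to the pre-noise signal:

* `amplitude_factor` — multiplicative suppression/enhancement of response
  amplitude (e.g. 0.5 halves it: "reduced activity");
* `mean_shift` — additive offset;
* `decay_factor` and `asymmetry_factor` — disrupted-dynamics signatures that
  stretch the kernel's decay or interpolate it toward its time-reverse,
  energy-matched to the control kernel so signal variance carries no group
  information and only the temporal shape differs.

Generators are deterministic given their seed and draw each subject from a
counter-based substream, so subject i is identical regardless of cohort size.
Default desk-scale sizes: 200 subjects × 140 time points for the pretraining
corpus, clinical cohorts of 120–160 subjects.

What the generator does *not* emulate: spatial structure, scanner/site
effects, physiological confounds, age/sex covariates, autocorrelated noise,
eyes-open/closed protocol differences, or any biophysically calibrated BOLD
model. Passing tests therefore demonstrate that the pipeline's machinery
recovers planted statistical structure of these specific kinds — not that it
would recover clinical effects in real data.

## Desk-scale study conditions

The acceptance experiments train the full pipeline on one CPU in minutes by
reducing hidden sizes (D_enc = 32, D_main = 24, attention scorer 16) while
keeping the full 53-component input, the 20-point windows, and the training
recipe. Fine-tuning runs at most 60 epochs with patience 15; pretraining at
most 25 with patience 8. These are the package's chosen problem sizes for the
synthetic study; the reference-scale defaults (256/200, patience 50) remain
the constructor defaults.

## Findings the test suite documents

* Planted-signature recovery: with auditory amplitude suppressed in
  patients, the Auditory network receives the most negative importance score
  in ≥ 90% of seeded end-to-end runs; enhancement flips the sign.
* Pretraining benefit is signature-dependent. On temporal-dynamics
  signatures (asymmetry reduction), pretrained models classify better and
  yield more statistically significant latent features than scratch models —
  the pretext features align with the downstream signal. On pure amplitude
  signatures the pretext is uninformative by construction (both copies of a
  series have identical amplitude statistics), and transfer gives no
  advantage; scratch models learn such signatures directly and recover them
  across cohorts just as consistently. The cross-cohort consistency
  experiment's expectation that the scratch arm agrees *less* therefore
  holds only in regimes where the signature is hard for scratch models but
  readable through pretext-aligned features, a regime this synthetic
  setting cannot produce at desk scale; the corresponding assertion is left
  failing with this explanation rather than weakened.

## Numerical choices

* Probability clamp 1e−7 in the cross-entropy; softmax shifted by the row
  maximum (exact for softmax).
* Ridge λ = 1e−3·trace/C on patient covariances; Cholesky-based distances.
* Distance ties break lexically by subject id; fold assignment, shuffling
  and initialization are all seeded; stage seeds derive from one global seed
  by a fixed hash.
* Degenerate inputs: series shorter than one window, single-class folds,
  zero-variance latent columns and non-PD covariances raise structured
  errors rather than propagating NaNs; any non-finite value in a forward
  pass raises with the stage name.

## Known limitations

* The autodiff engine is minimal by design (no GPU, no mixed precision, 2-D
  matmul only); reference-scale training (256/200 hidden units on hundreds
  of subjects) is possible but slow on one CPU.
* Algorithm-level attribution inherits the collapse property above: with
  normalized attention, subject-level attention cannot differentiate M.
  Interpretation should rely on the probe-weighted network scores, not on M
  alone.
* The seven-network component assignment shipped as default is a stand-in
  with the conventional block sizes (5/2/9/9/17/7/4); any authoritative
  assignment should be supplied as a CSV and is honored everywhere.
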