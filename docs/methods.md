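# Methods

This note documents the statistical model behind `decodem`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Decoding model

The backward decoding model is linear discriminant analysis applied
independently at every time sample, with the channel vector at that single
sample as the feature vector (no temporal embedding). For classes *a*, *b*
with means μₐ, μᵦ and pooled within-class covariance
S = Σᵢ(xᵢ − μ_{c(i)})(xᵢ − μ_{c(i)})ᵀ / (n − k), the discriminant is

    w = Σ̂⁻¹ (μₐ − μᵦ),   b = −wᵀ(μₐ + μᵦ)/2,
    Σ̂ = (1 − λ) S + λ (tr S / p) I.

Sensor counts routinely exceed per-fold trial counts, so an unregularized
S is singular or ill-conditioned. λ is estimated analytically by the
Ledoit–Wolf formula on the class-centered training data (`shrinkage="auto"`,
the default); a fixed λ ∈ [0, 1] may be supplied, and a pseudo-inverse is
the last-resort fallback should the shrunk matrix still fail to factor.
Multi-class problems fit one discriminant per class pair. AUC is computed
from graded decision values (never hard labels): two-class AUC is the
Mann–Whitney rank probability with ties counted ½; multi-class AUC is the
unweighted Hand–Till mean of pairwise AUCs, so chance is 0.5 regardless of
class count. Hard-label metrics (balanced accuracy, d′, hit/false-alarm
rate) derive predictions from pairwise votes, margins breaking ties;
extreme hit/false-alarm rates are clipped to 1/(2N) before the inverse
normal so perfect performance yields a finite d′.

## Cross-validation and balancing

Trials are split by stratified k-fold (default k = 5, shuffled under the
analysis seed); per-fold metrics are averaged with equal weight. If k
exceeds the smallest class count the split degrades to leave-one-out.
When training and test data are independent (separate recordings, or
disjoint train/test event codes) no folds are formed and `nfolds` is
ignored.

Two balancing steps precede and accompany the fold loop:

* **Within-class event undersampling** (once, before folds): for each
  class, event code *c* with ratio weight r(c) retains m·r(c) trials,
  where m is the largest integer with m·r(c) ≤ count(c) for all codes —
  with unit ratios this cuts every event to the class minimum. Selection
  is uniform without replacement under a dedicated seed substream.
* **Between-class oversampling** (per training fold): every minority class
  is brought up to the majority count with synthetic trials
  x_i + u(x_nn − x_i), u ∼ U(0,1), interpolating a minority trial and one
  of its k = 5 nearest same-class neighbours. The per-trial budget is
  allocated proportionally to the fraction of other-class members among
  the trial's k nearest neighbours in the whole training set (ADASYN-style
  density weighting), falling back to a uniform split when no minority
  trial has other-class neighbours. Synthesis operates on whole trials
  (channel × time flattened, Euclidean metric) so one synthetic trial is
  usable at every time point — per-time-point synthesis would be
  O(n_times) more expensive and would let the synthetic set drift across
  the time loop. Boundary proximity is realized as neighbourhood density,
  not classifier margin, because margin weighting would require a trained
  classifier before training. Test folds keep natural counts (AUC is
  insensitive to imbalance) and ERPs are computed from the undersampled,
  never the oversampled, trials.

## Preprocessing

Applied in the order channel pool → resampling → baseline, so the baseline
is taken on the final time grid and filter edge effects cannot bias it.
Resampling is polyphase and anti-aliased (rational factor from the reduced
fraction of the rates), applied per trial with linear-extension padding so
the DC level of a constant trial is preserved exactly; upsampling is
refused. The baseline window is closed on both ends (start ≤ t ≤ end).
Muscle-artifact rejection is deliberately not implemented: no published
algorithm is specified for it, and guessing a filter silently would be
worse than refusing the config key.

## Activation patterns

Weight vectors of a backward model are transformed to activation patterns
by a = Σₓ w (Haufe transform), with Σₓ the empirical covariance of the
training-fold data (all classes pooled, grand-mean centered) at the
relevant time point, patterns then averaged over folds. Computing Σₓ
fold-locally keeps train/test separation intact; for two balanced classes
Σₓ = Σ_w + ¼δδᵀ, hence a ∝ δ, the class-mean difference. Correlation
(class-separability) maps use the correlation matrix instead; spatial
z-scoring normalizes a map to mean 0, sd 1 across channels.

## Group statistics

Per sample, a one-sample t-test compares the subject ensemble against the
metric's chance level (AUC 0.5, balanced accuracy 1/k, d′ 0) or, for
paired comparisons, the per-subject difference against 0. Zero-variance
degenerate samples yield t = 0, p = 1 at the reference and t = ±∞, p = 0
off it, without numerical failure.

Cluster-based permutation follows the max-statistic scheme: samples with
two-tailed p < 0.05 (per sign) form clusters under the data's adjacency —
a chain for time series, 4-connectivity for train × test matrices, or a
sensor graph for topographies (neighbours within 1.5× the median
nearest-neighbour distance, the conventional heuristic when no montage
adjacency is given). A cluster's mass is its summed t. The null collects,
per random per-subject sign flip of (value − reference), the maximal
cluster mass; for a two-sided test both tails are referred to the null of
the maximum over either sign, which keeps the family-wise error of the
whole two-sided procedure at α (testing each tail at α against its own
null would double it to ≈0.10 — the type-I simulations in the test suite
measure ≈0.04 for the implemented scheme). Positive and negative clusters
are reported separately in `pStruct`-style records with permutation p,
cluster size, data size, and start/stop/peak times, peak being the sample
of maximal |group mean − reference| within the cluster. When no null mass
reaches an observed cluster the p-value is reported as the bound
1/n_iter (`p_is_bound`), to be read as p < 1/n_iter; note that at small
cohort sizes (S ≲ 12) a random draw occasionally reproduces the identity
sign pattern (probability ≈ 2·n_iter/2^S), tying the observed mass, so
bounds are expected behaviour only for larger cohorts. FDR correction is
Benjamini–Yekutieli (valid under arbitrary dependency), delegated to
statsmodels and cross-checked in the tests against a hand-rolled step-up
oracle. Sampling k-fold metrics from a single task makes these tests
fixed-effects statements about the tested sample; prevalence-style random
effects inference is out of scope.

Dimension reduction of temporal generalization matrices (`diag`,
`avtrain`, `avtest`) applies train/test window limits before averaging,
so a 250–400 ms training window, say, is averaged only over rows inside
that window.

## Synthetic data

Each simulated trial is Σ components + noise: a component is a Gaussian
envelope (latency = center, width = FWHM) scaled by a per-event-code
amplitude and projected through a fixed channel topography. The Gaussian
envelope (rather than a raised cosine) was chosen so oracles can be
written analytically; note its support is unbounded, so at near-zero noise
even pre-stimulus samples become decodable — realistic noise levels (sd
≈ amplitude/2 and up) are what make "chance outside the window" hold.
Noise is 1/f^α-shaped (spectral shaping of white noise, α = 1 by default)
and spatially mixed by the Cholesky factor of a uniform-ρ (default 0.2)
channel correlation matrix, normalized to the requested sd. Cohorts jitter
component amplitudes multiplicatively (sd 0.2 by default) and latencies
additively per subject, with subject seeds spawned from the master seed.
Defaults emulate a repetition-design cookbook study: a 3 × 3 factorial
event table with first presentations twice as frequent as repeats, epochs
−500…1500 ms at 55 Hz (the analysis grid after downsampling), 32 channels
on a grid layout, 1 µV noise.

What the generator does **not** emulate: volume conduction from realistic
head geometry, non-stationary or non-Gaussian artifacts (blinks, muscle),
trial-order effects, and latency jitter within subject. Passing tests
therefore demonstrate the correctness of the estimation and inference
machinery under a known truth, not robustness to every property of real
recordings.

## Problem sizes in the test and acceptance runs

The simulations are sized for a single-CPU desk run: chance calibration
uses 200 trials × 16 channels × 100 time points; type-I error uses 500
null cohorts of 8 subjects × 60 samples at 1000 permutations each
(vectorized sign-flip t-maps with run-length cluster massing); parameter
recovery uses 12 subjects, 8 channels, 40 trials/class at 40 Hz. These
sizes give standard errors comfortably inside the asserted tolerances and
were fixed before the assertions were run.

## Numerical conventions

Time is milliseconds everywhere, t = 0 the stimulus-locked sample.
Performance arrays are indexed (train_time[, test_time]). All randomness
flows from one master seed per analysis through named `SeedSequence`
substreams (fold assignment, undersampling, per-fold oversampling), so
every sub-step is independently reproducible and different seeds change
selections but never counts. Permutation p-values live on the grid
k/n_iter. The `splinefreq` display smoothing (anchor grid phased through
the global-extremum sample, cubic spline through anchors) alters plots
only — statistics always use unaltered data.

## Known limitations

Non-linear classifiers, searchlights, time-frequency decompositions,
forward encoding models and prevalence statistics are out of scope.
The EEGLAB/Fieldtrip importers of the original MATLAB ecosystem are not
bundled; the neutral `.epochs` container (raw float32 + JSON sidecar) is
the interchange format, and trial order is taken as file order.
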