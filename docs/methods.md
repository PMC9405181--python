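# Methods

This note records the modelling choices, defaults and limitations behind the
pipeline. Notation: X is the n×d feature matrix after min-max scaling, y the
integer labels, D the number of candidate features, N the batch size, L the
number of canonical dimensions.

## Pre-processing

Min-max normalization maps each feature to (x − x_min)/(x_max − x_min) using
column extremes *fitted on the training fold only* and applied unchanged to
test folds, preventing leakage. Constant columns map to 0 (the map stays
total); out-of-range test values are deliberately not clipped, preserving
the transform's linearity. Raw UCI-style labels {1..5} (1 = ictal) are
remapped on read so that class 0 is the seizure class: binary 1→0, 2–5→1;
multi-class k→k−1.

## Coyote optimization and feature selection

COA is used as a bounded continuous optimizer. Packs of up to 14 coyotes
update greedily: a candidate position X + r₁(alpha − X_r1) + r₂(Y − X_r2)
(alpha = pack best, Y = componentwise median "cultural tendency") is adopted
only if its cost strictly decreases, which makes every per-coyote cost — and
hence the best-so-far trace — non-increasing. Candidates are clipped to the
bounds. Breeding follows the scatter/association probabilities
Prs = 1/D, Pra = (1 − Prs)/2, with two dimensions forced from each parent;
the pup replaces the worst pack member when strictly better. Two choices
were genuinely open and resolved as follows: the even-pack-size branch of
the cultural tendency is read as the ordinary componentwise median (mean of
the two middle ranked values), and there is no inter-pack exchange — the
pack count remains configurable so it could be added.

The wrapper binarizes positions in [0, 1]^D at 0.5. Fitness is
α·ΔR + (1 − α)·|Y|/|T| with α = 0.99, so error dominates and subset size
acts as a mild tie-breaker. ΔR defaults to the 3-fold cross-validated error
of a ridge classifier on the masked columns — a deliberately cheap, convex
surrogate, since evaluating the full deep model inside the wrapper loop
would multiply its cost by orders of magnitude; the estimator is a plain
callback and can be replaced. An empty mask is assigned the worst error
(1.0) without calling the estimator. With α = 0.99 the subset-size term
contributes at most 0.01, so the reported best cost is interpretable as
roughly the masked error rate.

## The DCSAE

Two sigmoid encoders f, g (defaults: 32→16 units on the feature view, 8 on
the second view) with mirrored decoders (ReLU hidden, linear output). The
second view defaults to the one-hot label matrix: maximizing canonical
correlation against labels yields a discriminative projection, which is
what makes the autoencoder a classifier; a "split" mode that halves the
feature vector is available for unsupervised two-view experiments.

The loss combines the negative canonical correlation, squared
reconstruction errors weighted by λ (default 1.0), and Bernoulli KL
sparsity penalties on the mean code activations (weights 0.1, targets 0.05
per side). Covariances use 1/N scaling with ridge terms r_x = r_y = 1e-4;
the correlation is the sum of the top-L singular values of
Σ₁₁^(−1/2) Σ₁₂ Σ₂₂^(−1/2), and its gradient with respect to the encoder
outputs is the closed-form deep-CCA expression (verified against finite
differences at 1e-6 tolerance in the tests). Eigenvalues are clamped at
1e-12 before inverse square roots; code activations are clamped to
[1e-6, 1 − 1e-6] before logarithms. L defaults to min(10, 2·classes),
capped by the code widths.

Training is plain full-batch gradient descent at learning rate 0.01 for 50
epochs with inverted dropout 0.5 on hidden (non-code) layers — the
reference protocol's settings. Full batch is used for every term because
small-batch covariance estimates of the CCA term are rank-deficient below
roughly 10·L samples; at the package's problem sizes (hundreds to a few
thousand rows) a full-batch epoch is a handful of small matrix products, so
minibatching buys nothing. The `batch_size` field is retained in the config
for forward compatibility but the current trainer ignores it. Sigmoid is
used on sparse code layers (the KL penalty needs activations in (0, 1));
ReLU appears in the decoders. A `linear` activation mode removes all
nonlinearities, under which training provably can do no better than
classical CCA — the acceptance suite checks it gets there within 0.02 and
within 5° of principal angle at n = 500.

Prediction projects Uᵀf(x) and assigns the nearest class centroid
(Euclidean); ties break toward the lower class index. Negated distances
serve as per-class scores for ROC analysis.

## Krill herd tuning

The herd's velocity sums three fields. Induced motion:
N_max·(α_local + α_target) + ω_n·N_old with N_max = 0.01, ω_n linear
0.9→0.1, α_target scaled by C_best = 2(rand + I/I_max), and α_local summed
over neighbours within the sensing distance (one fifth of the mean pairwise
distance), fitness differences normalized by the worst–best spread with
ε = 1e-10 denominators. Foraging: V_f·(β_food + β_best) + ω_f·F_old with
V_f = 0.02, the food position the 1/K fitness-weighted centroid, and
C_food = 2(1 − I/I_max). Diffusion: D_max·(1 − I/I_max)·U[−1, 1]^D with
D_max = 0.005, exactly zero at the last iteration. Positions update by
Δt = C_t·Σ(ub − lb), C_t = 0.5, clipped to bounds; only the named induced
and foraging constants were stated by the method's sources, so the
remaining internals follow the standard krill-herd formulation and every
constant is exposed in `KhaConfig`. No genetic operators are included.

Tuning decodes each krill from the unit cube to a `DcsaeConfig` (log scales
for learning rate and loss weights, linear for sparsity targets, half-up
rounding for integer widths), trains for a short 10-epoch inner budget, and
scores the percentage error on a held-out quarter of the data; a diverging
configuration scores the worst fitness (100) and the search continues. The
winning configuration should be retrained at the full epoch budget, which
the pipeline does.

## Metrics and cross-validation

Per-class metrics are one-vs-rest; summaries are unweighted macro means
(the convention chosen for multi-class tables here). Zero-denominator
ratios return 0 and are flagged in the report rather than raising. MCC is
reported per class one-vs-rest and macro-averaged, not as the single
multi-category coefficient. ROC curves come from a threshold sweep with
trapezoidal AUC; the tests pin the AUC to the Mann–Whitney U statistic and
MCC to the Pearson correlation of the binarized vectors. Cross-validation
is stratified with a fixed seed, and normalization plus feature selection
are refitted inside every training fold; the pooled report is computed from
the summed confusion matrix.

## Synthetic data

The generator emulates the UCI table's layout (178 columns by default,
2–5 balanced classes; an imbalance option reproduces the 1:4 binary ratio).
`iid-gaussian` mode plants a mean shift of c·separation·noise_sd on the
informative columns of class c; `sinusoid-segment` mode adds a
class-specific-frequency sine sampled at n_features points, mimicking
1-second segments. Defaults used across the benchmarks: 300 rows per class,
30 features with 5 informative, separation 3 noise-SD units — well
separated but not degenerate, so selection and classification both have
work to do. What the generator does **not** emulate: 1/f spectra,
spike-wave morphology, channel correlations, artefacts, or the label noise
of real EEG. Passing benchmarks on it therefore demonstrate the pipeline's
mechanics and internal consistency, not clinical performance.

## Problem sizes and numerical choices

The test and acceptance benchmarks run at desk scale — 600-row tables, 30
features, 2 packs × 5 coyotes × 15 iterations for selection, 200-iteration
COA and 100-iteration KHA sphere checks — sizes at which every property
being asserted is already exercised and the whole suite completes in about
a minute. Determinism is end-to-end: every stage consumes an explicit seed
and a rerun of a pipeline config is bit-identical (wall-clock timings are
quarantined in `manifest.json`).

## Known limitations

- The optimizers are reference implementations tuned for clarity, not
  large-D performance; the wrapper's mask cache assumes a deterministic
  error estimator.
- Nearest-centroid decision in canonical space is linear per class pair;
  strongly non-convex class regions would need more canonical dimensions
  or a different read-out.
- The label-view construction makes canonical correlation supervised; with
  k classes only k − 1 informative canonical directions exist, and the
  remaining whitened dimensions carry noise that mildly dilutes distances.
- Published accuracy figures for seizure classification on the real UCI
  table depend on that dataset and unreported training details; this
  package's benchmarks are the synthetic ones above.
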