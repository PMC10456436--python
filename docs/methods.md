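# Methods

## The problem and the model

Untargeted GC–MS intensities drift with injection order and jump at batch
boundaries: instrument state, derivatization completeness and splitless
injection behaviour bias most compounds of an injection *together*. Pooled
QC samples — aliquots of one homogenized pool injected at regular intervals
— measure exactly this technical component, because their true composition
is constant.

SERDA treats normalization as sample-wise denoising. On an additive scale,
a QC profile is `x = c + e`, a constant compound vector plus systematic
error. A denoising autoencoder

    Φ(x) = s(W′ s(W x + b) + b′),   s = elu (elementwise),

trained to reconstruct clean QC profiles from corrupted ones, learns the
low-dimensional manifold the QC profiles live on. Applied to any sample,
`Φ(x)` estimates the systematic part of that profile; the correction

    x′ = x − (Φ(x) − mean_samples Φ(x))

subtracts each sample's deviation of the reconstruction from the target-set
mean. Because the subtracted term is mean-centered per compound, per-compound
target means on the scaled space are preserved to machine precision —
normalization never relocates a compound, it only shrinks its technical
variance.

Both the encoder and the decoder output pass through the elu nonlinearity,
as the forward map above states. elu is bounded below by −1, so
reconstructions of auto-scaled values far in the lower tail saturate; in
practice the MAE loss places the fit where the data mass is and the
correction degrades gracefully in that tail.

## Pipeline and numerical choices

1. **glog transform**, `g(x) = log2((x + sqrt(x² + λ²))/2)`. Default
   `λ = 0` (plain log2); curated GC–MS matrices are complete and positive.
   Exact zeros under `λ = 0` are lifted to a one-ion-count floor
   (`zero_offset = 1`) so the transform stays finite; any `λ > 0` handles
   zeros exactly and is exposed for sparser data.
2. **Corruption scale** per compound: `σ_j = max(sd(x2_j) − sd(x1_j), 0)`,
   sd on the glog scale with the n−1 denominator (x1 = training QCs,
   x2 = targets). The subtraction is read on the sd scale, literally; the
   clamp covers compounds where QCs already vary more than targets. The
   corruption makes the training inputs resemble target profiles (which
   carry biological variance on top of drift) and regularizes the fit.
3. **Oversampling** (default n = 0): n extra copies of the QC set, each
   with fresh Gaussian noise. Dropout is *input* corruption applied freshly
   each epoch — exactly `⌊ν·d⌋` compounds per row (without replacement) are
   zeroed; it is never applied at prediction time.
4. **Auto-scaling** per compound to mean 0 / sd 1. The statistics are fit
   on the concatenation of training and target rows so one affine map
   applies to both (fit-on-training-only is a switch). Constant compounds
   get an sd floor of 1e−8 and scale to zeros.
5. **Training.** Glorot-uniform weights (limit `sqrt(6/(d+d′))`), zero
   biases. Loss = mean absolute error against the *clean* profiles.
   Mini-batch Adam (lr 1e−3, β₁ 0.9, β₂ 0.999, ε 1e−8 — conventional
   settings), one full pass over shuffled mini-batches per epoch. Phase A
   holds out a random 20% of QC rows and stops when held-out MAE has not
   improved (strictly) for `patience = 50` epochs, capped at 2000; `n_e` is
   the epoch of the best held-out MAE, not the last. Phase B reinitializes
   and trains `n_e` epochs on all rows. One master seed fans out to
   independent streams for corruption, the split, initialization and
   batching, so the whole pipeline is a pure function of (table,
   hyperparameters, seed).
6. **Correction, batch medians, inverse transforms** as above; optional
   per-batch median equalization on the scaled space subtracts each batch's
   per-compound median and restores the global median (off by default,
   since it breaks exact mean preservation).

Default hyperparameters: `d′ = 32`, `ν = 0.1`, `n = 0`, `b = 16`
(mini-batch), elu. Held-out precision is flat across sensible grids —
`tune_hyperparameters` runs the k-fold CV selection (folds interleaved over
injection order so every fold spans the acquisition; ties break to smaller
d′, then smaller n), but the defaults are adequate for routine use. The
command-line default adapts the mini-batch size to `min(16, n_QC/2)` so
thin QC sets still train.

## Comparator methods

* **Sum norms**: divide each sample by its summed intensity over the mode's
  compound set; mTIC sums identified metabolites excluding spiked standards
  (ISTDs, FAMEs), which are not endogenous signal. Divided values are
  rescaled by the median of the divisors (median-of-sums / median-of-ISTD)
  so outputs stay intensity-like; RSD is scale-invariant, so evaluation is
  unaffected by the rescale.
* **Batchwise LOESS**: per compound and batch, a locally linear (degree 1)
  smooth of QC intensity vs injection order (`span = 0.75`, no robustness
  iterations, deterministic), evaluated at QC points and carried to other
  injections by linear interpolation, linearly extrapolated at batch edges;
  correction is `raw · median(QC) / max(fitted, ε)`. Batches with fewer
  than 4 QCs fall back to a flat median correction (logged). Degree-2 local
  fits are not offered.
* **SERRF-style random forest**: per compound, the `top_k = 10` most
  |correlated| compounds over the training QCs (log2 scale) feed a random
  forest (default 500 trees; 100 in the test/acceptance runs as a
  problem-size scaling) regressing the compound's QC values; the predicted
  level at every sample gives the same ratio correction. These are
  reasonable baseline settings, not a bit-compatible reimplementation of
  the published SERRF tool.

## Evaluation protocol

Per-compound RSD = 100·sd/mean (n−1), computed over a group of identical
QC injections; compounds with zero mean are reported missing and excluded
from summaries with a logged count. The headline protocol is **k-fold
cross-validated RSD**: training QCs are split into interleaved
injection-order folds; each fold is corrected by a model trained on the
others; held-out corrected values are pooled before computing RSDs. Methods
that need no training (sum norms, raw) are applied directly — CV is vacuous
for them. **External validation** scores an independent QC material that
never trains. Coverage at a threshold uses strict inequality (RSD < 30%).
The paired method comparison is a two-sided Wilcoxon signed-rank on
per-compound RSDs, exact for ≤ 25 informative pairs, normal approximation
above, `p = 1` when all differences vanish.

## The simulator

`simulate_study` emulates the acquisition design this class of methods
assumes: ~960 injections in 7 batches (800 study samples, a pool QC and a
validation QC every 10), blinded duplicate pairs, and log2-scale signal

    log2 x_ij = μ_j + Σ_l Λ_jl f_l(t_i) + β_{j,b(i)} + u_i + bio_ij + ε_ij

with smooth factor paths `f_l` (smoothed random walks, window 15
injections, plus a jump at every batch boundary), loadings `Λ`, compound ×
batch offsets `β`, a per-injection scalar `u_i` shared by all compounds
(injection/derivatization variability — random in time), study-sample
biology `bio` (iid; validation QCs instead carry one fixed compositional
shift; pool QCs none), and cell noise `ε`. Ten percent of compounds are
drift-immune (loadings ×0.05) so the correlation structure is
heterogeneous. Default scales (`drift 0.95`, `batch 0.45`, `sample effect
0.10`, `noise 0.12`, `bio 0.25` log2) were calibrated once so the raw
pool-QC median RSD lands in the 50–60% range typical of uncorrected
long-run GC–MS acquisitions.

Two named variants support the method comparison: `correlated_drift_config`
(12 factors, noise 0.18, sample effect 0.3 — heterogeneous correlation plus
strong time-random error, the regime that motivates sample-wise profile
correction) and `uncorrelated_smooth_drift_config` (60 factors, no shared
sample effect — the regime where a time smoother shines).

What the simulator does **not** emulate: missing values and detector
saturation, heteroscedastic (intensity-dependent) noise, retention-index
misalignment, co-elution artifacts, derivatization product ratio shifts
between specific compound pairs, and real biological covariance between
compounds. Passing recovery tests therefore demonstrates that the
implementation removes the kinds of structure it models — lognormal
factor drift, batch jumps, injection-level scalar error — not that any
particular real study will reach the same precision.

## Problem sizes in the test and acceptance runs

The default acquisition (200 compounds, ~960 injections) is used for
recovery, interval and replicate checks; the method comparison uses the
correlated-drift acquisition at 150 compounds; unit tests use tables of a
few dozen rows. These sizes keep the full suite in the low minutes on one
CPU while leaving every protocol at realistic QC counts.

## Known limitations

* The elu output layer bounds reconstructions below by −1 on the scaled
  space (see above).
* σ from `sd(x2) − sd(x1)` conflates biological with technical excess
  variance when targets are biologically diverse; that is inherent to the
  corruption heuristic.
* SERRF and LOESS here are faithful *styles* of their namesakes, intended
  as comparators, not replacements for the published tools.
* With very few QCs (interval 80 leaves ~11) the 80/20 early-stopping split
  becomes coarse; precision degrades smoothly but selection noise grows.
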