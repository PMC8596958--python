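# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

**Band-pass + spectral-truncation decimation.** Each region's series is
taken to the frequency domain with a real FFT over the session duration
`dur`; bins with frequency k/dur outside [f_low, f_high] are zeroed (the DC
bin unconditionally), the spectrum is truncated at k_max = floor(f_high·dur)
and inverted onto T′ = 2·k_max + 1 samples, rescaled so in-band sinusoids
keep their amplitude on the new grid. This is lossless inside the band,
removes the long-range autocorrelation a band-pass filter would otherwise
induce, and fixes the arithmetic 1,200 → 155 samples (virtual TR 5.57 s)
for the standard 864-s session. Defaults: f_low = 0.008 Hz, f_high =
0.09 Hz — the slow-fluctuation band in which hemodynamic signal power is
expected.

The precondition on f_high is that the truncation bin be representable,
k_max ≤ (T−1)//2, rather than f_high ≤ Nyquist: the decimated 155-point
grid has Nyquist 0.0897 Hz < 0.09 Hz, yet re-applying the same band on that
grid is well defined (and is the identity), which the looser literal
precondition would wrongly reject. The sub-band and supra-band bins are
zeroed in a single mask; doing the high-pass before or within decimation is
indistinguishable in the result.

**Standardization.** Per region, mean 0 and unit variance with divisor T−1,
matching the divisor used for saliency temporal variance and for the
correlation normalizer in δC. Standardization is applied per session after
decimation and is treated as part of the differentiable model.

**Confound decorrelation.** The trait is residualized on confounds plus
intercept by OLS; the residual is centered and scaled to unit variance. All
statistics — coefficients, center, scale — come from the training fold and
are applied frozen to validation subjects, so no validation information
reaches training. Degenerate cases (rank-deficient design, zero residual
variance) raise.

## Architecture and training

Two additive BiLSTM stages and an affine head. Each direction-LSTM has a
combined input+recurrent weight matrix (4h × (d+h)), a single gate-bias
vector (4h) and learnable initial hidden/cell states (2h). These
conventions are not optional: they are the only accounting that reproduces
the published parameter counts (632,320 / 525,824 / 257 / 2,316,545 at
d = 360, h = 256), and the test suite pins all four. Gate order internally
is [input, forget, output | candidate]; biases and initial states start at
zero, weights Glorot-uniform.

Training minimizes per-session MSE against the subject's adjusted trait
with Adam plus decoupled weight decay (applied to weight matrices only; the
paper-scale defaults are 50 epochs, learning rate 5e-4, decay 5e-4, crop up
to 20 timesteps). Sessions are separate samples; each batch independently
crops a uniform number of timesteps (0..max_crop) from each end. Ensemble
members differ in initialization **and** in their per-epoch shuffles —
during development we measured that members sharing one shuffle produce
error-correlated ensembles with no variance-reduction benefit; independent
shuffles restore the expected gain (asserted as a stochastic property in
the suite). Crop draws are shared across members so all members of a fold
advance in one batched tensor computation.

Everything is NumPy. The forward recurrence is transcendental-bound and
runs through vectorized ufuncs; the backward recurrence is multiply-bound
and uses a numba kernel when available (bit-compatible with the NumPy
reference loop, which is the fallback and the tested ground truth). All
parameter and input gradients are analytic reverse-mode and are checked
against central finite differences.

## Cross-validation

Families are stratified into terciles of family-averaged trait × family
size group {1, 2, 3+} (nine strata), shuffled within strata with a seeded
generator and dealt round-robin into k = 10 folds with a deal pointer
carried across strata so fold sizes stay balanced. Tercile edges are
whole-cohort quantiles; ties go to the lower tercile. Families are never
split. The recombination rule across strata is under-determined in the
source design; round-robin with a carried pointer is this package's choice
(deterministic, order-free, balanced).

Metrics: MSE; R² = 1 − MSE/Var(y) with population variance so a constant
mean prediction scores exactly 0; ρ² = squared Pearson correlation. Across
folds we report mean and standard error (SD with divisor k−1 over √k).

## Elastic-net connectivity baseline

Features are session-averaged Pearson correlations (upper triangle,
row-major i<j; R(R−1)/2 features). On each training fold a univariate
two-sided correlation test (default p < 0.01; configurable — the source
design defers the exact filter) selects features; an elastic net with
l1_ratio = 0.05 is fitted over a 50-point penalty grid, log-spaced four
decades down from λ_max, with the penalty chosen by inner 3-fold CV.
The univariate filter is re-fit inside each inner split: filtering once on
the full training fold leaks the filter's spurious selections into the
inner score, which measurably biases the inner CV toward light penalties
and produces systematically negative holdout R² on null data. With the
nested filter the null behaviour is correct (holdout |R²| < 0.1), which the
suite asserts. Ties in inner MSE go to the heavier penalty.

## Ablation and the size-matched null

Ablation zero-fills selected standardized columns on validation data (zero
is the post-standardization mean — information removal with minimal
distribution shift; noise injection and re-standardization were considered
and rejected as they perturb the untouched regions). Degradation is
summarized by the paired-T statistic over per-fold (baseline − ablated)
metric differences, df = k−1, positive toward degradation; zero-difference
and zero-variance edge cases are flagged (t = 0, or a capped ±1e6).

Because larger sets remove more information regardless of content, an
observed statistic is referred to a null of statistics from ablating
uniformly random same-size sets (default 300 iterations). Empirical
p-values are one-sided in the degradation direction with the +1 correction
p = (1 + #{t_null ≥ t_obs})/(n_iter + 1). FDR correction over the sets
tested in one analysis defaults to Benjamini–Yekutieli, with
Benjamini–Hochberg available — the source design names both in different
places, so both are first-class and neither is guessed as intended.

**Null calibration.** The suite verifies that on a model trained against
pure-noise targets, the empirical p of a random observed set is uniform
(KS at 1%, 200 draws). Each draw gets its *own* freshly resampled
50-iteration null: a single shared null pool would shift every p-value
coherently by the pool's sampling error (~1/√50), so the KS check would
measure the pool, not the calibration. With fresh pools the p-values are
exactly discrete-uniform under the null. To make 10,200 ablation
evaluations affordable, the calibration cohort uses singleton families and
one session, so all folds' ensembles evaluate their validation subjects in
a single stacked forward pass.

## Saliency machinery

`input_saliency` returns the exact gradient of a session's scalar output
with respect to the pre-standardization series; the chain rule through
per-column standardization is (G − mean(G) − z·⟨G,z⟩/(T−1))/sd, which
enforces the structural invariants (zero temporal sum, orthogonality to the
standardized data) to machine precision. Ensemble saliency is the mean of
member saliencies, computed member-wise. The temporal band-pass is held
fixed (not differentiated through) by default: it is linear and its
gradient commutes with it, so for in-band inputs the result is identical
and the computation cheaper.

**Saliency-defined networks.** For each distinct resting-state-network size
M in the partition (duplicates collapse), the top-M regions by mean
saliency temporal variance over the *training* fold; selection on training
saliencies and ablation on validation data avoids circularity. Sets are
nested by construction; ties break by region order.

**δC propagation.** The η-free direction (DᵀX + XᵀD)/(T−1). One divisor
(T−1) is used everywhere a correlation-style normalizer appears — the
source notation is inconsistent between M and n−k, and unifying removes a
silent scale mismatch between the saliency variance, C, and δC. Across
sessions/subjects the mean and SD per pair are aggregated; the top 5% of
|mean/SD| pairs are categorized by sign(mean C) × sign(mean δC) into
IMPC/DMPC/DMNC/IMNC (increase/decrease of magnitude for positive/negative
correlations).

**ZCA saliency.** Thin SVD X = U diag(s) Vᵀ with a deterministic sign
convention (largest-magnitude entry of each V column positive); Z = UVᵀ,
W = V diag(s) Vᵀ. The directional derivative of Z along D is computed via
the matrix-square-root differential: with A = (XᵀX)^{1/2}, dA solves
dA·A + A·dA = DᵀX + XᵀD, diagonal in the V basis with denominators
sᵢ + sⱼ, and dZ = D A⁻¹ − Z dA A⁻¹. This form never divides by singular
value *gaps*, so it is well posed whenever X has full column rank;
nevertheless, a nearly-degenerate spectrum (gap < 1e-8·s_max) triggers a
warning and a central-finite-difference fallback, and the analytic path is
itself validated against finite differences in the suite. We do not assert
the folklore identity between ZCA columns and all-other-region regression
residuals: that identity belongs to precision-matrix whitening (X·C⁻¹),
not to C^{−1/2} whitening.

## Synthetic cohorts

The generator is a Gaussian AR(1) process with trait-modulated innovation
covariance — the simplest process in which both functional connectivity and
innovation variance carry trait signal, matching the structure the δC and
ZCA analyses assume (the real generative structure of resting-state data is
unknown; this choice is the package's own and passing tests speak to the
pipeline, not to biology). Per subject, Σ(g) = Σ0 + g·effect_scale·Δ:

* Σ0 — unit diagonal, within-network correlation 0.3 (`baseline_within`),
  zero between networks;
* Δ — salient regions are paired across networks (coupling 1 per pair) and
  carry an innovation-variance modulation on the diagonal
  (`variance_effect` = 0.25). Pairing across networks keeps the planted
  coupling on a zero baseline and Σ(g) well conditioned over the realistic
  trait range; effect_scale defaults to 0.2, under which PSD repair
  (eigenvalue clipping at 1e-8, with a warning naming the subject) fires
  only for |g| in the far tail. Nonzero rows of Δ are exactly the salient
  regions, so ground-truth recovery is well defined.
* The series is the AR(1) filter (lag-1 coefficient 0.4) of innovations
  drawn from Σ(g), started from the stationary distribution; the AR filter
  is common to all regions, so it does not distort spatial correlations.

Trait g is standard normal with a family-shared component (heritability
weight 0.5, making family stratification consequential); family sizes
follow the composition of the study population this emulates
(28% / 38% / 34% for sizes 1 / 2 / 3+, with "3+" realized as 3 or 4);
confounds are c_j = w·g + √(1−w²)·ε with w² = r²/(k(1−r²)+r²) so the
population R² of g on the k confounds equals `confound_r2` (default 0.138,
the shared variance reported for the real confound set). All randomness
descends from one master seed through named substreams
(cohort / ground truth / subject-session), so cohorts regenerate
byte-identically.

What the generator does **not** emulate: hemodynamics, motion and
physiological artifacts, spatial geometry, non-Gaussian or non-stationary
dynamics, and any timeseries feature of the trait beyond second-order
structure. Consequently the tests demonstrate that the pipeline recovers
effects of the kind it assumes — not that such effects exist in real data.

## Desk-scale study conditions

Full-scale defaults (360 regions, 1,200 timepoints, 4 sessions, 256 hidden
units, 50 members, 50 epochs) reflect the design this package re-implements
and are impractical for routine runs. The desk-scale study
(`restsal.desk_study`) uses: 300 subjects, 60 regions, 400 timepoints
(→ 51 after decimation), 2 sessions, 12 salient regions; a 12-hidden-unit
architecture, 5 members, 12 epochs, learning rate 3e-3, batch 64, crop 5
(scaled from 20 in proportion to the shorter sequences), float32. The
desk partition has six networks of sizes 3/5/8/10/14/20, mirroring the
heterogeneity of real resting-state networks and exercising the
duplicate-size collapse. These sizes were chosen a priori as the package's
scaled-down study conditions; the acceptance-style tests then assert
planted-signal recovery (cross-validated R² > 0.3, salient-region AUC >
0.8) and that saliency-defined sets out-degrade size-matched random sets in
≥ 8 of 10 replicate cohorts.

One desk-scale caveat is recorded as a design choice: with 12 planted
regions in a size-14 set, ablating the saliency-defined network removes
most of the model's signal, producing a *large* R² drop whose size varies
across folds, while random sets produce small but highly *consistent*
drops. The paired-T statistic therefore saturates and can rank a random set
above the saliency set even when the latter degrades performance by 4× more.
The replicate comparison consequently uses the cross-fold mean R²
degradation — the quantity of scientific interest — while paired-T values
are still computed and reported for each set.

## Known limitations

* The LSTM is trained at desk scale in float32; gradient oracles run in
  float64. Bit-level reproducibility holds for a fixed seed and BLAS.
* `calibration_pvalues` requires a balanced design (equal validation counts
  and session counts); general cohorts use the slower `resample_null` path.
* The elastic-net λ grid spans four fixed decades below λ_max; pathological
  feature scales could need a wider grid.
* Family stratification assumes family sizes 1/2/3+; larger pedigree
  structure is collapsed into "3+".
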