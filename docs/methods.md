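# Methods

`spoilfuse` implements a multi-sensor chemometric pipeline for predicting
bacterial total viable counts (TVC, log CFU/g) in fresh meat from FTIR
spectra and multispectral imaging features, and for asking whether combining
sensors ("data fusion") beats the best single sensor. This note documents the
models, the synthetic-data generator that stands in for unreleased raw
spectra, the numerical choices, and what the results do and do not show.

## The regression model

All models are one-response partial least squares (PLS1) regressions fit with
NIPALS. PLS is the standard choice for spectroscopic matrices, which are
strongly collinear and often have far more features than observations. The
implementation centres X and y but applies **no per-feature variance
scaling**: spectra are already row-normalised by SNV, and z-scoring is
applied explicitly exactly where the fusion design calls for it (early
fusion). This choice changes numbers relative to an auto-scaled PLS and is
therefore validated by a property suite (full-LV PLS equals ordinary least
squares on full-rank problems; agreement with scikit-learn's
`PLSRegression(scale=False)` to 1e-6 relative) rather than against any
published table.

PLS1 needs no iterative inner loop (each weight vector is the closed form
`w = X'y / ||X'y||`), so fits are deterministic. If the residual covariance
collapses (`||X'y||` below 1e-12 of its initial value) the component sequence
is truncated with a warning rather than an error. NIPALS components are
nested, so the model retains a *coefficient path* — the coefficients of every
truncated model with `k <= n_lv` components. Hyperparameter searches over LV
counts evaluate the entire range from one decomposition per fold, which makes
exhaustive grids cheap.

## Preprocessing

Default per-modality recipe, applied to each train/test partition's rows
separately:

* **FTIR**: SNV → Savitzky–Golay (window 11, polynomial order 1) →
  restriction to the 2000–900 cm⁻¹ "spoilage fingerprint" region (1141
  features on the default grid). Restriction comes last so smoothing edge
  effects fall outside the retained window.
* **MSI / MSIF**: SNV only, applied across each row's 36 / 16
  mean-and-sd-per-band features.

SNV uses the n−1 denominator, making it exactly idempotent and exactly
invariant to per-row affine artifacts (`snv(a·x + b) = snv(x)`, a > 0).
Savitzky–Golay edge handling fits the edge polynomial to the outermost window
(scipy `mode="interp"`), the only mode that reproduces linear signals exactly
at the edges; with polynomial order 1 the filter is a pure smoother (no
derivative). SNV and SavGol are row statistics with no fitted state, so
applying them per partition cannot leak information; the z-score
standardiser used by early fusion is the only fitted transform and is always
fit on training rows only. SNV is applied to FTIR for both meat types — one
recipe everywhere, configurable per modality.

## Fusion architectures

Modality order is fixed as (MSI, FTIR, MSIF) so column layouts and fitted
models are reproducible regardless of how blocks are supplied.

* **Early**: each block z-scored with train statistics, concatenated, one PLS
  with `n_lv` tuned (2–20 by default).
* **Mid / feature**: per-modality PLS models are fit on the full training
  partition (no out-of-fold scheme at this level — the single-sensor models
  are reused as feature extractors); their latent scores are concatenated
  (width = sum of base LV counts) and a second PLS with `u` latent variables
  (2–17) is fit on that space.
* **Late / decision**: stacked generalisation. Base models produce
  out-of-fold (OOF) predictions under a seeded shuffled 20-fold split of the
  training rows; an ordinary least-squares meta-learner (intercept plus one
  unconstrained weight per base model — negative weights permitted) is fit on
  the OOF prediction matrix; base models are refit on all training rows for
  inference. The OOF matrix is retained on the model for audit. Only the OOF
  variant is implemented; training the meta-learner on in-sample base
  predictions invites exactly the overfitting stacking exists to avoid.

## Evaluation designs

* **Batch-on-batch**: train and tune on sourcing batch 1, test on batch 2 of
  the same and the opposing packaging condition. Tuning is repeated k-fold CV
  (3 × 10) minimising RMSEcv.
* **Repeated nested CV**: 10 repeats × 5 outer folds (50 assessments per
  model). Per outer fold, an inner 5-fold CV selects LV counts on the
  training side only; the winner is refit on all inner data and scored on the
  held-out fold. The outer splits are a pure function of (sample IDs,
  repeats, outer_k, seed) with repeat-level seeds derived as `seed + repeat`,
  so every model sees the identical split series (paired folds) and adding
  repeats never changes earlier splits.

Metrics: RMSE (log CFU/g); test-set R² = 1 − SS_res/SS_tot (can be negative);
"accuracy" = fraction of predictions within ±1 log CFU/g (inclusive), the
domain's acceptability threshold. Summary tables report accuracy as a
percentage; the internal metric is a fraction.

LV search ranges default to MSI 2–17, FTIR 2–20, MSIF 2–7, early 2–20, meta
2–17 (the nested-CV-specific statement of the search space, chosen over the
looser 1–20 phrasing; all config-overridable). Random search draws candidates
uniformly **without replacement** (the standard roster uses 1500 draws for
two-sensor mid fusion, 2500 for three-sensor mid, 400 for three-sensor late);
exhaustive search elsewhere. Ties in RMSEcv break toward fewer total LVs,
then lexicographically — preferring the simpler model.

## Model comparison

Paired fold RMSEs are compared with the Wilcoxon signed-rank test: zero
differences dropped (classical Wilcoxon rather than Pratt's method; recorded
in the report metadata), midranks for ties, W = min(W⁺, W⁻), two-sided p.
For n ≤ 25 the p-value is exact, computed from the tie-aware null
distribution of W⁺ built by dynamic programming over all 2ⁿ sign assignments
(doubling ranks makes midranks integral); beyond that, the normal
approximation with continuity correction and tie-corrected variance is used.
Within one scenario panel, all tested pairs form a single Holm–Bonferroni
family (step-down, monotonicity enforced, capped at 1); tiers are `*` / `**`
/ `***` at 0.05 / 0.01 / 0.001 on the adjusted p, and the star-matrix
rendering flags pairs whose difference favours a non-fusion model.

## The synthetic-data generator

The raw study spectra are not deposited, so the generator emulates their
statistical structure at the tabular level the pipeline consumes.

**Design.** Two sourcing batches × two packaging conditions (aerobic and
vacuum/MAP) × three isothermal temperatures (0, 5, 10 °C), sampled every
24–48 h out to temperature-dependent horizons (216/192/96 h by default),
with 2–4 replicates drawn per sampling point (the studied data had 2–10; the
narrower default keeps dataset sizes near the study's ~270–290 samples).
Sample IDs follow `<meat>_<condition>_<tempC>_<timeH>_<batch>_<rep>`.

**Growth.** TVC follows a three-phase logistic in log-count space: flat at
`initial_load` during a lag (default 12 h), a logistic rise whose rate is
`rate_at_ref · temp_sensitivity^T · condition_rate_factor` (defaults 0.035/h
at 0 °C, ×1.12 per °C, ×0.6 under vacuum), and a plateau at `max_load`. The
logistic is renormalised so the curve starts exactly at `initial_load` and
approaches `max_load` exactly. Defaults (initial 5.2, max 9.3 log CFU/g)
place initial loads in the observed 4.5–6 range and drive counts past the
7–8 log CFU/g spoilage region within the monitoring horizon. Replicate noise
is 0.25 log; batch 2 is offset by −0.7 log CFU/g (the observed ~0.5–1 log
between-batch difference) plus a 2% spectral gain shift.

**Spectra.** Each modality observes the TVC signal through its own loading:
FTIR loadings are Gaussian bands at 1545/1640/1450 cm⁻¹ (the amide region
where spoilage-related variance concentrates) on a uniform grid whose step
(1100/1140 cm⁻¹) puts exactly 1141 points in the closed 900–2000 cm⁻¹
window; MSI loadings sit in the 450–700 nm pigment region across 18
VideometerLab-style bands (mean and sd features per band, 36 columns); MSIF
is an 8-band UV/blue analogue with weaker amplitude (16 columns). Rows
receive multiplicative gain and additive offset artifacts (sd 0.08) that SNV
removes exactly, plus iid feature noise.

**Fusion headroom.** The key generative lever: each modality's effective
signal is `tvc + w_u · u_m`, where `u_m` is a per-modality latent factor
drawn independently of the target and of the other modalities' factors.
Every single sensor therefore carries an irreducible error floor of about
`w_u` (defaults: MSI 0.28, FTIR 0.40, MSIF 0.55 log CFU/g — ordering chosen
so MSI is the best single sensor and MSIF the weakest, as observed), and
because the floors are independent, combining sensors genuinely reduces
error (the inverse-variance bound for MSI+FTIR is ≈0.23). This makes "fusion
beats the best single sensor" a property of the data-generating process, not
of a tuned pipeline, and `oracle_signal_report` exports the exact generative
weights so recovery tests can condition on them. A shared nuisance factor
(loadings outside the signal regions) adds non-target structure all sensors
see.

**What the generator does not emulate.** Instrument physics, image
segmentation, species-level microbiota composition, nonlinear
detector effects, and the messier failure modes of real batch effects
(condition-dependent drift, heteroscedastic replicates). Synthetic results
therefore demonstrate that the pipeline recovers fusion gains *where gains
exist by construction*; they do not certify effect sizes on real meat, and
the study's published per-table values are not reproduction targets here.

## Problem sizes and numerical choices

Reduced-scale defaults used by the tests, the acceptance script, and the
analysis drivers: ~130-sample datasets (48 h sampling, 2–3 replicates),
2 repeats × 5 outer folds, trimmed LV grids (MSI 2–8, FTIR 2–10, MSIF 2–5,
meta 2–8) — sizes at which the designed fusion effect (~20% RMSE reduction)
is resolved comfortably while a full replicate experiment runs in about a
minute on one CPU. The full study-scale design (~290 samples, 10 × 5 nested
CV) is the default for the analysis drivers' dataset simulation and runs in
a couple of minutes.

Other numerics: CSVs are written with 17 significant digits and parsed in
round-trip mode, so write/load is bit-exact; dataset alignment is a strict
inner join on sample ID with dropped-row counts logged; constant rows
(SNV), constant training columns (standardiser), constant y (PLS, R²), and
empty restriction windows raise immediately rather than propagating NaNs;
all randomness flows from explicit integer seeds through
`numpy.random.default_rng`, and late-fusion OOF folds derive from the run
seed so rerunning any stage is bit-reproducible.

## Known limitations

* Wilcoxon on 50 nested-CV folds treats fold RMSEs as exchangeable pairs;
  folds within a repeat share training data, so p-values are optimistic in
  absolute terms — they are used comparatively, as in the study design.
* The meta-learner is unregularised OLS; with many highly correlated base
  models a ridge penalty would be more stable (out of scope).
* Batch effects are additive on TVC plus a small gain shift; real batch
  structure can be adversarial in ways the generator does not attempt.
* No feature selection (e.g., recursive elimination) and no PLS2 /
  multi-response variants.
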