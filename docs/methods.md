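# Methods

This note records the models, the numerical choices, and the design
decisions behind `rootnirs`, in the order the pipeline runs.

## Synthetic study data

The generator emulates a multi-environment cassava field study phenotyped
with a pocket NIR spectrometer (740–1070 nm). It is first-class, tested
code: every downstream stage is validated against data whose ground truth
is known.

### Trait tables

Plot values follow the variance-component decomposition used for the mixed
model itself:

    y_ijlk = mu + beta_j + g_i + r_l(j) + rho_k(l) + (g beta)_ij + e_ijlk

* `beta_j` — environment effects, drawn once from N(0, `env_effect_sd`²)
  and then held fixed (environments are fixed effects; the draw only
  creates a realistic spread between trials).
* `g_i`, `r_l(j)`, `rho_k(l)`, `(g beta)_ij`, `e_ijlk` — independent
  zero-mean Gaussian draws at the configured variances, with the clone
  effect `g_i` reused across environments.
* Defaults (trait-percent² units): σ²_g = 4, σ²_r = 0.5, σ²_k = 0.25,
  σ²_ge = 1, σ²_e = 2 (StC) / 1 (DMCo). Trait means default to StC 30 %,
  DMCo 35 % — plausible breeding-population values, configurable.
* DMCg is generated as DMCo plus N(0, 1.5²) measurement noise: the
  gravimetric (air/water weighing) method observes the same underlying
  composition as oven drying, more noisily. This makes DMCg intrinsically
  the hardest trait to predict, matching its reported behaviour.
* Designs are randomized complete blocks: clones are spread over
  `n_blocks_per_rep` blocks within each replication deterministically
  (clone index modulo block count). Augmented designs are out of scope.

### Spectra

A reading r of plot p is

    A_r(λ) = a_r · [ s0(λ) + Σ_k L_k(traits_p) · G(λ; c_k, w_k) ]
             + b_r + t_r · (λ − λ_mid)/span + ε_r(λ)

* `s0` is a common smooth baseline profile (~0.5 AU). It matters: trait
  information must ride on band *shape* on top of a large shared
  absorbance, so that multiplicative scatter (`a_r`) contaminates raw
  amplitude and scatter-corrective pre-treatments (SNV/MSC) have something
  real to fix. Scaled by `baseline_amplitude` (0 disables).
* Bands are Gaussians with per-trait loadings. Defaults place a water-
  dominated band at 970 nm (width 35 nm, negative loading on dry matter),
  a C–H/starch band at 910 nm (width 25) and a secondary combination band
  at 1020 nm — domain-plausible stand-ins chosen inside the device window;
  the device itself constrains only the range. Spectra are driven by the
  *physical* traits StC and DMCo; DMCg, being a measurement of DMCo, has
  no band of its own.
* `a_r ~ 1 + N(0, slope_sd)` (multiplicative scatter), `b_r` additive
  offset, `t_r` linear tilt, `ε` iid channel noise.
* Sample-type regimes (defaults): mashed — slope 0.02, offset 0.010, tilt
  0.008, noise 0.002, 4 readings/plot; fresh — slope 0.08, offset 0.040,
  tilt 0.030, noise 0.008, 47 readings/plot, **plus** a per-reading trait
  jitter (sd 1.5 %) for within-root heterogeneity **and** a per-plot trait
  bias (sd 2.5 %) shared by all readings of the plot. The plot bias is the
  load-bearing fresh handicap: with 47 readings averaged, independent
  per-reading noise shrinks by √47 and would leave fresh spectra nearly as
  informative as mashed; a surface section that misrepresents whole-root
  composition does not average out. The 2.5 % default reproduces the
  reported size of the fresh/mashed calibration gap for dry matter
  (R ≈ 0.75–0.8 fresh vs ≈ 0.97 mashed).

What the generator does *not* model: instrument response of the 12-filter
detector, wavelength-dependent noise, temperature/moisture drift,
non-Gaussian trait distributions, spatial field trends, and unbalanced
trial networks. Passing tests therefore demonstrate correctness of the
*analysis* under a known truth, not device-level realism.

## Pre-treatments

* **SNV** centres each spectrum and scales to unit sample sd (n−1
  denominator; the convention is unstated in the chemometric literature
  often enough that it is fixed and documented here).
* **MSC** regresses each spectrum on a reference (OLS, x = b0 + b1·ref)
  and returns (x − b0)/b1. The reference is the column mean of the
  *calibration* partition; holdout and new spectra are corrected against
  the stored calibration reference so no holdout information leaks into
  the transform.
* **Savitzky–Golay**: local cubic least squares on an 11-point window;
  edges are fitted on the truncated asymmetric window so the length is
  preserved; derivatives are per nm.
* **Gap-segment first derivative** (the "first derivative" of the
  treatment set): slope between the means of two 7-channel segments whose
  inner edges sit (window−1)/2 = 5 channels either side of the target
  channel, divided by the distance between segment centres in nm. A line
  maps exactly to its slope; additive baselines vanish. Edges are filled
  with the nearest valid value. A plain two-point finite difference is
  available (`finite_difference`) but is not part of any named treatment.
* **Detrend** subtracts an OLS polynomial in wavelength, default degree 2
  (the common chemometric choice for baseline curvature).
* Compositions: `d1_dt` = derivative then detrend; `d1_msc` = derivative
  then MSC (reference computed on derivative spectra); `sg_snv` = SG
  smoothing (deriv 0), then gap-segment derivative, then SNV. SNV last
  means every `sg_snv` row has mean 0 and sd 1 exactly.
* **IQR screen**: per-channel Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
  with type-7 quartiles; a reading is discarded when more than 10 % of its
  channels fall outside. The per-sample rule (fraction of offending
  channels) is this package's operationalisation of a loosely stated
  practice; both threshold and k are parameters. Below 4 readings the
  filter is skipped with a warning — quartiles of 3 points are noise.

## Calibration protocol

* Modelling is at plot level on per-plot mean spectra (traits are
  plot-level observations; replicate readings are acquisition repeats, not
  independent samples).
* 80/20 calibration/holdout split, simple random over plots, seeded.
* Repeated cross-validation: 5 folds × 5 repetitions; out-of-fold
  predictions are pooled within a repetition, scored, and the reported
  metric is the mean over repetitions (pooling is one of two common
  conventions; chosen for stability at these fold sizes).
* Residual trimming: per-sample residual = |observed − mean out-of-fold
  prediction| from the stage-1 repeated CV — cross-validated, not refit,
  residuals, so the trim cannot be optimistic. The ⌊0.2·n⌋ largest are
  removed exactly once; stage-2 repeated CV on the retained set gives the
  reported calibration metrics; the final model refit on the retained set
  predicts the holdout.
* PLS components: chosen once on the full calibration set (stage 1) by the
  one-standard-error rule over repeated-CV RMSE (smallest count within one
  SE of the minimum, capped at 20) and reused for stage 2 and the final
  model, so trimming does not silently change model complexity.
* SVR open parameters (the printed configuration fixes kernel and C only):
  ε = 0.1 and γ = 1/(n_channels · mean channel variance) — not
  study-reported values, recorded here as implementation defaults.
* Stochastic-engine seeding: one protocol seed expands deterministically
  into per-repeat fold permutations and per-(repeat, fold) engine seeds,
  so fold assignments are byte-identical across engines and reruns.
* Treatment screening uses PLS runs only (one per treatment × sample
  type): treatments are ranked within each sample type on calibration-CV
  Pearson R (descending) and RMSE (ascending); the winner minimises the
  mean rank across both metrics and both sample types; exact ties break by
  the fixed treatment-name order and the decision is recorded in the run
  report.

## Metrics

RPD uses the sd of the *observed* (reference) values with the n−1
denominator; RPIQ uses the type-7 interquartile range of the observed
values. R² is the square of Pearson R by default — the convention matching
reported R/R² pairs (0.97 → 0.94) — with 1 − SSE/SST available via
`r2_method="explained_variance"`. "Bias" is genuinely ambiguous in
chemometric reporting (calibration biases quoted near 1 are slope-like;
validation biases near 0 are additive), so both candidates are computed
under unambiguous names: `bias_additive` = mean(predicted − observed) and
`slope` = OLS slope of predicted on observed. A zero-RMSE fit reports
RPD/RPIQ as +inf with a warning rather than failing.

## Mixed model, BLUPs, deregression

REML with the residual variance profiled out. With variance ratios
λ_i = σ²_i/σ²_e, the profiled −2 log-likelihood is, up to a constant,

    (n − p)·log(r/(n − p)) + Σ_i q_i·log λ_i + log|C|

where C is Henderson's coefficient matrix [[X'X, X'Z], [Z'X, Z'Z +
diag(1/λ_i)]] and r = y'y − [b; u]'[X'y; Z'y]. Cross-products are formed
once per fit, so each evaluation costs one Cholesky factorisation.
Optimisation is bounded Nelder–Mead over log λ (bounds ±10), followed by
an EM polish — the Nelder–Mead objective is numerically flat near the
optimum (curvature ~1e-2 in log λ), which caps derivative-free accuracy
near 1e-6 on the components, while the EM fixed point
σ²_i ← (u'u + σ²_e·tr(C⁻¹)_ii)/q_i satisfies the score equations to
machine precision. The balanced-design closed form (expected mean squares)
is the validation oracle.

* PEV_i = σ²_e · (C⁻¹)_ii on the clone block (the standard convention);
  reliability = 1 − PEV/σ²_g, clipped to [0, 1].
* dBLUP_i = BLUP_i / (1 − PEV_i/σ²_g). Clones at or below the reliability
  floor (default 0.05) get a missing dBLUP with a warning instead of an
  exploding value; σ²_g = 0 is an explicit error.
* Terms with fewer than two levels are dropped automatically, as is the
  clone-by-environment term when only one environment is present (it is
  confounded with the residual there). Non-convergence of the search is
  flagged on the returned fit, never silent.
* A single combined-analysis σ²_g is used for deregression of every clone,
  per the deregression formula's single genetic variance.

## Selection concordance

"Top" means largest values for all three traits (higher starch and dry
matter are the breeding goals). Selection takes the ⌈fraction·n⌉ best
clones (default 20 %); ties at the cutoff break by ascending clone id with
a warning; missing scores (e.g. floored dBLUPs) are excluded with a
warning. Kappa is the standard Cohen statistic κ = (p_o − p_e)/(1 − p_e)
with p_e from the marginal selection rates. (The source formula for this
statistic is sometimes printed with a plus sign in the numerator; that
form contradicts the statistic's own bounds — κ = 0 at chance agreement
requires the minus — so the standard form is used.) The degenerate case
p_o = p_e = 1 is defined as κ = 1. In the pipeline, the phenotype ranking
and each engine's ranking are both dBLUPs from the same mixed model — the
engine's fitted on its plot-level predictions — so the comparison is
selection-decision against selection-decision, not prediction against raw
mean.

## Problem sizes and determinism

The bundled demo and the acceptance script use 120 clones × 2 environments
× 2 replications (480 plots; fresh 22 560 readings, mashed 1 920), with the
parameter-recovery check at 200 clones × 3 environments × 2 replications —
sizes at which every qualitative contrast the package tests (mashed >
fresh, scatter correction under contamination, trim recovery, high-R /
high-κ coupling) is stable across seeds while a full run stays in the
minutes range on one CPU. All randomness flows from a single master seed
through named `SeedSequence` streams; identical configuration + seed
reproduces every table byte-for-byte (the two stochastic pieces — fold
shuffles and gradient-boosting subsampling — are seeded per repeat and
fold).

## Known limitations

* The gap-segment derivative's exact segment/gap geometry varies between
  chemometric packages; the convention above is fixed, tested and
  documented, not claimed to replicate any particular implementation.
* The IQR screen is a per-channel-fraction rule; other operationalisations
  (scalar summaries, response-space screening) exist.
* REML assumes homogeneous residual variance across environments and no
  genetic relationship matrix; unbalanced augmented designs are not
  supported.
* Synthetic spectra are linear in trait loadings (Beer–Lambert-like);
  engine comparisons on them will not reproduce nonlinearity-driven
  advantages (e.g. tree ensembles on heterogeneous fresh tissue) beyond
  what the injected distortions create.
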