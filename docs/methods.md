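# Methods

This note records the models, the numerical choices and the limits of what
the test suite demonstrates.

## Lipid normalisation

Bulk liver δ¹³C is corrected per individual as
`δ¹³C_corr = δ¹³C_bulk + β₀ + β₁·ln(C:N)`, where C:N is the elemental
*mass* ratio %C/%N (the correction literature for this model family uses
mass ratios, and elemental analysers report mass percentages).  The shipped
`liver-ethanol` coefficient set, β₀ = −3.9556, β₁ = 3.7319, is calibrated
for ethanol-preserved rodent liver by requiring the shift to be +0.5 ‰ at
C:N 3.3 and +1.4 ‰ at C:N 4.2 — the two per-individual worked examples this
pipeline is expected to reproduce.  Under a cohort with C:N ~
Normal(3.8, 0.5) truncated to [3.2, 5.7] the mean shift is ≈ 1.1 ‰.  The
registry is user-overridable (named set or explicit β₀/β₁ in the run
config).  Two caveats: (i) a site-mean corrected value is the mean of
per-individual corrections, which differs from correcting the site means
(ln is concave), so mean-level reproductions can disagree by ~0.1–0.2 ‰;
(ii) the SD of the per-animal shift under the truncated normal (≈ 0.4 ‰)
is smaller than in right-skewed real C:N samples.  δ¹⁵N and δ³⁴S are never
corrected.

Elevational bins are half-open `[lower, upper)`, the top bin unbounded; a
boundary elevation belongs to the bin whose lower edge it equals.

## Plant baselines

Baselines keep raw plant values, because the Bayesian models treat baseline
observations as data, not fixed constants; a baseline needs ≥ 2 plants.
"Plants > 4000 m" is implemented as the union of the 4000–5000 and > 5000
bins.  For a bin mixing photosynthetic pathways, the two-source split is
the global optimum of the two-group within-sum-of-squares objective on
δ¹³C (for 1-D data the optimum is a contiguous split of the sorted values,
so scanning the n−1 split points is exact); source1 is the ¹³C-depleted
(C3) group.  A manual `source` column on the plant table overrides the
automatic split.  When the best split still leaves > 25% of the δ¹³C sum
of squares within groups, a weak-bimodality warning is emitted — a unimodal
normal sample leaves ≈ 1 − 2/π ≈ 36%, a separated C3/C4 mixture ≈ 5%, so
the threshold sits between the two regimes.  This is a heuristic, not a
formal dip test.

One ambiguity is resolved in favour of the tabulated analysis: the summit
singleton's baseline defaults to all plants above 4000 m; a > 5000 m-only
mapping is expressible in the run config.

## Trophic-position models

Point estimate: `TP = λ + (δ¹⁵N_cons − δ¹⁵N_base)/Δ¹⁵N`, λ = 1 for plant
baselines.  TDF defaults (mouse liver, control diet): Δ¹³C = 0.7 ± 0.3,
Δ¹⁵N = 4.3 ± 0.2, Δ³⁴S = −2.1 ± 0.1 ‰ (δ³⁴S is used only for habitat
discrimination, never in TP).

**Population one-baseline.**  baseline ~ N(μ_b, σ_b); consumer ~
N(μ_b + Δ¹⁵N·(TP−λ), σ_c); Δ¹⁵N ~ N(4.3, 0.2).

**Two-baselines full.**  Both elements carry a trophic shift and the diet
proportion α (from source1) mixes the source means:
δ¹⁵N ~ N(α·μ_N1 + (1−α)·μ_N2 + Δ¹⁵N·(TP−λ), σ_cN), and analogously for
lipid-corrected δ¹³C with Δ¹³C; α ~ Uniform(0, 1).  All four source
mean/SD pairs are estimated from the plant values.  Label switching is
absent because each source carries its own observations.

**Individual one-baseline** (for a single animal): μ_b ~ N(baseline sample
mean, baseline sample SD); σ_b ~ Cauchy(location = baseline sample SD,
scale 3) truncated to [0, ∞); the one consumer value is
N(μ_b + Δ¹⁵N·(TP−λ), σ_b).  The heavy-tailed σ_b prior is honest about how
little one observation constrains the residual spread — individual CIs are
wide by design.

Priors the procedure does not fix: TP ~ Uniform(λ − 0.5, 10) (permissive,
covers sub-baseline consumers, bounded for sampler stability) and
half-Cauchy(0, 3) on residual SDs, matching the scale used for the
baseline SD.  The Cauchy/half-Cauchy scale is exposed as
`TPModelConfig.sigma_prior_scale` (default 3).

### Sampling and numerics

Models are sampled with affine-invariant ensembles (emcee); a "chain" is an
independently seeded ensemble of ≥ 2·(n params) walkers, initialised at
moment estimates with small jitter.  Per chain, `n_adapt + n_iter` steps
are run; the first `n_adapt + n_burnin` are discarded and every `thin`-th
snapshot of all walkers kept.  Defaults: population models 3 chains ×
(1000 adaptive + 20 000 iterations, 1000 burn-in, thin 10); the individual
model 16 chains × (1000 warm-up + 600 steps, thin 8) ≈ 10 000 kept draws.
SDs are sampled on the log scale (with the Jacobian) and floored at 10⁻⁶,
which keeps degenerate-variance runs finite.  Convergence is summarised by
split-R̂ per parameter: a fit with any R̂ ≥ 1.1 raises unless
`allow_nonconverged`; R̂ ≥ 1.05 clears the `converged` flag.

Posterior summaries: the mode is the argmax of a Silverman-bandwidth
Gaussian KDE on a 512-point grid over the draw range (≥ 1000 pooled draws
required; constant draws short-circuit); the credible interval is the
central 95% quantile interval.  In the degenerate limit (all data variances
and the SD-prior scale driven to ~0) every model's mode matches the
deterministic formula to < 0.02 TP units; with the default scale-3 prior
the single-observation model keeps a broad posterior background, and its
KDE mode then carries ~0.03 of estimation noise — a property of
KDE-summarising a sharp-peak-plus-heavy-tail posterior, not of the sampler.

## PERMANOVA and CAP

Distances are Euclidean on raw (unstandardised) ‰ values of
(lipid-corrected δ¹³C, δ¹⁵N, δ³⁴S); the elements share a scale, and no
standardisation step is part of the procedure (a config switch could add
one).  The pseudo-F uses the sums-of-squared-distances decomposition
(SS_tot = Σd²/N form); p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) under
raw-observation permutation, so p ≥ 1/(n_perm + 1) always.  On univariate
Euclidean data the pseudo-F is algebraically the classical one-way ANOVA F,
which the tests verify to 10⁻¹⁰, and its type-I error at α = 0.05 is
calibrated to [0.03, 0.07] over 1000 simulated exchangeable nulls.
Pairwise post hoc tests report t = sqrt(two-group pseudo-F) with raw
(unadjusted) p-values.  Sites represented by one animal are excluded.

CAP Gower-centres the squared distance matrix, eigendecomposes it, keeps
the first m orthonormal principal-coordinate axes and performs a canonical
correlation analysis against the group indicators; because the axes are
centred and orthonormal this reduces to the eigenstructure of Q_m'HQ_m
(H the group-mean projection), whose eigenvalues are the squared canonical
correlations; trace = their sum ≤ min(m, g−1).  If m is not given it is
chosen in [1, min(N−2, 20)] to maximise leave-one-out success, smallest m
on ties.  Negative PCoA eigenvalues (absent for Euclidean input) are
dropped with a warning.

Classification rescales each canonical axis to unit within-group variance
(factor 1/√(1−δ²), clipped at δ² = 1 − 10⁻¹²) and allocates to the nearest
group centroid; with Euclidean distances and full-rank m this reproduces
classical linear discriminant allocation exactly (verified against an
independent LDA implementation).  Leave-one-out refits on N−1 samples and
projects the held-out sample by the Gower add-a-point formula
y = (g'Q)/λ with g = ½(diag(B) − d₀²), which reproduces a training point's
coordinates exactly; distance ties are broken to the lexicographically
first group label and flagged.  A sample whose group is emptied by its own
removal is classified against the remaining groups and flagged.  Confusion
tables report per-row percent correct with plain rounding (so 7/8 prints
as 88, whatever convention produced a published 86).

## Synthetic data

The generators are pure functions of (spec, seed).  The default consumer
survey transcribes the seven-site structure of the motivating study
(n = 8/8/4/8/5/7/1 from 2370 to 6739 m, with the published per-site
isotope and C:N means/SDs); within a site, variables are independent
normals except (C:N, bulk δ¹³C), drawn jointly with correlation −0.3
(the within-site direction reported in the study; the true within-site
covariance of the three isotopes is unknown and left at zero).  C:N is
rejection-truncated to [3.0, 6.0], wide enough not to distort the mean
materially.  %C/%N columns are emitted consistent with the drawn ratio.

Default plant baselines: δ¹³C ≈ −26 ‰ (C3) vs −13 ‰ (C4/CAM) with an even
bimodal mixture in the 3000–4000 m bin; plant δ¹⁵N ≈ 5–6.5 ‰ at low/mid
elevation and ≈ 1–2 ‰ above 4000 m.  These values were fixed once so that
the synthetic survey reproduces the qualitative TP structure of the real
system (high-elevation herbivores near TP 2, the summit singleton near
2.2, an implausibly high TP at the ¹⁵N-enriched lowest site) and are not
fitted quantities.  What passing tests show is that the *methods* recover
known truth under this structure; they cannot show that real livers meet
the normality, independence or baseline-matching assumptions.

`simulate_consumers_known_tp` inverts the TP equation (consumer δ¹⁵N =
baseline mean + Δ¹⁵N·(TP−λ) + noise) for parameter-recovery studies and
serialises the truth record.

## Simulation sizes used by the test suite

Parameter recovery: 102 datasets (34 each at TP 1.5/2.2/3.0; 8 consumers,
σ_c = 0.5, baseline n = 20) with a shortened sampler (2 chains ×
1500 iterations), mean absolute error of the posterior mode ≤ 0.25.
Individual-model coverage: 50 single-consumer replicates at TP 2.5, 95% CI
coverage within 85–100%.  Type-I error: 1000 PERMANOVA nulls × 199
permutations.  The end-to-end fixture uses 3 chains × 4000 iterations
(population) and 8 chains × 600 (individual), which keeps every split-R̂
below 1.05 on the fixture data.

## Known limitations

- The exact likelihoods of the reference population-model implementation
  are not published alongside the procedure; the forms above are
  reconstructions and are validated by parameter recovery and limit
  behaviour, not line-by-line equivalence.
- No multi-element mixing beyond the two-source δ¹³C/δ¹⁵N model; δ³⁴S never
  enters TP.  No multi-factor or nested PERMANOVA; Euclidean distances
  only; no eigenvalue corrections for non-Euclidean input.
- The lipid-correction coefficients are a single named set calibrated for
  one tissue/preservation combination; cross-species use requires
  supplying published coefficients for the tissue at hand.
- Ensemble walkers within a chain are not independent, so the reported
  effective sample size (Geyer initial-sequence estimate per chain) is an
  approximation.
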