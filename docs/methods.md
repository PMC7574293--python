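# Methods

## Model

A mixed-cell sputum measurement is treated as a linear combination of
cell-type-specific values. For feature j and sample s,

    y_sj = sum_c f_sc * beta_cj + e_sj

with f_sc the counted fraction of cell type c (from the differential cell
count, not estimated), beta_cj the latent cell-type profile, and e_sj
measurement noise. This linearity only holds on scales where signals add:
linear intensity for expression and the beta-value scale for methylation.
Log2 expression is therefore linearized before deconvolution and a hard
error stops log2 input.

Per sample group, per feature, the profiles are the solution of the
box-constrained least-squares problem

    min_beta || y - F beta ||^2   s.t.   l <= beta <= u

solved as a quadratic program (`scipy.optimize.lsq_linear`). Bounds are
[0, 1] for beta values; for expression the dynamic range of the observed,
normalized array (`BoxBounds.expression_auto`), overridable. The design F
has one column per *major* cell type plus a weighed-intercept column equal
to the summed fractions of the remaining minor types, which absorbs their
pooled profile while preserving residual degrees of freedom. Monocytes are
excluded from the design before renormalization (near-absent and
non-determinant; in the generator they carry no spiked signal either, so
they are pure nuisance by construction). Major types default to
AM/NG for every group and AM/NG/EO for asthma, where eosinophils are
prevalent and variable enough to be identifiable.

Standard errors use the classical formula SE_j = sigma_hat *
sqrt(((F'F)^-1)_jj), sigma_hat^2 = RSS/(n - p), df = n - p. When box
constraints are active this is an approximation; affected features are
flagged in the diagnostics (`n_active`) so users can filter. Near
rank-deficient designs (condition number > 1e6) get a 1e-8 ridge in the SE
computation plus a warning rather than a crash.

Estimates are compared across groups with a Welch t test built from the
estimate, its SE and the residual df of each group's fit:
t = (b1 - b2)/sqrt(se1^2 + se2^2), df by Welch-Satterthwaite. On mixed-cell
matrices the Welch test runs on per-sample values (log2 scale for
expression, beta scale for methylation). P values are BH-adjusted
(statsmodels). Significance policy ("paper" policy, immutable per run):

| context      | modality     | BH p    | effect floor    |
|--------------|--------------|---------|-----------------|
| mixed-cell   | expression   | < 0.05  | abs log2FC >= 1.5 |
| mixed-cell   | methylation  | < 0.05  | abs dbeta >= 0.1  |
| deconvolved  | expression   | < 0.005 | abs log2FC >= 1.5 |
| deconvolved  | methylation  | < 0.001 | abs dbeta >= 0.1  |

The stricter deconvolved cutoffs compensate for the normality assumption
being least trustworthy there. Deconvolved expression effects are
log2(est1/est2) of the (positive, bounded) linear estimates; a difference-
of-logs variant exists behind `effect_mode` but is numerically identical
for point estimates. Two-sided tests throughout (standard for screens).

## RNA-degradation correction

Partial degradation attenuates probes at probe-specific rates. On log2
data the pipeline offers:

- **Correlation filtering**: drop probes with |Pearson r| against RIN at
  or above a threshold. The threshold is a required explicit argument in
  pipeline runs — it trades robustness against coverage and must be a
  deliberate choice, so there is no silent default.
- **Linear correction**: per probe, fit value ~ intercept + b*RIN
  (+ group indicators if requested), then subtract b*(RIN - rin_ref).
  rin_ref defaults to the cohort mean RIN, keeping corrected values on the
  observed scale. Covariate-free correction makes every probe's residual
  correlation with RIN exactly zero (least-squares orthogonality; asserted
  to 1e-6 in the acceptance suite). When degradation is confounded with
  group, the group covariate must be supplied: it protects true group
  effects from being regressed away, at the price of slope estimates
  driven by within-group RIN spread only. Both modes are exposed because
  the right choice depends on the confounding structure; covariate-free is
  the default for unconfounded cohorts.

Samples below a minimum RIN (default 3.0, configurable) are excluded at
intake for expression analysis. PCA diagnostics (feature-centered SVD,
sign fixed by making each component's largest-magnitude loading positive)
quantify how much of the variance the integrity axis explains before and
after correction.

## Preprocessing

Expression: background correction subtracts mean background from median
foreground; nonpositive values are replaced by half the minimum positive
corrected value on that array (the "minimum" convention), keeping all
values log-transformable. Quantile normalization maps every column onto
the cross-column mean quantile vector; ties receive the mean of the tied
rank values, which makes the operation deterministic, order-independent
and idempotent. Probe filtering drops controls, probes flagged
non-uniform/saturated/population-outlier on *any* array, and probes not
found-and-significant in at least 50% of arrays of at least one group.
Replicate probes are arithmetically averaged to probe level.

Methylation arrives as beta matrices (raw-intensity import and stratified
quantile normalization are upstream concerns). CpGs are dropped on
detection p >= 0.01 in any sample (an `any`/`fraction` rule switch exists;
`any` is the default reading), on chrX/chrY, SNP affection or
cross-reactivity, with per-rule drop counts reported.

## Region and enrichment analysis

Significant DMPs are merged by a transparent distance rule: consecutive
significant CpGs on a chromosome within `max_gap` (default 1000 bp) form a
region, retained with >= `min_cpgs` (default 2) CpGs and at least one CpG
with |delta beta| > 0.1. This deliberately replaces kernel-smoothing DMR
callers with an auditable rule; the retention condition and the upstream
FDR contexts are unchanged. Region spans run from the first to the last
CpG position + 1; all internal coordinates are 0-based half-open (BED
convention), with 1-based-inclusive gene tables converted on read.
Promoters cover up to 1500 bp immediately upstream of the TSS on the
strand-appropriate side, clipped at the chromosome start; regions map to a
promoter or gene body at >= 200 bp overlap (`min_overlap`), possibly to
several genes. Gene-set overrepresentation is the upper-tail
hypergeometric p = P(X >= k) against a user-supplied background universe,
BH-adjusted across sets, reported at p < 0.1 and q < 0.2.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions of every recovery experiment.

- **Cell fractions**: per-group Dirichlet with alpha = mean * c. Means
  (percent): asthma AM 27.9 / NG 54.7 / EO 12.9 / LY 0.7 / MO 0.1 /
  CC 1.6 / SC 2.1; COPD 9.0 / 88.9 / 1.0 / 0.2 / 0.0 / 0.4 / 0.6
  (renormalized; the raw row sums to 100.1); controls 52.3 / 40.3 / 0.2 /
  2.0 / 0.2 / 1.6 / 3.4. The concentration c is fitted a priori from the
  dominant cell types' SDs via Var = m(1-m)/(c+1): asthma 3.2, COPD 22,
  controls 3.0. A Dirichlet guarantees simplex validity, which independent
  truncated normals would not; zero-mean components (COPD monocytes) are
  structural zeros. At n = 10,000 the empirical means recover the cohort
  means within 1 percentage point.
- **Profiles**: expression log2 values uniform on [6, 14] per feature with
  N(0, 1) cell-type deviations, exponentiated and clipped to the dynamic
  range [1, 65536]; methylation betas from a low/high/intermediate Beta
  mixture with N(0, 0.08) cell-type jitter, clipped to [0.01, 0.99] so
  mixtures stay interior. Marker features get large shifts in one cell
  type; spiked group effects (defaults: delta beta 0.2 and log2FC 1.5 in
  AM/NG/EO for asthma and AM/NG for COPD, 25 features each) are recorded
  with nominal and achieved (post-clipping) sizes.
- **Mixing**: observed = F B + additive Gaussian noise, clipped to the
  valid range with clip counts reported. Noise defaults: 0.02 beta units
  (typical technical replicate spread of beta arrays) and 25 linear-scale
  units for expression (an array noise floor that leaves low-expressed
  features noisy and high-expressed ones precise, as on real arrays).
- **RIN and degradation**: truncated-normal RIN per preservation route —
  RLT 8.6 +/- 0.4 on [7.6, 9.1]; HOPE 4.3 +/- 0.6 on [3.2, 5.1] — and
  multiplicative decay value * 2^(-lambda_p (rin_ref - RIN)), rin_ref = 9,
  with half the probes insusceptible (lambda 0) and the rest
  lambda ~ U(0.02, 0.3). The multiplicative form makes log2 trends linear
  in RIN, matching the per-probe linear correction model. After quantile
  normalization this produces probe-RIN correlations of both signs
  (insusceptible probes are pushed up in degraded samples to equalize the
  column distributions) — the generator reproduces the artifact the
  correction is designed for. A `confound_group_preservation` switch puts
  all COPD samples on the heavily degraded HOPE route; the joint
  fraction-group-RIN dependence of a real cohort beyond these marginals is
  deliberately not asserted.

What the generator does *not* emulate: probe-sequence effects, raw IDAT or
scan-file structure, spatial artifacts, correlated (batch) noise, and the
factor structure of real between-subject biological variation. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not performance on any real cohort.

## Study conditions and problem sizes

Default scenario: n = 10 per group, 2000 features per modality — the scale
at which per-feature QP estimation and Welch screens are exercised in the
test and acceptance suites. Null-calibration simulations use 10,000
features with composition held fixed across samples, because the
machinery-level null (iid Gaussian per feature) is the property being
tested: with group-specific composition laws, between-group mixture
differences are genuine signal, and the heavy common-factor structure of
compositional data makes per-feature "null" rates meaningless. The
degradation-diagnostic scenarios use a single cohort (n = 24) or a fully
confounded two-group design (n = 10 + 10, 4000 probes, lambda up to 0.6,
spiked log2FC 2.5 in neutrophils) so that degradation is strong enough to
corrupt naive calls — in that regime, covariate-adjusted linear correction
roughly doubles the F1 of differential calls against planted truth.

## Numerical choices and degenerate inputs

- QP tolerance 1e-12; when the unconstrained optimum is interior, the
  solution equals closed-form OLS to better than 1e-8 (tested on 1000
  random instances; grid-oracle optimality on 200 active-bound instances).
- Quantile normalization refuses missing values (handling them is an
  explicit upstream step) and warns on single-column input.
- Welch degenerate cases are defined, not accidental: zero variance on
  both sides with equal means gives (t=0, p=1); unequal means give an
  underflow-guarded minimal p and a degeneracy flag path.
- BH propagates NaNs without counting them as tests.
- Background correction errors out on an array with no positive corrected
  value rather than inventing a floor.
- Empty DMP tables and empty enrichment universes are explicit error or
  empty-output paths, never silent.
- All randomness flows through `numpy.random.SeedSequence` spawns of one
  user seed; identical seed + config reproduces every output byte.

## Known limitations

- SEs ignore active box constraints (flagged, not corrected); a
  constrained-inference treatment is out of scope.
- The DMP-merging region caller is a distance rule, not a smoother; region
  boundaries are data-dependent in a different way than kernel methods.
- Fractions are treated as known; counting error in the differential cell
  count propagates into the design matrix unmodelled.
- Mixed-cell differential results on compositionally distinct groups mix
  composition and regulation by construction; only the deconvolved
  contrasts separate them.
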