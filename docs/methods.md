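# Methods

This note documents the statistical models implemented in `methwas`, the
design of the synthetic cohorts that drive its tests, the numerical
choices inside the estimators, and the limits of what the test suite can
show about real data.

## Phenotype model and OREML

A binary case–control phenotype is analysed as 0/1 on the observed scale
with a linear mixed model — no liability-scale transformation is applied,
so the variance fraction `ρ² = σ²_o/(σ²_o + σ²_e)` is an observed-scale
quantity. The random-effect covariance is the omics relationship matrix
`A = WW′/m` over standardized probes; probes are standardized with the
population (1/n) variance so that `mean(diag A) = 1` exactly, which makes
the scale convention testable. The reported `ρ²` is
`σ²_o·mean(diag A) / (σ²_o·mean(diag A) + σ²_e)`, identical to the usual
ratio under this standardization but invariant to rescaling `W`.

REML uses average-information (AI) updates with three safeguards:

* the first iteration is an EM step (slower but ascent-guaranteed);
* components pinned at the floor (`1e-6 × var(y)`) with a negative
  gradient are dropped from the AI solve — including them distorts the
  update for the free components;
* AI steps are capped at 70% of the distance to the parameter boundary
  and step-halved (up to 8 times) whenever they would lose restricted
  likelihood, falling back to EM. Without the cap, the Newton step for a
  small variance component routinely overshoots negative and the halving
  never recovers an interior optimum.

Convergence is `|Δ log-lik| < 1e-8` within 100 iterations; non-convergence
raises with the full iteration trace. Standard errors come from the
inverse AI matrix, `se(ρ²)` by the delta method. The p-value for `ρ²` is
a `0.5·χ²₀ + 0.5·χ²₁` mixture likelihood-ratio test against `σ²_o = 0`;
the test used for the published OREML p-values is not stated, so this
convention is the package's own and is labelled as such.

Default fixed covariates for OREML and the scans are sex, predicted age,
predicted smoking score and predicted cell-type proportions excluding
eosinophils (dropping one type avoids compositional collinearity).
Predicted age and smoking are consumed as given covariates; the
predictors that produce them are out of scope.

## MOA and MOMENT

Both scans are two-step: variance components are estimated once under the
windowless model and reused for every probe. The covariance *shape* is
then held fixed while the overall scale is re-estimated per probe from
the generalized residual sum of squares, with a t reference on
`n − p − 1` degrees of freedom. This choice has a sharp consequence: when
the component variances vanish, both scans collapse *exactly* to the
per-probe OLS scan (a fixed-scale GLS would not, because OLS re-estimates
the residual variance per probe). The tests assert this limiting
equivalence at 1e-6.

MOMENT partitions probes into two random-effect components by their
initial OLS p-value (threshold 0.01 by default; the canonical default of
the underlying method is not printed in the study this package follows,
so the threshold is a flagged configurable). For each target probe, every
probe on the same chromosome within 50 kb (strict inequality) is removed
from both components. The removal is implemented as a Woodbury down-date
of the fitted covariance — exact given the fitted components — rather
than a per-probe REML refit; the `1/m_j` component scaling keeps the full
component's `m_j` (the difference is O(window/m)). An empty
high-association group collapses MOMENT to a single-component model with
a warning.

The genomic inflation factor is `λ = median(χ²₁)/0.4549364` computed from
the reported p-values.

### A measured property worth knowing

Under a planted cell-composition confounder (case–control Dirichlet shift
with no composition covariates), the per-probe OLS scan inflates badly
(pooled λ ≈ 1.15–1.35 in the acceptance conditions) while **both** mixed
models correct it almost completely. In these simulations MOA's pooled λ
is essentially 1.000 and MOMENT's is slightly above (≈ 1.016): a low-rank
composition factor lies inside the span of the probe matrix, so the
single-component random effect absorbs it fully, while MOMENT's exclusion
of the target from the random effect removes self-shrinkage and lifts its
statistics slightly. The same ordering appears in the real-data values
the pipeline is modelled on (MOA λ = 1.01 vs MOMENT λ = 1.04). MOMENT's
documented advantage — fewer spurious *top hits* when a confounder
concentrates on strongly associated probes — is not resolvable at desk
scale in this generator, where tail false-positive rates of the two
methods are statistically indistinguishable (OLS ≈ 5× nominal at
p < 1e-4; both mixed models ≈ nominal).

## Synthetic cohorts

Each probe's logit-scale signal is a cell-type mixture plus batch,
intrinsic and measurement-noise terms (observed beta = inverse-logit, so
values stay in [0, 1]):

* **Composition**: per-sample leukocyte proportions drawn from a
  Dirichlet around typical adult blood (neutrophils ≈ 52%, CD4T ≈ 15%,
  …, concentration 60, giving a neutrophil SD of ≈ 6 percentage points —
  in line with blood-count reference variation). By default 15% of probes
  are strongly cell-type discriminative (logit SD 2.0 between types, i.e.
  beta differences commonly > 0.3), the rest carry no composition signal,
  mirroring the discriminative-subset structure of real arrays.
* **Batch**: slide/row/column assignments with per-(level, probe) effects
  of logit SD 0.1.
* **Intrinsic variation**: per-sample, per-probe logit SD 0.8 — the
  disease-relevant axis; **noise**: logit SD 0.15.

Case status follows a liability-threshold model. The methylomic liability
component is a weighted sum of the *measured* causal-probe values
residualized on batch and composition (the intra-cell-type signal that
survives the downstream adjustments), rescaled so its sample variance is
exact; covariate and residual components are orthogonalized in sample, so
the configured fractions are exact rather than expected. Because the
liability is Gaussian and the threshold sits at the case-fraction
quantile, the *linear* observed-scale variance explained equals
`h²_liability · z²/(K(1−K))` exactly (z the normal density at the
threshold), and the generator inverts that relation: the configured
`liability_variance_explained` is the estimand of a linear mixed model on
the 0/1 phenotype. When case and control Dirichlet parameters differ, the
cases' compositions are redrawn after status assignment — disease drives
the composition shift (the direction of causation the blood-methylome
literature suspects), and the advertised variance fraction is then exact
only up to the small perturbation of the causal columns.

Discovery/replication pairs share a `CohortArchitecture` (probe map, cell
signatures, causal set and effect direction) so that sign-concordance and
classifier-transfer experiments have a shared truth; per-cohort draws
rescale the shared weights to the exact configured fraction.

All randomness flows from one integer seed through named substreams
(CRC-keyed `SeedSequence`s), so adding a component never perturbs the
draws of the others and regeneration is bit-identical.

**What the generator does not emulate**: probe–probe co-methylation
beyond shared composition/batch factors, sex chromosomes, related
individuals, population structure, dye-bias or intensity-level artefacts,
and real mQTL genetic architecture in the cohort matrices (genetics
enters only through the summary-statistic trio generator). Passing tests
therefore certify the estimators' behaviour under the stated model, not
performance on any particular array product.

## Cell-type deconvolution and LEDD

Proportions are estimated per sample by nonnegative least squares against
a reference signature matrix and normalized to sum to one — nonnegativity
is a hard constraint, the sum constraint is post-hoc normalization,
matching common practice for reference-based blood deconvolution. The
granulocyte fraction is defined as eosinophils + neutrophils. Disease
association is tested one cell type at a time by logistic regression
(intercept + sex + predicted age + the cell type); perfect separation is
flagged and the p-value reported as missing. Levodopa-equivalent daily
dose values given as ranges are resolved to midpoints, log-transformed
(the distribution is right-skewed) and z-standardized; LEDD–composition
correlations are Pearson, with a Bonferroni threshold of 0.05/6 for the
six tested types (seven minus eosinophils — which six were tested in the
source study is not stated, so the tested set is a parameter).

## Meta-analysis and replication tests

Fixed-effects inverse-variance pooling only (`b = Σw·b/Σw`,
`se = (Σw)^{-1/2}`, `w = se^{-2}`), restricted to probes present in all
cohorts; Cochran's Q is reported but never used to switch to random
effects. Sign concordance uses the exact binomial tail `P(X ≥ k)` at
p = 1/2; the empirical variant resamples probe sets without replacement
and uses the `(1 + #{null ≥ obs})/(reps + 1)` correction, so it can never
return zero (the `≥` side is this package's convention). Probe pruning is
greedy, ascending by p with ties broken by probe id, keeping a candidate
only if its squared correlation with every kept probe is below the
ceiling.

## SMR and HEIDI

`b_xy = b_zy/b_zx` with `χ²_SMR = z²_zy z²_zx/(z²_zy + z²_zx)` on 1 df;
instruments require exposure p < 5e-8 and the absence of one is a typed
outcome, not an exception. HEIDI includes cis-SNPs with exposure
p < 1.6e-3 and r² with the instrument inside [0.05, 0.9] (the cited
method's conventions; configurable), up to 20 SNPs. The deviations
`d_i = b_xy(i) − b_xy(top)` get a full delta-method covariance from the
LD correlations, and `Σ z²_d` is referred to an eigenvalue-weighted sum
of 1-df chi-squares. The tail is evaluated by Imhof's numerical
inversion, integrating one oscillation period at a time (the per-period
contributions form a near-alternating series; truncation when a period
contributes < 1e-9); a Monte-Carlo fallback exists and the two must agree
within 10% in tests. LD comes from a reference panel of at least 50
individuals (continuous imputed-style dosages in the simulator, so the
panel correlation is an unbiased estimate of the generating LD). The
multiple-testing threshold for the methylation→expression→trait chain
divides by the number of candidate genes carried forward.

## Classification

BLUP probe effects `û = (σ²_o/m) W′V⁻¹(y − Cβ̂)` are computed on the
training cohort and applied to the target by an id-keyed join (missing
training probes are dropped; the overlap fraction is reported and must
exceed 0.5 by default). Raw scores are z-scaled within the target cohort
*before* covariate-adjusted evaluation (the alternative order is not
identified by the source study; this is the documented choice).
Nagelkerke R² is the max-rescaled Cox–Snell statistic from nested
logistic fits with a 1-df LRT p; AUC uses the midrank (Mann–Whitney)
formulation with DeLong variance for the 95% CI — chosen over the
bootstrap for determinism.

## Quality control

Probe filters apply in a fixed order — detection rate (< 95% of samples
at detection p < 0.01), bead count (< 3), cross-reactive, sex-chromosome,
low variability (SD < 0.02) — and each reports its removal count;
filters whose input layer is absent are skipped and reported. Sample
filters: call rate (the 450K-era absolute threshold of 450,000 detected
probes generalizes to a fraction, default 0.927, of the array size), sex
mismatch, median-signal outliers (> 3 SD). Batch structure is removed by
regressing each probe on one-hot slide/row/column indicators and keeping
residuals (re-centred at the probe mean; values may leave [0, 1], which
is why downstream modelling uses standardized values and the readers
accept residualized matrices with range validation off). Filtering
precedes residualization; control-probe functional normalization is
deliberately not implemented — batch residualization is the explicit,
testable replacement, and this is a documented fidelity gap with
intensity-level pipelines.

## Problem sizes in the tests

The acceptance-style checks run at n = 500/m = 2000 (variance recovery,
10 seeds), n = 300/m = 1000 (scan calibration, 20 replicates), 100–200
replicates for SMR/HEIDI operating characteristics and n = 400/m = 1000
for classifier transfer — sizes chosen so the whole suite completes in
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted bands. On-disk formats are plain TSV/BED/.ma text; coordinates
are 0-based half-open on disk and 1-based in memory, converted in exactly
one reader/writer pair.
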