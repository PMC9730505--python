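# Methods

## Mismatch derivation

For one donor:recipient pair, candidate peptides are all 15-mer windows of
the donor's HLA proteins at A, B, C, DRB1 and DQB1 (both haplotypes, ten
alleles with possible repeats), and their 9-mer cores. Because every
protein here is ≥ 15 residues, the set of 9-mer cores of all 15-mers equals
the set of all 9-mer windows; the implementation uses this identity, and
the test suite checks it against a literal 15-mer → core → presenter
enumeration. A core is a T-cell molecular mismatch (TcEMM) when it is
absent from the recipient's self-repertoire and presented by ≥ 1 recipient
DRB1 allele.

Design choices where the procedure was genuinely open:

- **Self-repertoire is not binding-filtered**: every 9-mer window of every
  recipient HLA protein at the five loci counts as self, whether or not
  the recipient's DRB1 would present it. The alternative reading (subtract
  only *presented* recipient cores) is available via
  `self_repertoire_binding_filtered=True`.
- **Population identity of a TcEMM is the 9-mer string alone**, not the
  (core, presenter) pair; two pairs share a TcEMM when they share the
  core, even with different DRB1.
- **Score**: default is the number of distinct presented non-self cores
  (`distinct_core`); `core_presenter` counts (core × presenting allele)
  combinations instead. Under the default, the sum of per-pair scores
  equals the number of nonzero entries of the binary matrix — a tested
  invariant.
- A core found in both a class I and a class II donor protein carries both
  origin labels and is counted once.
- Coordinates are 0-based half-open internally; reports are 1-based.

## Presentation model

Rather than depending on a trained MHC class II predictor, each DRB1
allele receives a 9×20 position-weight matrix with i.i.d. standard-normal
entries drawn deterministically from (allele name, model seed); a core's
score is the sum of its nine positional weights, and the allele threshold
is the empirical (1 − q_bind) quantile of scores over 100,000 seeded
random cores, so a fraction **q_bind** (default 0.2) of random cores is
presented per allele (the Monte-Carlo calibration is tested to ±0.01).
Keying weights by allele *name* rather than sequence means registry-version
diffs isolate sequence changes, the way an external predictor's per-allele
models persist across database releases. q_bind = 0 / 1 are admitted as
degenerate nothing/everything-presented settings for testing. This model
preserves the combinatorial structure of the derivation (set subtraction,
presenter dependence, monotonicity in q_bind) but has no biochemical
content: absolute mismatch counts are not comparable to predictions made
with trained binding models.

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes, at
desk scale:

- **Genotypes.** A pool of distinct five-locus haplotypes (default 12)
  with Dirichlet(1) frequencies; each individual is two independent
  haplotype draws, donors and recipients independent. Haplotype sampling
  induces linkage disequilibrium and hence correlated mismatch columns —
  with so few haplotypes the LD is much stronger than in real populations,
  which inflates the fraction of mismatches appearing in co-expression
  profiles relative to registry cohorts. Registries are synthetic: per
  locus one random base protein (length 180–270) with alleles differing at
  ≤ `n_polymorphic_sites` designated sites.
- **Covariates.** A complete (no missingness) clinical block — recipient
  age/sex/time-on-dialysis/insurance, donor age/sex/type, era, induction,
  calcineurin-inhibitor type, steroid use, cold-ischemia time, weight
  ratio — from plain normal/exponential/multinomial draws with plausible
  desk-scale parameters (not registry margins). Default log-time effects
  are modest (|beta| ≤ 0.3, continuous covariates per SD) so planted
  mismatch signal dominates.
- **Outcomes.** log T\* = mu + x'beta + sigma·W with W standard
  minimum-Gumbel (Weibull AFT), sigma default 0.8. Observed time is
  min(T\*, C_death, C_admin): death acts as an independent exponential
  censoring time (rate 0.025/year — death-censored endpoint, informative
  censoring not modelled) and administrative censoring truncates at 15
  years. The intercept mu is bisected (60 iterations on fixed draws) so
  the realized event fraction matches a target, default 0.17, a typical
  death-censored graft-failure rate over a 15-year window. Times are
  floored at 1e-6 years. Per-core effects are *planted* by adding
  beta_core · x_core to the linear predictor; planted cores must be
  realizable from the pool (validated by a dry-run derivation).

What passing tests show — and don't: calibration (bias, coverage, FDR,
selection sensitivity, permutation validity) is demonstrated under a
correctly specified Weibull AFT data-generating model with complete
covariates and exchangeable censoring. Real registry data involve model
misspecification, informative censoring, imputed genotypes and missing
covariates; nothing here quantifies robustness to those.

## Survival screening

Per-mismatch screening fits one Weibull AFT model per core with support
≥ `min_support` (default 50, "present in ≥ 50 pairs"), adjusted for all
clinical covariates and recipient-DRB1 carrier indicators (one per allele
seen in ≥ min_support recipients, most frequent allele as reference).
The AFT likelihood is maximized by an in-package damped-Newton solver for
right-censored location-scale models (analytic gradient/Hessian on
(beta, log sigma), Cholesky-ridged ascent direction, step-halving; the
linear predictor's standardized residual is capped only above, at z = 100,
to avoid overflow — capping below would fabricate a spurious likelihood
maximum at sigma → 0). The solver is validated against lifelines to ~1e-4
on coefficients; it exists because the screen fits thousands of models per
cohort and is warm-started per core from the covariate-only solution.
Reported log-likelihoods are on the time scale (log f_T = log f_{log T}
− log t), making AICs comparable across software.

HR = exp(−beta/sigma) with a delta-method CI on log HR that propagates the
covariance of (beta, log sigma). Non-converged fits are excluded from the
BH adjustment (m reduced) and logged. Proportional-hazards diagnostics use
the scaled-Schoenfeld trend test on a Cox fit (lifelines); because a Cox
fit per core doubles the screen cost, `ph_test_on` selects none /
significant-only / all (pipeline default: significant). The AIC table
compares Weibull, lognormal, loglogistic and exponential AFT full
likelihoods with the Cox *partial* likelihood; the cross-family use of the
partial likelihood is heuristic and flagged as such in the output. The
cohort-level score model uses log(score + 1) so zero mismatch loads stay
defined. The significant/non-significant frequency split uses q < 0.05.

## Penalized selection and inference

The selection model maximizes the Breslow-tie Cox partial log-likelihood
minus an L1 penalty on mismatch coefficients only; binary mismatch columns
are *not* standardized (equal penalty per mismatch), continuous clinical
covariates are centered/scaled but unpenalized. Coordinate descent is
scikit-survival's Coxnet (glmnet-style; 0/1 penalty factors are rescaled
internally so the effective penalty is lambda × n_features/n_penalized).
The penalty grid is geometric from the data's lambda_max down to
0.01·lambda_max (default 100 points); lambda_min minimizes event-stratified
10-fold cross-validated held-out deviance, −2 × the test fold's own
Breslow partial log-likelihood. Two numerical guards proved necessary and
are regression-tested: an explicit path whose first point exceeds the
fitted data's own lambda_max silently returns empty models (each fold's
path is therefore anchored at its own lambda_max, computed from the
in-package score equations), and the low end of a path can diverge when
p ≫ n (such points are dropped and their deviances treated as missing).
KKT conditions at the solution are verified with the in-package gradient
to 2% of the penalty level, matching the coordinate solver's 1e-7
convergence tolerance.

Post-selection inference defaults to **sample splitting**: CV-Lasso
selection on a random event-stratified half, unpenalized Cox refit (with
all covariates) on the held-out half, Wald 95% CIs; significance = CI
excludes HR 1. Splitting is assumption-light and exactly valid, at the
cost of half-sample selection power; a `naive` full-data refit is offered
and warns that its intervals ignore selection. Fixed-lambda polyhedral
conditional inference is out of scope. A funnel is expected:
posi-significant ⊆ selected, and both typically smaller than the
BH-significant screen set.

## Co-expression profiles

Pearson correlation of the binary columns (the phi coefficient;
constant and low-support columns dropped), unsigned soft adjacency
a = |r|^beta with beta = 4 — chosen because 0.74⁴ ≈ 0.2998 reconciles the
conventional correlation cutoff 0.74 with the adjacency cutoff 0.3 — and
edges where a ≥ 0.3. Profiles are connected components with ≥ 2 members;
profiles plus singletons partition the nodes, and raising the threshold
only refines components (both property-tested). Full WGCNA machinery
(topological overlap, dynamic tree cut, eigengenes) is intentionally not
implemented. Graph export is GraphML with screen/selection status flags as
node attributes.

## Positional composition comparison

Group position-frequency matrices use a Laplace pseudocount of 0.5 (avoids
zero-frequency instabilities in small groups). The per-position statistic
is Jensen–Shannon divergence in bits (symmetric, bounded by 1); the null
is label permutation with the add-one estimator
p = (1 + #{perm ≥ obs}) / (1 + n_perm), BH-adjusted across the nine
positions. JS was chosen over a logo-difference tool's internal statistic
for its boundedness and symmetry; only the test's validity and power are
asserted, not any particular rendering.

## Registry-version sensitivity

Two registry versions are compared by re-deriving every pair under each
(same model seed ⇒ shared PWMs for shared allele names) and reporting the
population-level symmetric difference of cores and the pairs whose sets
changed. Pairs whose alleles are untouched by an edit can never be
affected; the report is label-symmetric under version swap.

## Problem sizes

Tests and the acceptance script run the statistical experiments at sizes
chosen to make each check decisive at desk scale: AFT calibration at
n = 5,000 with 150–200 replicates; FDR control with 100 null mismatches
over 40–50 replicates at n = 500; selection sensitivity with 10 planted
mismatches (HR ≈ 2) among 300 at n = 3,000 over 20 seeds; permutation
validity over 100 simulations. Pipeline demos use cohorts of 150–1,500
pairs. Monte-Carlo acceptance bands are set at ±2.6 binomial standard
errors of the nominal rate.

## Known limitations

- The presentation model is calibrated noise: it supports engine and
  statistics validation, not immunological inference.
- Only recipient DRB1 presents; DRB3/4/5, DQA1 and DP loci are absent both
  as presenters and as peptide sources.
- Alleles are two-field; partial sequences, null alleles and
  serology→allele imputation are out of scope.
- Small haplotype pools exaggerate LD; profile statistics from synthetic
  cohorts are not comparable to registry values.
- Cox AIC vs AFT AIC comparison is heuristic (partial vs full likelihood).
- Split-based inference halves the selection sample; its selected set can
  differ from the full-data Lasso set.
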