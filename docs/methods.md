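# Methods

## The model

`twinace` implements the classical twin design for continuous phenotypes.
A phenotype measured on both members of monozygotic (MZ) and dizygotic
(DZ) twin pairs is decomposed into three latent sources with path
coefficients a, c, e:

- **A** — additive genetic influences, correlated 1 between MZ co-twins
  and 0.5 between DZ co-twins;
- **C** — shared (family) environment, correlated 1 within every pair;
- **E** — non-shared environment, uncorrelated between co-twins; it also
  absorbs measurement error, so e > 0 always.

Each pair is one draw from a bivariate normal with variance
a² + c² + e² and cross-twin covariance k·a² + c², where k is 1 (MZ) or
0.5 (DZ). The standardized components A = a²/(a²+c²+e²) etc. are the
reported variance proportions. The bivariate *correlated-factors* model
extends this to two traits: each trait has its own paths, and the
same-named factors of the two traits correlate rA, rC, rE. The implied
4×4 per-pair covariance (variable order `x₁ y₁ x₂ y₂`) has within-person
cross-trait covariance a₁a₂rA + c₁c₂rC + e₁e₂rE and cross-twin
cross-trait (CTCT) covariance k·a₁a₂rA + c₁c₂rC — no E term, since
non-shared environment does not cross twins. On standardized traits the
phenotypic correlation decomposes as rPh = a₁a₂rA + c₁c₂rC + e₁e₂rE, and
the *bivariate heritability* is the A share of that sum, a₁a₂rA / rPh
(shares can fall outside [0, 1] when components have opposing signs).
All of this algebra lives in one place (`acecov.py`), used by both the
simulator and the likelihoods, so the generating and fitted models cannot
drift apart.

## Estimation

Likelihoods are full-information ML: each pair contributes the marginal
normal density of its observed subvector, so individuals missing one
phenotype still inform the fit. For speed, rows are grouped by
missingness pattern and summarised by sufficient statistics; a -2lnL
evaluation costs a few small Cholesky factorisations regardless of n.
Optimization is quasi-Newton (L-BFGS-B) on an unconstrained
reparameterization — log path coefficients (nonnegativity by
construction), atanh component correlations (PD-respecting, sign
identified), free means (one per trait, equal across twins and zygosity
groups, justified by the saturated-model assumption tests). Starts are
moment-based: Falconer's formulas A ≈ 2(rMZ − rDZ), C ≈ 2rDZ − rMZ
clipped into the parameter space, plus two jittered restarts with fixed
internal seeds, so fits are deterministic. A non-positive-definite
implied covariance is penalised (large finite value) rather than raised,
so optimizers can back out of bad regions. DZ same-sex and opposite-sex
pairs are pooled in all biometric fits (their correlations are equated by
the generating model and, in the study design, empirically similar); the
saturated stage can keep them separate.

Saturated models estimate free means/covariances per zygosity group; the
*constrained* saturated model equates means and variances across twin
order and makes the correlation structure symmetric under swapping
twins — this is where twin and CTCT correlations are read off. Equality
assumption tests form the standard cascade (twin-order means, twin-order
variances, then zygosity means and variances on top of the accepted
order constraints), each a likelihood-ratio test with df equal to the
number of parameters removed.

Model comparison uses the naive chi-square LRT p-value as primary
(matching common practice in this literature), with the 50:50
chi²(0):chi²(1) boundary-mixture p reported alongside for single dropped
variance components: a variance component sits on the boundary of its
space under the null, so the naive test is conservative (type-I error
≈ alpha/2). Model selection — the most parsimonious submodel not
significantly worse than ACE — is reported as a recommendation, never
applied silently.

## Confidence intervals

95% CIs are profile-likelihood based: a bound is the quantity value at
which the constrained -2lnL exceeds the optimum by χ²(0.95, 1) = 3.841,
found by outward bracketing and Brent root-finding (tolerance 1e-4 on the
quantity scale). Component correlations are profiled by fixing the
corresponding parameter; univariate variance proportions by a dedicated
reparameterization (mean, log total variance, mixing of the remaining
components) that reaches the boundary value 0 exactly; derived bivariate
quantities (rPh, covariance shares, per-trait standardized components) by
SLSQP with an equality constraint. A bound that lands on the parameter
boundary (e.g. A's lower bound at 0 on null data) is reported at the
boundary and flagged. If profiling fails, a delta-method (Wald) interval
from a finite-difference Hessian is substituted with a logged warning and
flag. In simulation studies, CI *coverage* is assessed by
likelihood-ratio inversion — one constrained fit at the true value,
covered iff the profile deviance is at most 3.841 — which is equivalent
to locating the endpoints and an order of magnitude cheaper.

## The synthetic cohort

The generator draws pairs directly from the implied per-pair covariance
(mathematically identical to simulating latent A/C/E factors for
multivariate-normal phenotypes, and simpler). Its defaults pin the study
conditions: 658 MZ, 765 same-sex DZ and 708 opposite-sex DZ complete
pairs born 1999–2003; a synaesthesia screening score that is heritable at
a² = 0.46 with the rest non-shared environment; autistic-trait measures
with AE structure a² = 0.44 (total), 0.35 (RRBI-D), 0.47 (SIC) taken
from the constrained-saturated MZ correlations; and cross-trait
correlations rA = 0.26/0.34/0.18, rE = 0.09/0.09/0.02.

Realism layers are composable and optional:

- **Ordinal discretization.** Latent standard-normal scores are cut into
  the 17-level screening scale (0–8 in 0.5 steps) at thresholds
  calibrated once by matching a zero-inflated truncated-geometric
  marginal to the reported mean 0.76 / sd 1.25 (implied skewness 2.24);
  the same calibration routine serves the A-TAC-style scales (total
  0–12, mean 1.91, sd 1.62; RRBI-D 0–4, 0.92/0.88; SIC 0–8, 1.09/1.15).
  Values exactly at a cut point go to the upper level.
- **Covariate effects.** Deterministic linear sex and birth-year shifts
  (defaults 0.15 sd and 0.02 sd/year — modest effects of the size
  registry phenotypes typically show), centred so the grand mean is
  unchanged; they exist to give the residualization step something real
  to remove.
- **Missingness.** Independent per-cell MCAR at a configurable rate
  (default 2%). The models assume ignorable missingness; MNAR mechanisms
  are out of scope.
- **Item responses.** Graded {0, 0.5, 1} item endorsements generated from
  the latent liability with loading 0.74 (calibrated so eight items give
  a Cronbach alpha of ≈0.79 — the instrument's reported internal
  consistency — for a standard-normal liability; a right-skewed observed
  score used as the liability pushes alpha somewhat higher) and
  rare-endorsement cut points, used for the
  internal-consistency descriptive and the
  scoring-sensitivity analysis (both scorings are applied to the *same*
  item data, so the comparison isolates the scoring rule).

What the synthetic data does *not* emulate: genuine item-level response
processes behind the analysed score (the analysis score is the
discretized latent, not the item sum), selective participation,
zygosity misclassification, sex-limitation or assortative mating, and
MNAR missingness. Passing recovery tests therefore show the estimator
chain is correct under its own assumptions — they cannot show those
assumptions hold in any real registry. One consequence worth knowing:
fitting normal-theory ML to the *discretized* score attenuates variance
components and correlations by roughly 15–25% relative to the latent
values (visible in the pipeline report); recovery and coverage checks
therefore run on the continuous phenotypes, while pipeline smoke tests
run the full ordinal chain.

## Preprocessing rules

Scale scores are plain sums of available item codes (no proration): the
17-level support of the screening score only exists under plain
summation. An individual missing more than 20% of a scale's items gets
no score — for an 8-item scale this tolerates exactly one missing item.
The sensitivity scoring collapses the four sequence-colour items into
one derived item by taking the maximum code over the group (preserves
any-endorsement semantics for graded responses; the derived item is
missing only if the whole group is). Scores are log(1+x) transformed,
residualized on sex (two-level indicator) and birth year (linear) over
complete cases by OLS, and the residuals standardized to sd 1 (ddof 1);
constant predictors are dropped with a warning rather than failing.
Skewness is the adjusted Fisher–Pearson estimator; Cronbach's alpha is
computed on complete cases with the Feldt F-distribution CI.

## Numerical choices and problem sizes

Optimizer tolerance is 1e-13 relative on -2lnL (≈1e-8 absolute at the
likelihood magnitudes involved) with up to 1000 iterations; profile
root-finding stops at 1e-4 on the quantity scale. Simulation studies in
the test suite use 200 replicates at n = 2000 pairs for recovery and
coverage (coverage pooled across the generating grid, where its binomial
error is a fraction of the acceptance band), 500 replicates for LRT
calibration, and cohorts of 20 000–60 000 pairs where a single-draw check
needs Monte-Carlo error well inside the stated tolerance. Replicate
loops fit from the moment start only (`n_starts=1`); the jittered
multi-start default guards interactive use on arbitrary data.

## Known limitations

- No ordinal-threshold (liability) ML: ordinal scores are analysed after
  transformation as the study did, with the attenuation noted above.
- No ADE models, no sex-limitation models, no >2-trait models, no
  sibling/parent extensions.
- The constrained-saturated correlation CIs are profile-based; registries
  analysed with other software may print slightly different intervals
  even for identical point estimates.
- At boundary nulls (a² = 0 or c² = 0) the nonnegativity-constrained ML
  estimate is biased upward on the order of half its sampling sd; this is
  intrinsic to the estimator, not a defect of the optimizer.
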