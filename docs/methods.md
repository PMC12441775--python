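# Methods

This note documents the statistical models, the numerical choices and
the synthetic-data assumptions behind `weedpath`, in the order the
pipeline runs them.

## Diversity metrics

Hill diversity is computed as $(\sum_i p_i^a)^{1/(1-a)}$ after
dropping zero-abundance species (this resolves the $0^0$ ambiguity at
$a=0$ and makes richness exactly the count of species present).
Orders within $10^{-9}$ of 1 dispatch to the analytic limit
$\exp(-\sum p_i \ln p_i)$, and an infinite order to $1/\max_i p_i$.
Shannon entropy uses natural logarithms so that $\exp(H')$ equals the
equivalent species richness exactly. The general-power branch is
numerically stable down to $|a-1| = 10^{-6}$ (relative error well
below $10^{-4}$, checked by property tests).

Counts (autumn) and dry biomass (summer) share all formulas through
proportions but are never pooled: $\alpha/\gamma$ partitioning
refuses mixed bases. Pooling across blocks or fields sums raw
quantities before normalising; $\alpha$ is the unweighted mean of
per-field diversities, $\gamma$ the diversity of the pooled
community.

## Treatment frequency index

TFI sums applied/registered dose ratios per field x treatment x
cropping year. Tank-mix partners are separate records, follow-up
treatments ordinary records of the same year, and the registered dose
is taken per application. Doses must be positive; an applied dose
above the registered one is flagged as a warning rather than an error
(it usually indicates a unit mistake, but authorized split
applications can look like this in coarse records). Report-style
percentages round half-away-from-zero to whole percent.

## Exact all-pairs rank comparisons

Within each field the k treatment responses are ranked (mid-ranks on
ties). For a treatment pair, the single-block distribution of the
rank difference is obtained by enumerating all k! rankings; the
n-block null of the rank-sum difference D is its n-fold convolution,
and the two-sided p-value is $P(|D^*| \ge |D|)$. No multiplicity
adjustment is applied. Letters are assigned by insert-and-absorb with
a repair pass, so two treatments share a letter exactly when their
p-value exceeds the significance level (default 0.05); letter order
follows decreasing mean rank.

The exact null assumes tie-free rankings. With ties the module falls
back to a seeded Monte-Carlo permutation test (default $10^5$
resamples, vectorised, add-one estimator) and tags the result
`approximate`.

Because the null is discrete, the attained size at a nominal 5% level
can sit visibly below it: at n = 15 blocks and k = 4 treatments the
attained levels closest to 0.05 are 0.0392 and 0.0554, so rejecting
at $p \le 0.05$ has true size 0.0392. The test is conservative, never
anti-conservative; simulation-based checks of the implementation
therefore compare against the exact attained size.

## Multi-group path model

The system is recursive (TFI never depends on summer diversity), so
the Gaussian likelihood factorises into the two regression equations
and the exogenous bivariate-normal block of (autumn diversity, log
autumn density). Each block is maximised separately:

* equations — an iterated variance-weighted least-squares fixed
  point (closed form per iteration, convergence when successive
  log-likelihoods differ by < 1e-12). With no cross-group
  constraints a single pass is exact, so unconstrained ML equals
  per-group OLS to machine precision.
* exogenous block — saturated per-group moments; when the
  covariance f is constrained equal across groups, BFGS over per-group
  log-variances and the shared covariance, warm-started at the sample
  moments. A vanishing gradient at the warm start counts as
  converged (it occurs whenever the groups share identical exogenous
  moments, which is the design when all plots of a field are surveyed
  together before treatment).

Conventions, chosen once and used throughout:

* Likelihood, residual variances, $R^2$ and standardization use the
  ML (1/n) moment convention. At n = 15 per group the 1/n vs 1/(n-1)
  distinction is visible, so it is stated explicitly.
* Standard errors apply small-sample df corrections on top of the ML
  point estimates: residual variances over n - p for the regression
  information, and for the exogenous path the normal-theory variance
  of the unbiased sample covariance, $(q_{11}q_{22}+q_{12}^2)/(n-1)$.
  Pure observed-information SEs at this n would undercover 95% Wald
  intervals by 5-7 points; with the correction, pooled coverage over
  all paths sits near 92% (checked over 500 simulated trials).
* The reported f estimate is the df-corrected sample covariance (the
  ML version carries an exact (n-1)/n bias); its standardized value
  is computed directly as the Pearson correlation, which is invariant
  to the convention.
* Densities are log-transformed with natural logarithms (configurable
  base; the base rescales the unstandardized b and e only).
* Coefficient p-values are two-sided normal (z) tests.
* A zero-variance predictor (e.g. a constant TFI column from an
  accidentally included untreated group) raises a hard error naming
  the variable and group.

Model selection constrains one path family at a time across groups
(greedy: the candidate with the largest LRT p-value is accepted while
it exceeds `alpha_keep`, default 0.05; ties break by family order
a-f). The LRT is the plain chi-square test, df = G - 1 per family.
Two finite-sample properties are worth knowing. First, at n = 15 per
group the chi-square approximation is anti-conservative (null
rejection ~0.12-0.15 per family instead of 0.05); no Bartlett
correction is applied, matching standard SEM practice. Second, the
greedy search stops as soon as *every* remaining candidate rejects,
and the statistics of families within one equation are correlated, so
even asymptotically a fully-shared truth is recovered in ~80% of
datasets rather than $1-\alpha$; the rest stop one or two families
early. Decision trails are deterministic given the data.

Mediation is reported on the unstandardized scale: direct effect e of
log density on summer diversity, indirect effect b x c through
herbicide intensity, total e + b x c.

## Synthetic trials

The generator encodes the trial design: 15 fields, four treated
groups, four blocks per field, 1 m² of quadrats counted per block in
autumn and 1 m² cut per plot in summer.

**Structural mode** draws one exogenous pair (diversity, log density)
per field — shared by all groups, as the autumn survey precedes
treatment allocation — from a bivariate normal with mean (10, 4.6),
SDs (2.0, 0.9) and covariance 0.972 (correlation 0.54), then applies
the path equations with Gaussian residual SDs (0.35, 2.0). Default
coefficients: a = -0.04, c = -1.8, d = 0.40, e = 1.21 and f common to
all groups; only the density-to-intensity slope b differs (0.433,
0.228, 0.194, 0 for DSSstd, DSSred, AdvLoc, AdvSer), chosen so the
implied mediated effects are approximately -0.78, -0.41, -0.35 and 0
and group TFI means are 1.37, 1.07, 1.40, 1.53. This is the mode for
oracle and recovery tests: the generating coefficients are known.

**Mechanistic mode** builds the same tables from an explicit causal
chain. A 21-species pool (EPPO codes of common winter-wheat weeds,
dominated by *Viola arvensis*, *Matricaria* and *Papaver rhoeas*)
with log-normal field and species effects produces total densities of
roughly 17-662 plants per m² and 6-14 observed species per field
(>= 90% of fields under defaults). Decision rules per group:

* `DSSstd` — target efficacies rise with log density per species
  (base 0.62/0.72/0.80 by competitiveness + 0.05 ln(1+density),
  capped at 0.96); an exact minimal-cost search over plans of up to
  three products (candidate doses are the per-species requirements on
  invented log-logistic curves) returns the dose plan.
* `DSSred` — identical, with targets lowered 3-15 percentage points
  by species. Because the optimization is exact and product costs
  equal, lowering targets can never increase the optimal TFI; the
  reduced variant undercuts the standard one on every field of every
  seed.
* `AdvLoc` — inspects the field, doses the (up to six) species above
  1 plant per m² to a flat 0.95 target with a 1.6x overdose safety
  factor and log-normal dosing noise: intensity reacts to *which*
  species are present but barely to their density.
* `AdvSer` — one fixed broad-spectrum plan regardless of field state.
* `Untreated` — empty plan.

Survival per species multiplies (1 - efficacy) over the applied
products (independent action) plus a 4% escape fraction (spray
shadows, late emergence) with field-level noise; summer biomass is a
Poisson draw of survivors over the harvested area times per-species
unit mass and log-normal noise. Under defaults, treated whole-plot
biomass lands at 6-12% of the untreated control and the standardized
b of the DSS groups exceeds that of both advisor groups by ~0.4-0.5
on average — the qualitative pattern the analysis is designed to
detect. Dose-response parameters, product names and the advisor
caricatures are inventions calibrated to these ranges, not claims
about real products or advisory practice; the mechanistic DSS, being
a clean optimizer without split applications or portfolio frictions,
sits ~0.5 TFI units below the advisors rather than at parity.

All draws flow through one seeded `numpy` generator; identical
configuration and seed give byte-identical outputs.

## Problem sizes in the checks

Simulation-based tests use the trial's own dimensions (15 fields x 4
groups) wherever the property concerns that regime: 5000 null
matrices for the rank-test size, 500 trials for recovery coverage,
100 seeds for stepwise selection, 1000 random communities for the
Hill laws. Asymptotic LRT properties (p-value uniformity, full
sharing under a shared truth) are tested at 100-120 fields per group,
where the chi-square approximation holds.

## Known limitations

* The exact rank test requires complete block x treatment matrices;
  missing cells are an error, not an imputation case.
* The path model handles observed variables only: no latent
  constructs, non-recursive loops, robust/bootstrap SEs or fit
  indices, and no missing-data machinery.
* The mechanistic generator omits spring follow-up treatments, yield
  and economics, weather and the soil seed bank; it is a calibration
  device for the analysis chain, not an agronomic simulator.
* Passing tests on synthetic trials shows the chain recovers the
  structure it assumes (linear paths, Gaussian noise, log-normal
  densities); field data can violate any of these, most plausibly the
  linearity of the density-intensity coupling.
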