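# Methods

This note documents the statistical models, the synthetic-data design, and
the numerical choices behind `sheepmethane`, in the order the pipeline runs
them.

## Data model and editing rules

A record is one PAC measurement: animal, flock, date, chamber run, CH4 and
CO2 (g/d), coincident body weight (kg), and age. Two cohorts are analysed
separately: growing animals (males and nulliparous females measured at
105–600 d) and ewes (lambed at least once, 380–3,850 d, each record tagged
lactating or dry).

The editing rules are pure subsetting operations, each logged per record:

| rule | action |
|---|---|
| CH4 < 4 g/d | record removed |
| CH4 beyond ±3 SD of the cohort mean | removed (single pass, mean/SD computed after the hard threshold) |
| CO2 > 2,500 g/d | record kept for CH4 traits, invalid for CO2-based traits |
| contemporary group (flock × date × run) < 5 distinct animals | group removed, after the emission filters |
| body weight outside 25–80 kg (growing) / 55–100 kg (ewes) | removed |
| DMI farther than 30 d from the methane record, or beyond ±3 SD | not paired / discarded |
| carcass weight outside 15–26 kg, slaughter age outside 100–450 d, slaughter farther than 30 d | carcass not paired; with several methane records in the window, only the closest to slaughter pairs |
| CT scan farther than 3 d, or any CT trait beyond ±3 SD | row dropped |
| growth rate outside 150–350 g/d | blanked |

All "within N d" windows are inclusive at both ends, read as calendar days.
The ±3 SD screens are applied once, not iterated: iterating would remove
further records with no stopping rule stated, and a single pass is the
conventional reading of a one-shot edit. Nearest-date pairing breaks ties
toward the earlier date, which makes the pipeline independent of row order.

## Derived covariates

- Heterosis `1 − Σᵢ sireᵢ·damᵢ` and recombination loss
  `1 − (Σᵢ sireᵢ² + Σᵢ damᵢ²)/2`, from parental breed-fraction vectors over
  {Belclare, Blackface Mountain, Charollais, Cheviot, Lleyn, Suffolk, Texel,
  Vendeen, Other}; unknown breeds pool into Other. An animal's own breed
  fractions are the mid-parent values.
- Metabolic body weight BW^0.75 (kg).
- Average daily gain: the OLS slope of repeated body weights restricted to
  ±120 d around the methane record, at least two weights, converted to g/d.
  Internally a single unit (g/d) is used; intensity denominators convert to
  kg/d at the point of use so that MI_ADG ≈ CH4/0.2 ≈ 70 lands on the scale
  such traits are reported on.

## Ratio traits

Each ratio is the plain quotient of CH4 (or CO2) and one denominator, per
record, absent whenever the denominator is absent, non-positive, or not
defined for the cohort. Intake traits (MY, CO2 yield) use DMI in kg/d: with
CH4 ≈ 14 g/d and DMI ≈ 1.5 kg/d this puts methane yield near 11 g/kg DM,
the scale on which the trait is reported in sheep; a g/d denominator would
shift it three orders of magnitude. MI_KO divides by kill-out expressed as a
proportion (≈0.45); the alternative percent scaling differs only by the
constant 100 and cannot change any correlation or ranking.

## The mixed-model engine

Every residual trait, repeatability, and marginal mean comes from one
engine: a Gaussian linear mixed model with a full-rank fixed design and up
to two crossed random intercepts (contemporary group, animal), estimated by
REML.

**Algorithm.** EM iterations on Henderson's mixed-model equations. At the
current components the MME are solved for the fixed effects and BLUPs; the
updates are `σ²_r ← (û_r'û_r + σ²_e·tr(C^rr))/q_r` and
`σ²_e ← ê'y/(n − p)`. EM is monotone in the restricted likelihood and never
leaves the parameter space, which is why it was chosen over
faster-but-fragile average-information updates at this problem size.

**Cost.** The largest random factor (animal) is absorbed through its
diagonal MME block by a Schur complement; grouping animals by record count
turns the absorbed cross-product into a sum over distinct counts of
precomputed matrices. One iteration then costs a dense solve of dimension
p + q_cg (a few hundred), independent of the number of animals —
milliseconds at the scales used here.

**Boundary handling and convergence.** Variances are floored at 1e-10.
Convergence is declared when the largest relative component change falls
below 1e-10 (default; up to 30,000 iterations). Two accelerations deal with
EM's known slowness near a zero variance, where the EM map's derivative
tends to one: Aitken extrapolation every ten iterations, accepted only if
the restricted likelihood does not decrease, and a snap-to-floor for
components below 1e-8 of the residual variance (a component that small is
scientifically zero and would otherwise crawl forever). The tight tolerance
is deliberate: on balanced one-way designs the REML solution must equal the
ANOVA estimators `σ̂²_e = MSW`, `σ̂²_a = (MSB − MSW)/k` to 1e-8, and the test
suite holds the engine to that, as well as to a brute-force dense
restricted-likelihood optimizer on all small instances and to statsmodels
and lme4 on single and crossed designs.

**Identifiability guards.** A rank-deficient fixed design raises an error
naming the aliased columns (QR with column pivoting). A random factor with
one record per level is rejected — its variance is confounded with the
residual and EM would wander along the likelihood ridge. Fits that fail to
converge are flagged and refuse downstream use.

**Marginal means** hold continuous covariates at their sample means,
other factors at their reference levels, and random effects at their
population average of zero; pairwise level differences use Wald z tests.
Normal rather than t reference distributions are used because no degrees-of-
freedom approximation is defensible across the range of designs the engine
accepts and the intended datasets are large.

## Residual methane traits

Growing animals: RMT_BW, RMT_MBW, RMT_DMI, RMT_MBW+DMI, RMT_ADG, RMT_CW,
RMT_MBW+ADG. Ewes: RMT_BW, RMT_MBW, RMT_DMI, RMT_MBW+DMI. Fixed effects are
the cohort's systematic effects — growing: sex, birth and rearing litter
size (1/2/≥3), age in months (4–19) as a categorical factor, recombination
and heterosis as covariates, and breed proportions for Belclare, Blackface
Mountain, Charollais, Cheviot, Lleyn, Texel and Other with Suffolk as the
reference; ewes: age in years (1–≥7), lactation status, litter sizes, the
same crossbreeding covariates, and breeds with Vendeen replacing Blackface
Mountain — plus the trait's production term(s). Contemporary group and
animal are random. Age classes are categorical because only heterosis and
recombination are described as covariates in this modelling tradition;
breed proportions are continuous.

**Residual definition.** The default trait value is the conditional
residual `y − Xβ̂ − û_CG − û_animal`. With an intercept in the model the
first mixed-model equation forces these residuals to sum to exactly zero,
and `X'ê = 0` makes the trait exactly uncorrelated with every model
covariate at the record level — the 0.00 means and 0.00 covariate
correlations in the outputs are properties of the construction, not
empirical accidents. The alternative reading, in which the permanent animal
effect is part of the animal's methane identity, is available as
`mode="keep_animal"` (`y − Xβ̂ − û_CG`); it is the right object when the
goal is to rank animals on their stable deviation, but it is centred only
approximately on unbalanced data, so the conditional residual is the
default reported trait. Records missing a production term are excluded from
that trait only, which is why per-trait record counts differ.

## Repeatability

`R = σ²_A/(σ²_A + σ²_e)` from a model with animal and (by default)
contemporary-group random intercepts; the group variance is excluded from
the denominator because repeatability is meant to measure the permanent
between-animal fraction of the variance not explained by the measurement
environment. The CG term can be dropped entirely
(`contemporary_group=None`) for the animal-plus-residual-only variant.
Standard errors come from a parametric bootstrap (simulate from the fitted
model, refit; 200 replicates by default, seeded), which is exact-model
rather than asymptotic; pass 0 replicates to skip it.

## Correlations and selection ranking

Correlations are record-level Pearson coefficients over pairwise-complete
records (repeated records per animal included, since trait availability is
record-wise), with `SE = sqrt((1 − r²)/(n − 2))`.

The selection comparison uses four metrics: CH4, MI_MBW, MY, RMT_MBW+DMI.
Only animals complete for all four enter; each animal is represented by its
lowest (most efficient) record per metric; the best `round(0.25·n)` (half
away from zero) are selected, ties broken by ascending animal id. Group
means of intake, methane, weight, and cohort-specific traits (weaning
weight for growing animals; lambs born/reared for ewes) are computed over
the selected animals' ranking records and compared with Welch t-tests,
Holm-adjusted, annotated as compact letters. The selected groups overlap in
membership, so the letters are descriptive rather than independent-sample
inference — the same caveat applies to any such comparison.

## Synthetic flock generator

The generator emulates the data structure the analysis assumes, with truth
recorded per record so recovery is checkable:

`CH4 = μ + sex + litter + age + heterosis/recombination + breed effects
+ b_MBW·(MBW − MBW̄) + b_DMI·(DMI − DMI̅) + CG + animal + residual`,

with CG ~ N(0, σ²_cg) per flock × date × run, animal ~ N(0, σ²_a), residual
~ N(0, σ²_e), all configurable. Defaults describe the two cohorts at the
scale of chamber-measured sheep populations: growing animals at mean
≈14 g/d, phenotypic SD ≈5 g/d, variance split (cg, animal, residual) =
(7.5, 4.94, 14.06) so the animal fraction of non-group variance is 0.26;
ewes at mean ≈21 g/d, SD ≈8, split (17, 15, 29) giving 0.34. Sex effect
+0.8 g/d for males (growing), within the 0.55–1.36 g/d band such contrasts
occupy; breed slopes of order −2 g/d per unit proportion; DMI means 1.53 /
1.86 kg/d with CV ≈39%, linked to CH4 at 2 g per kg DM so that methane
yield is genuinely intake-driven. Body weights are generated inside the
cohort windows by construction; growing animals grow along a per-animal
line (≈250 ± 55 g/d) sampled by the repeated-weight table, so the ADG band
filter is exercised. About 28% of animals carry repeated records. Breed
composition is sampled as purebreds (50%), F1 crosses (25%) and
three-breed Dirichlet composites (25%), spreading heterosis and
recombination across (0, 1). Chamber runs hold 12 animals; the remainder
run of each session is partially filled, exercising the ≥5-animal rule.
Production tables (intake, weights, slaughter, CT, maternal) attach to
subsets of animals with deliberate out-of-window and outlier rows so every
editing rule fires.

`repeatability_config(cohort, R)` produces data whose true animal-variance
fraction is exactly R: it sets `σ²_a = R·V`, `σ²_e = (1−R)·V` on the
cohort's default total and switches off every systematic effect and trait
link. The switch-off is what the configuration's contract requires: sex,
breed composition and the body-weight link are constants within animal, so
leaving them on silently adds between-animal variance and the realised
fraction is no longer R (with defaults on it drifts to ≈0.30/0.37). The
repeatability recovery runs estimate on the raw simulated records —
parameter recovery isolates the generator-plus-estimator loop; the editing
rules are exercised separately.

**What the generator does not emulate**: pedigree relationships and genetic
covariance between relatives; PAC gas kinetics and diurnal/fasting effects;
seasonal pasture quality; correlated measurement error within a chamber
run beyond the shared CG effect; lactation as a longitudinal state (a
record's status is drawn independently at the configured rate). Passing
tests therefore demonstrate that the algorithms are correct under the
assumed variance structure, not that real PAC data satisfy that structure.

## Problem sizes and reproducibility

The shipped checks run at desk scale: residual-trait datasets of ~1,500
animals (≈2,300 records after editing) per cohort, and repeatability
recovery over 10 replicates of 1,000 animals × 2 records. At these sizes a
Monte-Carlo mean of 10 REML estimates has a standard error near 0.013, which
is the right order for the ±0.02 band the recovery check uses. A single
pseudo-random stream with an explicit seed drives each simulated dataset;
identical configuration and seed reproduce every table byte for byte.

## Known limitations

- The engine fits independent random intercepts only — no correlated or
  nested structures, no genetic relationship matrices, and therefore no
  heritability; repeatability is the ceiling of what the repeated-record
  design identifies.
- EM-REML near a likelihood ridge (very few repeated animals) converges
  slowly even with acceleration; the identifiability guard rejects the
  fully-confounded case, but weakly-identified fits can take tens of
  thousands of (cheap) iterations.
- Wald/normal inference ignores uncertainty in the variance components;
  at a few hundred records per fit the p-values are approximate.
- The ±3 SD screens assume roughly symmetric trait distributions; for a
  strongly skewed trait a quantile screen would behave differently.
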