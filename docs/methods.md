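# Methods

`hircus` estimates genetic parameters for growth, conformation and survival
of goat kids (*Capra hircus*) raised in smallholder village herds, in the
setting of community-based phenotypic recording: shallow two-generation
pedigrees (ear-tagged kids with identified founder sires and dams), repeated
body measurements at birth, 3, 6, 9 and 12 months, and survival to one year
with right censoring. This note describes the models, the samplers, the
synthetic-herd generator, and the design decisions a user should know about.

## Growth model

Body weight (BW, kg) is analysed jointly with one conformation trait —
chest girth (CG), body length (BL) or height at withers (HW), all cm — in a
bivariate repeatability–maternal animal model:

```
y_i = X_i b_i + Z_a a_i + Z_m m_i + Z_p p_i + Z_c c_i + e_i     (i = 1, 2)
```

* `a ~ N(0, A ⊗ G0)` — additive genetic effects over the pedigree, with `A`
  the additive relationship matrix (built dense by the tabular method;
  diagonal `1 + F`);
* `m ~ N(0, I ⊗ M0)` — maternal effects, i.i.d. per dam (deliberately not
  pedigree-linked);
* `p ~ N(0, I ⊗ P0)` — permanent environmental effects per recorded animal,
  tying its repeated records together;
* `c ~ N(0, I ⊗ C0)` — common environmental effects per herd (village
  flock);
* `e ~ N(0, I ⊗ R0)` — record-level residuals, with a full 2×2 `R0`
  (a flag-free design choice; the residual cross-trait covariance is
  estimated, since conformation traits are measured on the same visit).

Fixed effects are the full cross-classified cell means of age class (5) ×
sex (2) × parity (3) × birth type (2), empty cells dropped. The full
cell-means coding sidesteps choosing which interaction orders to include
and keeps the fixed-effect update conjugate under a flat prior. Age thereby
plays both of its roles: age class in the mean structure and the
repeated-records axis through `p`.

Records missing the second trait are masked and conditionally imputed
inside the Gibbs scan (never dropped); rows missing both traits are
dropped. Later-age record loss driven by death or field attrition is
ignorable for this likelihood as long as birth records are present, because
the generator's (and plausibly the field's) record-loss mechanism depends
on the data only through observed birth weight.

Derived parameters are computed sample-wise and summarised afterwards:
`σ²_ph = σ²_a + σ²_m + σ²_p + σ²_c + σ²_e`, `h² = σ²_a/σ²_ph`,
`r = (σ²_a + σ²_p)/σ²_ph`, `r_g = g12/√(g11·g22)`.

## Survival model

Survival time ST (days, censored at a 360-day horizon) follows an
accelerated-failure-time animal model

```
log(ST) = X b + Z_a a + Z_m m + Z_c c + e
```

with `X` an intercept plus the kid's birth weight, additive/maternal terms
as above, `c` the herd × year × season cross-classification, and Gaussian
residuals on the log scale (log-normal AFT). Censored log-times are
data-augmented from their truncated-normal full conditional above
`log(horizon)` at every scan; zero-day deaths are floored to half a day
before the log. Heritability is `h² = σ²_a/(σ²_a + σ²_m + σ²_c + σ²_e)`.

The Gaussian residual family is what gives the variance-ratio heritability
its meaning; an exponential residual family (`T ~ Exp(exp(η))`, constant
hazard given the linear predictor) is available behind
`--error-family exponential`, fitted by random-walk Metropolis location
updates with conjugate variance draws, and reports no residual variance.

Because the fitted fixed part contains only birth weight, the generator's
twin survival penalty is partially absorbed by the birth-weight slope
(twins are lighter and die more); the reported slope is therefore a
marginal, partially confounded effect, as it would be on field data with
this model.

## Sampling: why the covariances are drawn from collapsed conditionals

At herd-book scale the split of phenotypic covariance into additive,
maternal, permanent and common components is only weakly identified: with
tens of sires nested within a handful of herds, herd-level variance is
hard to separate from sire variance, dam-level variance from maternal
variance, and kid-level variance from Mendelian-sampling variance. The
joint posterior of `(G0, M0, P0, C0)` has a long, nearly likelihood-flat
ridge. Conventional animal-model Gibbs sampling — per-level effect updates
plus inverse-Wishart draws conditional on the effect vectors — is valid but
practically non-ergodic on this ridge: once one term's effect vector
absorbs another term's structure, the conditional covariance draws lock it
in, and the chain reports a spuriously narrow posterior at one corner of
the ridge.

`hircus` therefore samples the covariance matrices from *partially
collapsed* conditionals:

* **Closed two-generation herds** (recorded kids whose parents are
  unrecorded founders, with each kid, sire and dam confined to one herd —
  the study's structure, and what the generator produces): the collapsed
  density of `(G0, M0, P0, C0)` given the fixed cells and `R0` is computed
  exactly per herd block. Kid record means are
  `N(c + 0.5a_sire + (0.5a_dam + m), R0/n_k + 0.5G0 + P0)`; dam composites
  are integrated per family, then the herd intercept and sire halves
  through a small set of normal equations (dimension `2(1 + S_h)` per
  herd). A random-walk Metropolis sweep (default 16 proposals per scan on
  log-variance / Fisher-z coordinates) updates all four matrices jointly,
  after which every random effect is redrawn exactly from its Gaussian
  conditional. This moves the sampler *along* the ridge, so the posterior
  honestly reflects the weak identification (wide, heavy-tailed intervals
  for the herd term with 8 herds) instead of collapsing.
* **General pedigrees** (fallback, selected automatically): per-level
  Gibbs updates with two repairs — each animal's additive and permanent
  effects are one joint 4-dimensional block (they share incidence rows),
  and `(G0, P0)` are drawn by Metropolis from their collapsed conditional
  given `u = a + p` rotated into the eigenbasis of `A`, where the blocks of
  `u` are independent with covariance `λ_i G0 + P0`. Maternal and common
  terms keep conjugate draws, so on deep pedigrees with strong
  dam-additive confounding the maternal variance can still mix slowly;
  this is a documented limitation shared with conventional samplers.
* The survival sampler applies the same eigenbasis collapse to
  `(σ²_a, σ²_e)`, which are separated only by the pedigree when every
  animal has a single survival record.

The `collapse` argument of `gibbs_chain` (`auto`, `block`, `eigen`) exposes
the choice; `auto` picks the herd-block scheme whenever the structure
allows it.

Chain defaults mirror the full estimation protocol (100,000 iterations,
10,000 burn-in, thinning 10). The calibration experiments and the test
suite run scaled-down chains (20,000/2,000/10 for growth,
6,000/1,000/5 for survival) on scaled-down cohorts (400 and 1,000 kids);
these sizes were chosen so a complete 20-replicate coverage experiment runs
in a few minutes on one core while leaving the per-replicate Monte Carlo
error well below the width of the posteriors being checked.

## Priors

The default prior on every (co)variance matrix is flat (improper), encoded
as inverse-Wishart with `df = -(p+1)` and zero scale, the conventional
choice in animal-model Gibbs sampling. This is a deliberate and, in this
model class, consequential choice: a seemingly innocuous proper
inverse-Wishart such as `IW(df = 4, scale = 0.1·I)` has its mode near
`0.014·I` and contributes tens of log-density units in favour of
near-zero maternal/permanent/common matrices — on the weakly identified
ridge described above, such a prior (not the data) decides the variance
partition and pins the posterior at the corner where the additive term has
absorbed everything. Empirical HPD coverage of the true components is then
close to zero. With the flat prior, coverage in the recovery experiments is
at the nominal level for every component. Proper priors remain fully
supported per term (`PriorSpec`, `SurvivalPriorSpec`, YAML-overridable);
the flat prior needs enough levels per term to give a proper posterior
(more than `p + 1`; with only a handful of levels, e.g. 8 herds, expect a
heavy upper tail — that is the honest posterior).

Fixed effects always carry flat priors.

## Synthetic-herd generator

The generator is the analysis model run forwards, parameterised by the
published posterior means for Burundian indigenous goat kids
(`hircus.reference`), so that simulation-based calibration is exact:

* **Structure**: 106 sires and 645 dams in 8 village herds (round-robin
  assignment; herds split evenly between the two provinces), litters on a
  dam × year grid over 2016–2019. The litter count is `n_kids/(1 + f)`
  (`f` = twin fraction 0.4, so mean litter size ≈ 1.4); every dam gets one
  guaranteed litter, the number of twin litters is fixed so the kid count
  is exactly 1538, and sires serve within their herd. Parity is the dam's
  litter order capped at 3.
* **Growth traits**: four-trait Gaussian model with component covariances
  built from the per-trait variances, the published additive correlations
  of BW with CG/BL/HW (0.79/0.65/0.74) and single-factor cross-trait
  structure elsewhere (environmental correlations 0.90/0.88/0.84, chosen
  so the pooled phenotypic correlations reproduce the published ordering
  CG > BL > HW). Age-class means for BW are 2.1/6.4/9.0/11.4/13.6 kg;
  conformation means are plausible values for small East African goats.
  Sex (+0.58 kg male–female) and birth type (−1.0 kg twin–single)
  contrasts use population-mean-preserving weighted effect coding, so
  cohort age means equal the configured values in expectation.
* **Survival**: log-normal AFT with variance components 0.05/0.05/1.78/0.05
  (additive/maternal/herd-year-season/residual), birth-weight slope 0.1
  log-days per kg, and intercept 6.73 / twin effect −0.63 calibrated
  analytically so expected one-year mortality is 31.6% with twin and
  single strata at ≈39% and ≈21% (the published strata, 42% and 24.2%,
  are mutually inconsistent with the published overall rate at litter size
  1.4; the generator preserves the overall rate and the direction and
  rough size of the gap). Survival days are `floor(exp(log ST))`,
  censored at 360.
* **Record presence**: a kid is measured at an age class if it is alive
  then (birth is always measured) and passes an independent Bernoulli
  retention draw; the default retention probabilities
  (1, 0.893, 0.776, 0.681, 0.670) were derived analytically so the
  expected record counts reproduce 1538/1270/992/787/705. All kids carry a
  survival outcome.
* Growth and survival random effects are drawn independently — the two
  analysis models are not genetically linked, which also makes the record
  loss ignorable for growth inference.

What the generator does **not** emulate: age-heteroscedastic variances
(the repeatability model is homoscedastic, so simulated birth weights have
the pooled standard deviation ≈1.8 kg rather than the field's 0.5 kg, and
a small fraction of simulated birth weights is non-positive — they are
kept, because truncation would break the exact correspondence between
generator and model), measurement error spikes, recording mistakes in
pedigrees, genetic links between growth and survival, seasonal birth
pulses, and province-specific litter sizes. Passing recovery tests
therefore certify the inference machinery under the model's own
assumptions, not robustness to field-data pathologies.

## Numerical choices and degenerate inputs

* All 2×2 covariance updates are done in closed form; Metropolis moves use
  log-variance and `atanh`-correlation coordinates with the exact Jacobian.
* `A` is built dense (quadratic memory; ~2,300 animals is trivial) and
  inverted or eigendecomposed once per fit.
* Chains are bit-reproducible for a given seed (a single compiled RNG
  stream); the command-line layer expands one seed into per-stage
  substreams by fixed offsets.
* Zero-row designs sample from the prior (used by the prior-predictive
  test); an all-censored survival data set and an empty record set are
  rejected with errors.
* HPD intervals are the shortest contiguous window containing
  `ceil(prob·n)` sorted samples; effective sample size uses the initial
  positive sequence of autocorrelations; the Geweke screen compares the
  first 10% against the last 50% of the chain.
* Pedigree identifiers are exact strings after whitespace trimming;
  unknown parents ("0", empty, "NA") are unrelated non-inbred founders;
  an unknown single parent contributes its founder share to the
  Mendelian-sampling variance (`0.75 − 0.25·F_known`).

## Known limitations

* No direct–maternal genetic covariance, no dominance or epistasis (as in
  the source analysis).
* The maternal term of the general-pedigree (non-block) sampler can mix
  slowly when dams' breeding values and maternal effects are strongly
  confounded.
* The survival slope is reported on the log-time scale; a days-per-kg
  marginal effect depends on the censoring pattern and is not a model
  parameter.
* With few common-environment levels the flat prior yields very heavy
  upper tails for that component; users wanting regularisation should
  supply a proper prior deliberately.
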