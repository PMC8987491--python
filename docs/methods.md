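# Methods

## Models

### Guild-level prey-mass model

For prey item *i* of predator *j*,

```
Y_i = β₀ + β₁ M_j + β₂,T T_j + β₃,T (M_j × T_j) + α_genus[j] + α_id[j] + ε_i
```

with `Y_i` the log₁₀ prey wet mass (g), `M_j` the log₁₀ predator wet mass
(g), `T_j` the predator's trophic guild (treatment-coded, alphabetically
first guild as reference), `α_genus ~ N(0, σ²_genus)` and
`α_id ~ N(0, σ²_id)` random intercepts for genus and for individual fish
nested in genus, and `Var(ε_i) = σ²/w_i` with biomass weights `w_i`.
Estimation is REML.  Per-guild *total slopes* `β₁ + β₃,T` are the quantity
of scientific interest and are invariant to the reference-guild choice;
they are reported with Wald CIs from the fixed-effect covariance.

**Biomass weights.** Within a predator, weights are proportional to prey
wet mass, so a prey item's influence tracks its contribution to the
predator's energy intake.  The default scheme normalizes weights to sum to
one within each predator.  The raw-gram alternative is available, but
under the `σ²/wᵢ` convention raw weights make observations from
large-prey guilds (piscivore prey, ~10²–10³ g) millions of times more
informative than planktivore prey (~10⁻⁴ g), which destroys the precision
of the small-prey guild contrasts in a joint fit; per-predator
normalization keeps the within-gut biomass weighting while weighting
predators equally.

**PPMR.** For a predator of mass *m* in guild *T*,
`PPMR = m / 10^ŷ(m, T)`, oriented so that typical reef-fish values are
≫ 1.  Predictions can include genus and individual BLUPs (`full`), genus
only (`genus_only`), or fixed effects only (`fixed_only`; the default at
community scale, where only guild and body mass are observed).  The
back-transform is the naive `10^ŷ`; an optional lognormal (half-variance)
correction exists but is off by default.

**R².** Marginal R² = fixed-effect variance over (fixed + random +
residual); conditional R² adds the random-intercept variances to the
numerator (the Nakagawa–Schielzeth decomposition for Gaussian responses).

### Community PPMR

Surveyed fish are consolidated from nine fine guilds into four (algal
farmers, browsing/scraping herbivores and excavators → herbivore; benthic
invertivores, omnivores, corallivores → invertivore; higher carnivores →
piscivore; planktivores → planktivore); cleaners and non-fish predators
(marine mammals, reptiles, birds) are excluded with an audit trail.  Body
mass comes from the length size class (class midpoint, cm) through the
species' length–weight coefficients.  The transect-level community PPMR is

```
cPPMR = Σ_groups PPMR(guild, mass) · N / Σ_groups N
```

the abundance-weighted *arithmetic* mean over guild × size-class groups —
exactly equal to the mean over an exploded per-individual list, because
PPMR depends only on guild and mass.  A geometric-mean variant is exposed
for comparison (`transect_cppmr(..., mean="geometric")`); the arithmetic
mean is the definition used downstream.  Extreme communities can be
trimmed at the
1st/99th empirical percentiles (linear-interpolation quantiles; rows
strictly outside are dropped).

### Size spectra and theory

Individuals are binned into half-open log₂ doubling mass bins
`[2^k, 2^(k+1))` g; empty bins are dropped (log of zero is undefined —
zero-inflation smoothing was considered and rejected as it biases slopes
toward zero), and the per-transect abundance spectrum slope (*b* − 1) is
the OLS slope of log₁₀ abundance on log₁₀ geometric bin-midpoint mass.
The smallest size classes are included by default; a `min_mass_g` option
reproduces the common >32 g truncation.  The energetic-equivalence
relation `b = 0.25 + log(TE)/log(cPPMR)` is implemented with its exact
algebraic inversions for *TE* and *cPPMR*, with domain checks
(*TE* ∈ (0, 1], *cPPMR* > 1; inversion requires *b* < 0.25).

### Cross-transect slope model

`slope ~ log10(cPPMR) * SST + (1 | Year/Site)`: fixed effects for log₁₀
cPPMR, mean sea-surface temperature (°C) and their interaction; random
intercepts for year and for site within year.  REML for reported fits;
model comparisons (drop-one interaction LRT/ΔAIC, the four-way predictor
comparison) refit under ML, since REML likelihoods are not comparable
across fixed-effect structures.  CIs are Wald-type; ICC is
`(τ_site:year + τ_year) / (τ_site:year + τ_year + σ²)`.  Year variances
estimated at the zero boundary are tolerated and flagged singular.

## The mixed-model engine

`reefppmr._mixed.fit_mixed` fits weighted random-intercept models by
profiled REML/ML.  The marginal covariance is `σ²·V₀(θ)` with
`V₀ = diag(1/w) + Σ_k θ_k Z_k Z_kᵀ` and `θ_k = σ_k²/σ²`; all
per-iteration algebra goes through the Woodbury identity on the q × q
matrix `M = I + S (ZᵀWZ) S` (q = total random-effect levels), so cost is
O(q³) per evaluation independent of n.  θ is optimized by L-BFGS-B with
box constraint θ ≥ 0 (boundary estimates allowed), convergence tolerance
1e-8, maximum 500 iterations.  Weights are internally normalized to mean
one (a constant factor is absorbed by σ²; the reported σ² is rescaled to
the caller's weight convention, matching lme4's `weights=` semantics).
Data lying exactly on the fixed-effect plane make the profiled criterion
degenerate (log of a zero residual sum of squares); this is detected and
the exact generalized-least-squares solution is returned with zero
variance components, flagged singular.  The engine reproduces statsmodels
`MixedLM` (unweighted) and R `lme4` (weighted) estimates on a shared
fixture to ≤ 1e-3 relative; those cross-checks are part of the test suite.

AIC counts fixed effects + variance components + the residual variance.
p-values are normal-approximation Wald tests (a deliberate simplification;
no small-sample df correction).

## Synthetic generators

The generators draw from the same hierarchical structures the models
assume, so recovery tests are well-posed.

**Gut contents** (`GutGenConfig`): 80 predators per guild by default,
log-uniform masses within per-guild ranges spanning 1.97–7878 g; 8 genera
per guild; prey counts from a zero-truncated negative binomial (mean 10,
dispersion 5, capped at 200 — field prey counts are overdispersed and a
sampled gut has at least one measurable item); prey log₁₀ mass =
guild intercept + guild slope × log₁₀ predator mass + genus effect (SD
0.3) + individual effect (SD 0.3) + residual (SD 0.5).  Default guild
slopes are 2.22 (piscivore), 0.68 (invertivore), 0.47 (planktivore), 0.11
(herbivore); intercepts are free parameters set so fixed-effect PPMRs at
mid-range guild masses have realistic magnitudes (piscivores ~10³, the
plankton- and algae-associated guilds ~10⁴–10⁵).  Prey lengths are
back-computed through an invertible per-taxon allometry and then
*censored*: items at or below the guild's minimum measurable length
(0.5 mm planktivores, 1 mm others) are dropped after drawing, mimicking
the field measurement cutoff.  This truncation thins the small-prey tail
and is the main intended realism limit: recovery under censoring is part
of what the tests measure.

**Surveys** (`SurveyGenConfig`): 1,500 transects over 200 sites × 5 years
by default, each transect assigned a uniformly random site and year;
site-level SST uniform on 14–28 °C; per-transect log₁₀ cPPMR ~
N(3.9, 0.4).  The transect's spectrum slope is the linear predictor with
default coefficients (1.67, −0.40, −0.13, 0.03) plus year (variance 0.00),
site-within-year (0.02) and residual (0.03) noise.  Each transect also
emits a guild × size-class abundance table (12 mass-doubling length
classes, Poisson counts around expectations proportional to
mass^slope) so the full pipeline can run end to end; the drawn cPPMR and
slope columns are the authoritative truths for recovery.

A single global seed fans out to per-stage child generators
(`numpy.random.SeedSequence.spawn`), so stages can be regenerated
independently and CSV exports are byte-reproducible.

**What the generators do not emulate:** spatial autocorrelation among
sites, species-abundance-distribution realism beyond guild/size
composition, digestion-dependent prey detectability, ontogenetic diet
shifts within species, or any coupling between a transect's community
composition and its drawn cPPMR.  Passing recovery tests therefore show
that the estimators are correct and calibrated *under the assumed
hierarchical structure with measurement censoring* — not that the models
are well-specified for any particular field dataset.

## Numerical and design choices

- Strict inequalities at the measurement thresholds (a 1.0 mm invertivore
  prey is dropped), consistently in the generator and the filter, so the
  filter is idempotent on generated data.
- Dry-weight allometries: wet = factor × dry, the factor carried as data
  per taxon; a placeholder of 5.0 (dry mass ≈ 20% of wet) is used with a
  warning when a dry rule arrives without one.
- Class midpoints for survey size classes; bin-edge conventions are data.
- Percentile trimming uses linear-interpolation quantiles; on n distinct
  values this removes ~2% (exactly 2 of 100).
- Reference guild is alphabetical (herbivore); only total slopes are
  reported downstream, so the choice is invisible.
- Random-effect uncertainty is not propagated into community-level cPPMR
  estimates; community predictions are fixed-effects-only.
- Recovery-protocol sizes: 50 seeded replicates for the guild-slope study
  and 20 for the transect-slope study in the test suite; the reproduction
  script uses 20 for both.  At these sizes the Monte-Carlo error of the
  reported means is an order of magnitude below the assessment tolerances.

## Known limitations

- The engine supports random intercepts only (no random slopes or
  correlated effects) — sufficient for every model in this package.
- Wald inference throughout; profile-likelihood CIs are not implemented.
- cPPMR here is fish-only; invertebrate predators are not assigned PPMRs
  even though invertebrates appear in the size spectra.
- The per-transect OLS spectrum slope ignores cross-transect pooling; a
  hierarchical spectrum fit across transects is deliberately out of scope.
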