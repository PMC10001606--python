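# Methods

## Problem and model

`greyrank` analyses short annual health panels in which a single outcome
series (circulatory-system-disease mortality per 100,000, 2001–2020, by sex)
must be related to a handful of candidate factors (income per capita,
physician density, smoking rate, optionally alcohol-use and
overweight/obesity rates) with far too few observations for conventional
multivariate inference. Grey relational analysis (GRA) addresses this by
scoring the *geometric similarity* of each factor's curve to the outcome's
curve and ranking factors by that score; a small OLS stage with bootstrap
standard errors then sizes the leading association.

### Degrees of grey incidence

Let x₀(k) be the reference (outcome) and xᵢ(k), k = 1…m, a comparison
series. Sums and averages run over the m observations throughout; the
literature sometimes mixes its index symbols, and this package fixes one
convention rather than carrying the ambiguity.

**Deng's degree.** Both series are replaced by their *mean images*
x′(k) = x(k)/x̄ (the only standardization applied; no z-scoring). With
Δᵢ(k) = |x₀′(k) − xᵢ′(k)|, the pointwise grey relational coefficient is

    γᵢ(k) = (min min Δ + ε · max max Δ) / (Δᵢ(k) + ε · max max Δ)

where the double min/max runs over all observations *and all comparison
sequences of the run* (the classical two-level scope; with a single
comparison the scopes coincide). Deng's degree is the mean of the γᵢ(k).
The resolution coefficient ε ∈ (0,1] damps the influence of the maximum
deviation; 0.5, the conventional middle value, is the default. Because the
coefficient is non-decreasing in ε wherever Δᵢ(k) exceeds the global
minimum, so is the degree — a property the test suite asserts.

**Absolute degree.** Both series are reduced to *zero-start images*
X(k) = x(k) − x(1), and each image to its signed area signature
s = Σ_{k=2}^{m−1} X(k) + X(m)/2. The degree is

    (1 + |s₀| + |sᵢ|) / (1 + |s₀| + |sᵢ| + |sᵢ − s₀|).

It is computed on the **raw** sequences, not on mean images. Two
considerations force this choice. First, the construction's defining
examples evaluate on raw zero-start images (two parallel lines have degree
exactly 1). Second, the characteristic empirical fingerprint of the absolute
degree on this kind of panel — a currency-denominated income series pinned
at exactly 0.500 against a per-100k mortality series — only arises when the
sequences keep their units, so that |sᵢ| ≫ |s₀| drives the ratio to ½.
Mean-imaging first would erase that behaviour. The absolute degree is
therefore deliberately *not* scale-invariant.

**Relative degree.** The same area construction applied to *initial-value
images* x(k)/x(1). Scale-free; equals 1 for proportional series (identical
rates of change).

**Composite degrees.** SDGRA = θ·absolute + (1−θ)·relative with θ = 0.5 by
default; SSGRA = (Deng's + absolute)/2. Both identities are maintained
exactly on unrounded values; rounding happens only at the reporting layer.

**Ranking.** Within each model, factors are sorted by descending degree and
ranked 1…n on the unrounded values. Ties are detected *after* rounding to
the reporting precision (3 decimals by default) and share the notation
"r(r+1)" — two factors landing on the same 3-decimal degree in sort
positions 3 and 4 are both reported "3(4)".

**Numerical guards.** If every pooled deviation max max Δ falls below 1e-12
(the mean images live on a unit scale, so anything smaller is roundoff from
the division), all coefficients are defined as 1 — the limiting
perfect-incidence value. Without the guard, an exactly proportional
comparison would yield coefficients that are ratios of floating-point noise.
Zero-mean or zero-initial-value series are rejected as degenerate rather
than silently shifted.

**Lagging.** `lag_align` pairs the outcome at year t with factors at year
t − lag (lag 1 is the robustness convention: this year's mortality explained
by last year's factors). Pairing is by year value, so explicitly permitted
gaps align correctly; gaps are otherwise rejected — interpolating an annual
health panel would fabricate data.

## Regression stage

The outcome (stacked male + female rows, n = 40 at the default 20-year
panel) is regressed on smoking rate and physician density plus a
"female after ban" dummy equal to 1 for female observations from the ban
year (2012, **inclusive**) onward; its coefficient is the excess post-ban
change in female mortality. Three specifications are run: without the
dummy, full, and without smoking.

* **Bootstrap SEs.** Case resampling: whole (year, group) rows drawn with
  replacement, size n, the model refit, SE = sd of the estimates over 1,000
  refits (default). Rank-deficient resamples are redrawn and counted. The
  unit is the row, not the residual, matching the nonparametric
  "resample from the empirical distribution" rationale for small samples.
* **RESET.** Powers 2–4 of the fitted values are added and jointly F-tested
  (statsmodels `linear_reset`), giving numerator df 3 and denominator df
  n − p − 3 — (3, 34) for the 3-parameter and (3, 33) for the 4-parameter
  specification at n = 40. A numerically perfect fit makes the augmented
  regression degenerate; it is then reported as F = 0, p = 1 (no evidence of
  misspecification, which is true by construction).
* **Descriptives.** mean, SE = sd/√n, and a t-based 95% CI (n − 1 df —
  appropriate at these tiny n and matching the wide published intervals).
* Stars at 0.01/0.05/0.1 from normal-approximation bootstrap z-tests.
* **Known limitation:** no HAC/autocorrelation correction is applied even
  though the rows are annual time series; the SEs inherit whatever serial
  dependence the panel carries.

OLS, R² and RESET go through statsmodels; the incidence degrees — the
method this package exists for — are implemented here and are additionally
cross-checked in the test suite against an independent, deliberately
unvectorized loop transcription of the formulas (1,000 random small-integer
cases, agreement to 1e-12).

## Synthetic panels

`simulate.simulate_panel` generates the study-shaped world: 2001–2020,
groups male/female, ban year 2012.

| parameter | default | rationale |
| --- | --- | --- |
| physician density | linear 2.0 → 2.89 per 1k, jitter sd 0.02 | mean ≈ 2.44 per 1k |
| income | 150·e^(0.07·t) thousand MOP | smooth, strictly increasing |
| smoking, male | 33.8%, slope −0.05/yr | flat-high ≈ 33% |
| smoking, female | 2.6%, −0.02/yr pre-ban, −0.16/yr post | ≈ 2% level, roughly halving over the ban era |
| mortality | α + β_phys·physician + β_ban·1[female, t ≥ 2012] + N(0, σ²) | α = 67.9, β_phys = −9, β_ban = −5 |
| noise sd σ | 7.5 | calibrated once (500 replicates) so the full specification's mean R² ≈ 0.28, the fit quality the synthetic world is meant to match |

Sex-specific mortality responds to one shared covariate (physician density)
plus the group-specific ban shift, so with σ = 0 the female-minus-male gap
changes by exactly β_ban across the ban — the construction the regression
tests exploit. A `SyntheticPanel` stores the exact `SyntheticSpec` that
generated it and is regenerable bit-for-bit from it.

`planted_rank_scenario` is the ranking test harness: per group, mortality is
a positive multiple of one chosen factor's series rescaled to the mortality
level and perturbed *multiplicatively*, ε_rel ~ N(0, (σ/α)²) ≈ 11% relative
noise at the defaults. Multiplicative noise keeps the co-movement in
mean-image geometry — the geometry the pointwise degrees measure — so the
planted factor's dominance is a property of the construction, not luck.
With σ = 0 the planted factor is exactly proportional to mortality and its
Deng and relative degrees equal 1.

What the generator does **not** emulate: serial correlation in the mortality
noise, demographic composition effects, measurement error in the survey
variables, or any behavioural response linking smoking to mortality with a
biological lag. Passing tests therefore certify the estimators and the
pipeline plumbing on a well-specified world, not the epidemiological claims
themselves.

### What the simulations show

* Over 500 default panels, OLS recovers β_ban and β_phys with mean bias
  below 10% of the true magnitudes, and mean R² lands in the calibrated
  band.
* The planted factor is ranked 1 by Deng's degree in ≥ 95% of 200 planted
  scenarios (both dominants, both groups). Deng's, SDGRA and SSGRA jointly
  rank it first in ≥ 95% when the dominant factor carries a visible trend
  (female smoking): the area-based degrees are scale-sensitive by design, so
  a near-flat dominant series (male smoking) gives them little signal — an
  honest reflection of how the models disagree on weakly-trending factors in
  the real tables too.
* Intercept-only bootstrap SEs average within 15% of the closed-form σ/√n
  across independent datasets at 2,000 replications (a single n = 40 dataset
  would confound the check with the ~11% sampling noise of its own sd, so
  the calibration is asserted on the average).

## Design choices where the design was open

* **Groups as parallel 1-D sequences**, not a multi-index: the incidence
  operators are strictly one-dimensional, and a "total" population series is
  never synthesized from the sex strata (population totals are not an
  average of per-sex rates); a total group exists only if supplied.
* **Rounding policy:** all cross-stage handoffs use full precision; ranks
  and composite identities are computed unrounded; the reporting layer
  rounds to 3 decimals.
* **Tie convention** is tied to the reporting precision deliberately — ties
  are a display-resolution phenomenon on continuous degrees.
* **Bootstrap redraw bound:** a resample that is rank-deficient (possible
  when the dummy column draws all zeros) is redrawn, up to 100× the
  requested replications, after which the run fails loudly rather than
  silently dropping terms.
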