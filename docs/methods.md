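# Methods

`tempdiv` partitions the within-season diversity of a repeatedly sampled
assemblage into three temporal components and compares disturbed
("fragment") against intact ("reserve") sites on each. This note records
the statistical model behind every stage, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices that an auditor would want to see
written down.

## Data model and filtering

Input is a long-format survey table — one row per (plot, treatment,
year, julian_date, method, species, count, id_level) event — plus a
species-trait table (diet breadth, native flag, genus). Years are
always analysed separately: sampling designs and effort typically
differ between years, and nothing in the package ever pools counts
across years.

Default filters reflect standard practice for passive-trap comparisons
of native assemblages: only bowl-trap records enter the analyses
(netting effort is observer- and vegetation-dependent), non-native
species are excluded via the trait table's `native` flag rather than a
hard-coded list, and specimens not identifiable beyond genus are
dropped. Each filter reports exactly how many rows it removed.
Duplicate (plot, date, species) rows are summed rather than rejected,
since field data commonly split one sample across collection bouts. A
genus-level re-analysis is supported by pivoting with `taxon_level=
"genus"`; diet-breadth metrics are species-level traits and are not
computed for genus matrices.

## Temporal gamma diversity

Per plot, counts are pooled across the year's temporal samples. Four
responses are computed:

- **Rarefied species richness.** Individual-based rarefaction: each of
  `iterations` (default 1000) draws subsamples `depth` individuals
  without replacement (multivariate hypergeometric); richness is
  averaged over draws. `depth` defaults to the lowest pooled plot total
  in the year, so every plot is read at the poorest plot's effort.
- **Rarefied evenness.** Pielou's J = H'/ln S per draw (natural-log
  Shannon; the log base cancels in J), averaged over draws with at
  least two species; draws with S = 1 have no defined evenness and are
  counted rather than imputed, so degenerate depths are visible.
- **Generalist proportion.** Generalist individuals over generalist +
  specialist individuals. Parasitic and unknown-diet taxa are excluded
  from both numerator and denominator: diet breadth is defined for
  pollen-collecting species only.
- **Abundance.** Plot total divided by the number of temporal samples,
  cube-root transformed.

Evenness and generalist proportion are logit-transformed before
testing. Boundary proportions (exactly 0 or 1) are first shrunk by
p' = (p(n-1) + 0.5)/n with n the individuals behind the proportion;
interior values pass through the plain logit untouched, so the
transform is exact wherever it is defined.

Reserve and fragment plots are compared per response with Welch's
two-sample t-test (Satterthwaite df). An optional plot-level covariate
(e.g. host-plant richness) can be added by OLS, with the augmented and
base models compared by AIC on identical rows.

## Temporal alpha diversity

The same four responses are computed per temporal sample, with
rarefaction to `alpha_depth` (default 20) individuals. Samples below
the depth are flagged with an exclusion reason and excluded from the
rarefied responses but retained for abundance, which is analysed
without rarefaction.

Seasonal trends are modelled with a Gaussian random-intercept linear
mixed model per response: fixed effects are treatment, an orthogonal
polynomial in the Julian date (degree 1-3), and their interaction, with
plot identity as the random intercept. Dates are centered and scaled
before the basis is built; the orthonormal basis (QR of the Vandermonde
matrix, signs fixed so each column's leading raw-power coefficient is
positive) makes the fit invariant to the raw parameterisation.

The likelihood is profiled analytically over the fixed effects and the
residual variance, leaving a one-dimensional bounded search over the
variance ratio sigma_b^2/sigma_e^2 (log scale, with the boundary
lambda = 0 checked explicitly). Fits are exact; the test suite
cross-checks fixed effects, variances and the ML log-likelihood against
statsmodels' MixedLM and against a dense multivariate-normal
log-density. Singular fits (zero between-plot variance) are retained
with a warning rather than errored — small designs produce them
routinely — and reduce exactly to OLS.

Model degree is selected on ML AIC, defined as -2 logLik + 2(p + 2)
with p fixed-effect coefficients plus the two variance parameters;
models within delta AIC < 2 of the minimum are treated as equivalent
and the lowest degree wins. ML likelihoods are used for all AIC
comparisons (REML likelihoods are not comparable across fixed-effect
structures); the reported estimates and F tests come from the REML fit.

Per-term F statistics are sequential (type I, terms in entry order:
treatment, date terms, interactions), computed by whitening the model
with the estimated variance ratio and reading effect sums of squares
off a QR decomposition; a marginal (each term adjusted for all others)
option is available. Denominator degrees of freedom follow the
between-within rule: terms constant within a plot (treatment, plot-level
covariates) are tested on n_plots minus the number of plot-level
parameters (intercept included); within-plot terms on N_obs - n_plots
minus the number of within-plot parameters. For a 4+4-plot, 9-sample
design with one observation missing this yields the familiar 1,6 df for
treatment and 1,61 df for the linear date term.

## Temporal beta diversity

All of a year's samples, across every plot jointly, enter one
Bray-Curtis dissimilarity matrix (scipy's pairwise implementation; no
abundance standardisation by default, with Wisconsin and square-root
options off by default). Non-metric multidimensional scaling then seeks
k-dimensional coordinates (default k = 2) minimising Kruskal stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where dhat is the least-squares monotone regression of the
configuration distances on the rank order of the dissimilarities
(pool-adjacent-violators, written in-package; ties handled by Kruskal's
primary approach — tied dissimilarities impose no order among
themselves). The solver starts from the classical-scaling (PCoA)
configuration plus `n_restarts - 1` random starts (default 20 total),
takes Guttman-transform steps safeguarded by a halving line search so
the accepted stress never increases, and stops when the relative stress
change falls below `tol` (default 1e-7, `max_iter` 300). The best
restart is returned, centered and rotated to principal axes with a
deterministic sign convention; stress above 0.20 — the conventional
adequacy limit — triggers a warning, and the stress is always reported
since ordination-space distances are only rank-faithful.

Each plot's beta diversity is its multivariate dispersion: the mean
Euclidean distance, in the full returned k-space, between the plot's
centroid and its constituent samples. Plots with one usable sample are
flagged, not silently dropped. Scores are invariant to rigid motions of
the ordination and are compared between treatments with Welch's t-test.
A PCoA engine (`engine="pcoa"`) is available for sensitivity analysis,
computing dispersion in classical-scaling space instead.

## Synthetic seasonal communities

The generator emulates a bowl-trap bee survey in a Mediterranean-climate
shrubland season and is the package's test bed. Regional pool:
`species_pool_size` (default 200) species with lognormal relative
abundances (sigma 1.6, strongly uneven; a log-series option exists),
activity midpoints uniform over the season window (default days 91-240,
April-August), and lognormal activity-window widths around
`mean_activity_width` (35 days, spread 0.4). Traits: 60% of
pollen-collecting species generalist, 10% parasitic, 5% unknown diet,
2% non-native, and a 2% sliver of never-identifiable taxa to exercise
the filters.

Each plot hosts a random subset of the pool (`plot_occupancy` 0.8) with
lognormally jittered relative abundances (`plot_composition_sd` 0.45)
and a lognormal effort/quality multiplier (`plot_abundance_sd` 0.25);
occupancy thinning is what gives plots genuinely different richness, so
the plot random intercept in the mixed model has something real to
absorb. Counts per (plot, date, species) are Poisson; each species'
Gaussian activity curve is normalised over the plot's survey dates, so
a species' expected season total is its relative abundance times
`individuals_per_sample * n_samples` (default 60 individuals per survey
day, matching a ~58-individuals-per-survey bowl-trap effort) regardless
of how wide its window is. Activity-window changes therefore
redistribute individuals in time without altering season-pooled
composition — the turnover knob is gamma-neutral by construction —
while per-date totals still carry the seasonal abundance profile. A smaller aerial-netting stream (12 per survey) is emitted solely
to exercise the method filter. Survey dates are shared rounds with ±2
days of per-plot jitter.

Fragment effects are injected at the treatment level: a shared random
`richness_deficit_frac` of the pool removed (a regional fragment pool),
relative abundances raised to `evenness_skew` and renormalised,
activity widths multiplied by 1/`turnover_compression` (season-long
activity lowers temporal turnover while the per-sample normalisation
approximately preserves pooled structure), midpoints shifted by
`peak_shift_days`, and generalist abundances multiplied by
`generalist_boost`. All effects default to neutral; under neutral
settings the two treatments are exchangeable by construction. The
injected truth is always written beside the data.

Scenario presets encode four canonical disturbance patterns at a
balanced 8+8-plot design — alpha loss with turnover preserved
(deficit 0.35); turnover loss with alpha roughly level (deficit 0.25 +
compression 0.55); both reduced (0.45 + 0.6); and alpha raised while
turnover falls with expected gamma unchanged (compression 0.5 alone) —
plus two neutral presets reproducing the field sampling designs
(4+4 plots x 9 samples; 7+11 plots x 5 samples).

**What the generator does not emulate:** inter-annual population
dynamics, spatial structure among plots, plant-pollinator interaction
networks, weather-driven catch variation, or overdispersion beyond what
the lognormal plot effects induce (counts are conditionally Poisson; a
negative-binomial option was deliberately deferred). Passing tests
therefore demonstrate that the pipeline recovers known effects under
these idealised conditions, not that any particular field system obeys
them.

## Recovering the injected pool deficit

A naive ratio of observed (or equal-depth rarefied) richness
understates a pool deficit: with a fraction 1-f of the pool absent and
abundances renormalised, every surviving species is commoner and more
detectable. Under that subset model the fragment rarefaction curve
satisfies S_frag(n) = f S_res(n/f) in expectation, so
`estimate_richness_deficit` solves for f self-consistently from the two
treatment-pooled analytic rarefaction curves (root-finding on f in
[0.25, 1], evaluation depth 0.25 of the reserve total). The estimator
is unbiased by construction under the generator's own deficit model and
mildly biased low when other effects (window widening, occupancy)
perturb the pooled composition.

## Problem sizes in repeated-simulation studies

Single analysis runs use the full defaults (1000 rarefaction
iterations, 20 NMDS restarts). Repeated-simulation studies
(`power_study`, the acceptance script) default to 200 iterations and a
single PCoA-started NMDS run with `max_iter` 100 and `tol` 1e-4: type-I
error is invariant to the iteration count (the extra Monte-Carlo noise
is identical across treatments), detection power is only slightly
conservative, and the PCoA start reliably reaches the same stress as
random restarts on these matrices. Calibration is quoted at 2,000
replicates, power and scenario behaviour at 200.

## Known limitations

- Denominator df use the between-within rule, not Satterthwaite or
  Kenward-Roger; with very few plots the treatment test is accordingly
  approximate (as is Welch's t itself, whose true size at 4+4 groups is
  ~0.040 rather than 0.050 even for normal data).
- NMDS stress at realistic assemblage sizes (70-150 samples) typically
  lands around 0.13-0.22 in two dimensions; dispersion comparisons
  remain valid as rank-based summaries, but k should be raised when the
  stress warning fires and the configuration itself is of interest.
- The deficit estimator assumes the subset-and-renormalise model; it is
  a recovery diagnostic for the generator, not a general richness
  estimator (no Chao-type correction is attempted).
- Abundance-weighted dispersion is not perfectly orthogonal to richness
  in finite samples: a pure pool deficit makes the surviving species
  commoner and samples slightly less noisy, which shows up as a weak
  dispersion side effect (~0.25 rejection at the scenario design) even
  though no turnover effect was injected.
- Multiple testing is deliberately uncorrected, matching the analysis
  convention the pipeline reproduces; interpret the per-response tests
  jointly with that in mind.
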