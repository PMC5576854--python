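# tempdiv

Temporal alpha/beta/gamma diversity partitioning of seasonal survey
data, with a controllable seasonal-community simulator.

## The problem

Site-level ("gamma") diversity summaries hide *when* species are
active. Two sites with identical pooled species lists can differ
radically in seasonal structure: one may turn its assemblage over week
by week while the other hosts the same few species all season. For
seasonally sampled assemblages — the motivating case is native bee
surveys in fragmented shrubland, but nothing here is bee-specific — the
within-season diversity of each study plot can be partitioned into:

- **temporal gamma** — diversity of the plot with all of a year's
  temporal samples pooled;
- **temporal alpha** — diversity within a single sampling occasion;
- **temporal beta** — compositional turnover among a plot's occasions,
  measured as multivariate dispersion so it is mathematically
  independent of alpha and gamma.

`tempdiv` computes all three from long-format survey tables and runs
the treatment comparisons (disturbed "fragment" vs intact "reserve"
plots) appropriate to each component.

## The statistics

- **Gamma**: per-plot pooled counts, individual-based rarefaction
  (1,000 iterations, depth = the poorest plot's total) for species
  richness S and Pielou evenness J = H'/ln S; logit-transformed
  proportions (evenness, pollen-generalist share); cube-root mean
  per-sample abundance; Welch two-sample *t*-tests between treatments.
- **Alpha**: the same metrics per temporal sample (rarefied to 20
  individuals; shallower samples flagged and excluded from rarefied
  metrics only), modelled with Gaussian random-intercept linear mixed
  models: treatment x orthogonal-polynomial(Julian date, degree 1-3)
  fixed effects, plot random intercepts, ML-AIC degree selection with
  the delta-AIC < 2 simplicity rule, sequential F tests with
  between-within denominator df.
- **Beta**: Bray-Curtis dissimilarities among all samples jointly ->
  non-metric multidimensional scaling (Kruskal stress-1, isotonic
  regression, PCoA + random restarts) -> each plot's mean
  distance-to-centroid in ordination space, compared by Welch's test.
- **Simulator**: lognormal species-abundance distribution, Gaussian
  activity windows, plot occupancy/abundance heterogeneity, Poisson
  counts, and five injectable disturbance effects (pool deficit,
  evenness skew, turnover compression, peak shift, generalist boost),
  with presets for four canonical disturbance scenarios and two field
  sampling designs. Ground truth is emitted beside every dataset.

See `docs/methods.md` for the full model descriptions, defaults and
numerical choices.

## Worked example

Simulate a two-treatment season (4+4 plots x 9 survey days) with a 35%
fragment pool deficit and compressed turnover, then analyse it:

```bash
tempdiv simulate --preset scenario3 --out sim/ --seed 7 \
    --set n_plots_reserve=4 --set n_plots_fragment=4
tempdiv analyze --survey sim/survey.csv --traits sim/traits.csv \
    --out report/ --seed 7
```

which prints

```
wrote 2960 records to sim
year 2011: NMDS stress 0.186, selected degrees {'rarefied_richness': 3,
'evenness_logit': 3, 'generalist_prop_logit': 1, 'abundance_transformed': 3};
report in report/
```

and writes tidy CSVs. The headline tables (`gamma_welch.csv`,
`dispersion_welch.csv`) read:

```
response                    t      df       p   mean_reserve  mean_fragment
rarefied_richness     10.9685  5.0988  0.0001        83.5290        53.2745
evenness_logit         2.7427  5.9999  0.0336         2.0168         1.6745
generalist_prop_logit -0.6536  5.1316  0.5415         0.2692         0.3858
abundance_transformed  0.3970  4.8983  0.7081         4.0340         3.9274

dispersion            11.4559  4.6976  0.0001         0.4663         0.1951
```

Read: fragment plots pool ~30 fewer rarefied species (p = 0.0001) and
are less even on the logit scale (p = 0.03), with no abundance
difference — the injected gamma/alpha loss — while their dispersion
scores are less than half the reserve scores (p = 0.0001), the injected
turnover loss. The generalist share moves in the injected direction but
is not significant at this design size.
`alpha.csv` and `lmm.csv` carry the per-sample table and the full
mixed-model AIC trace; `truth.json` in the simulation directory records
exactly what was injected.

The same pipeline runs on real survey CSVs with the column layout
documented in `tempdiv.data_model` (plot_id, treatment, year,
julian_date, method, species_id, count, id_level; traits: species_id,
diet, native, genus).

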