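# lepiphen

Phenological shifts, climate trends and trait sensitivity in butterfly
communities monitored with Pollard-walk transect counts.

## The problem

Repeated fixed-route butterfly counts (weekly walks at a handful of
sites across a season) carry two kinds of signal: *when* each taxon
flies, and *how many* of it there are. This package turns such survey
tables into

1. **flight phenology** per taxon and year — the abundance-weighted mean
   flight date, `Σ_t p_t · t` with `p_t = n_t / N` the relative
   abundance on Julian day `t`, and the flight-period duration, the
   weighted standard deviation of dates about that mean (the first two
   moments of the flight curve; far less sensitive to sampling effort
   than first/last appearance dates);
2. **climate indices** per year — mean temperature, total precipitation,
   the aridity index `P / 2T` (mm/°C, larger = wetter), growing degree
   days above a 10 °C developmental threshold, and three seasonal
   temperature cues (annual Oct–Sep, spring–summer Mar–Aug, prior
   autumn–winter Sep–Feb), tested for monotone trends with the
   Mann–Kendall statistic `S = Σ_{i<j} sign(x_j − x_i)` and the Sen
   slope (median of pairwise slopes);
3. **robust per-taxon trends** — Siegel repeated-medians slopes of mean
   date and duration on year and on each temperature cue (50% breakdown
   point), and TRIM-style population trends from a Poisson log-linear
   model `log μ_{s,y} = site_s + β·year` with model-based imputation of
   missed site × year cells;
4. **comparative analysis** — phylogenetic generalized least squares of
   the per-taxon slopes on ecological traits (larval trophic
   specialization, larval diet composition, voltinism) under Pagel's λ,
   Brownian-motion and Ornstein–Uhlenbeck covariance models, with AIC
   model selection and GLS F-tests of the trait contrasts.

A synthetic-data module simulates the whole design (Gaussian flight
curves, Poisson counts, multiplicative site effects, weekly visits with
dropout, trending climate, birth–death phylogenies) with a known truth
ledger, so every stage is testable end to end without any field data.
A published 19-entity per-taxon results table for a Pennsylvania
grassland community ships as a package fixture and drives the
community-level classification bookkeeping.

## Worked example

The numbered scripts under `analysis/` run the study on synthetic data;
each writes its tables under `results/` and prints what it found:

```sh
python analysis/01_simulate_surveys.py --seed 1
python analysis/02_phenology.py       --seed 1
python analysis/03_climate_trends.py  --seed 1
python analysis/04_phenology_trends.py --seed 1
```

which prints, among other things:

```
wrote 24300 survey rows (466573 individuals), 36 climate years, 18-tip tree
18 taxa retained over 10 years; 0 filter events
warming trend detected: Sen slope 0.020 degC/yr (injected 0.020), S = 250, p = 0.000695
mean-date slopes for 18 taxa: correlation with injected truth r = 1.000,
median |error| = 0.020 day/yr
```

— the Mann–Kendall test recovers the injected 0.02 °C/yr warming, and
the repeated-medians estimator recovers each taxon's injected mean-date
shift to within a few hundredths of a day per year at 500 expected
individuals per year. Continuing with
`05_population_trends.py`, `06_pgls_traits.py` and
`07_reference_report.py` fits the population model (median log-trend
error ≈ 0.002/yr), runs the PGLS trait analysis, and summarises the
packaged results table:

```
of 18 taxa: 6 advanced and 3 delayed their mean flight date; 7 prolonged
and 1 shortened their flight period
13/18 taxa (72%) shifted in at least one metric; largest advancement 5.04 days/yr
populations increasing: univoltine 100%, oligophagous 80%, overall 69%
```

The same operations are available as a CLI
(`lepiphen simulate|phenology|climate|trends|pgls|report|all`) and, of
course, as library functions — see `docs/methods.md` for the models,
conventions and their rationale.

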