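# Methods

This note records the models implemented in `lepiphen`, the conventions
and thresholds they use, and the reasoning behind the choices that were
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Phenology estimation

For one taxon in one year, counts are aggregated per Julian day
(1 = January 1) across sites and visits. The **mean flight date** is the
abundance-weighted mean `Σ p_t · t`, `p_t = n_t / N`, and the
**flight-period duration** is the abundance-weighted *population*
standard deviation about that mean (divide by `N`, not `N − 1`). Using
the same relative-abundance weights for both moments keeps the pair
internally consistent and invariant to rescaling all counts; an
unweighted variant over raw observation dates is available via the
brute-force expansion the tests use, but the weighted form is the
default and the one every downstream stage consumes. Years in which a
taxon was surveyed but never counted produce no phenology row rather
than NaN rows.

**Inclusion filters.** Years with ≤ 4 individuals of a taxon are
dropped, and taxa with ≤ 4 remaining years are excluded (both thresholds
configurable via `AnalysisConfig`; retention is *strictly greater
than* the threshold). Every exclusion is logged with the rule that
fired.

**Flight-period selection.** Multivoltine taxa whose first brood falls
partly outside the survey window can be restricted to the second brood.
The split day may be given; otherwise it is found automatically as the
deepest trough of a 7-day moving-average daily-count profile between the
two largest modes, ties broken toward the earlier day. A unimodal
profile triggers a warning and keeps all records. A `combined_broods`
mode deliberately spans both broods for taxa analysed that way. The
automatic-split procedure is this package's own convention; no standard
exists.

**Per-sex entities.** A sexually dichromatic taxon whose sexes fly on
different schedules can be split into `taxon (F)` / `taxon (M)` analysis
entities. On the phylogeny the entities share one tip, implemented by
attaching near-zero-length daughter branches (10⁻⁶ of tree depth;
exactly zero would make the Brownian covariance singular). This is
reversible via configuration.

## Climate indices and trend tests

Daily mean temperature is `(t_max + t_min)/2`. Growing degree days
accumulate `max(0, mean − threshold)` with a 10 °C default threshold
(the usual minimal thermal condition for butterfly development). The
aridity index is `P / 2T` (mm/°C; larger = wetter); it is undefined and
signalled for `T ≤ 0`. The three seasonal cues are means of the daily
mean temperature over month windows — annual: Oct (year−1)–Sep;
spring–summer: Mar–Aug; autumn–winter: Sep (year−1)–Feb — and a cue-year
whose window is not fully covered is reported as missing, not
extrapolated.

The **Mann–Kendall test** uses `S = Σ_{i<j} sign(x_j − x_i)` with the
standard tie-corrected variance `[n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18`.
For `n ≤ 10` without ties the exact permutation null is used (the
inversion-count distribution, computed by polynomial convolution);
otherwise the normal approximation with continuity correction.
P-values are two-sided by default — the more conservative of the two
common conventions — with one-sided alternatives available. The **Sen
slope** is the median of all pairwise slopes against the series index;
it is exact on collinear data and affine-equivariant. Under an i.i.d.
Gaussian null of length 36 the non-rejection rate at the 0.95 confidence
level is 0.95 within Monte-Carlo error (the acceptance script recomputes
this).

## Robust per-taxon trends

"Median-based linear model" is implemented as **Siegel repeated
medians**: per point `i`, `m_i = median_{j≠i} (y_j − y_i)/(x_j − x_i)`;
slope = `median_i m_i`; intercept = `median_i (y_i − slope·x_i)`. It has
a 50% breakdown point (corrupting ⌊(n−1)/2⌋ of n collinear points leaves
the slope exact — tested). Theil–Sen is available as an option. The
p-value is a one-sample Wilcoxon signed-rank test of the per-point
median slopes against zero, mirroring what the R `mblm` family reports.
**Known limitation:** because the per-point medians are mutually
correlated, this p-value is liberal — Monte-Carlo under the null at
n = 20 puts roughly a third of p-values below 0.05 — so per-taxon
p-values should be read as descriptive rankings, not calibrated error
rates. It is retained because it is the field's convention for this
estimator; the community-level inferences run through PGLS, not through
these p-values.

## Population trends

Annual counts per site are modelled as Poisson with
`log μ_{s,y} = site_s + β·(y − ȳ)`, fitted by iteratively reweighted
least squares (statsmodels GLM). This is the TRIM linear-trend model
with site effects; serial correlation and overdispersion corrections are
deliberate extension points, not implemented. Missing site × year cells
are imputed with the fitted means; by construction, refitting on the
completed table leaves `β` unchanged (tested). Non-convergence (IRLS
failure, non-finite or |β| > 10) is flagged and the trend withheld. The
additive trend — individuals per transect walk per year — is
`β × mean fitted count per walk`, with walks-per-cell defaulting to 1;
the exact back-transformation between the multiplicative and additive
scales is a documented convention since no standard exists.

## Phylogenetic GLS

Residual covariance across taxa: Brownian `V_ij = t_ij` (shared
root-to-MRCA path length); Pagel's λ scales the Brownian off-diagonals
by λ ∈ [0, 1]; stationary Ornstein–Uhlenbeck on an ultrametric tree uses
`V_ij = (1/2α)(1 − e^{−2αT}) e^{−α d_ij}` with `d_ij` the patristic
distance. The rate σ² is profiled out. λ and α are estimated by
maximizing the **restricted** (REML) profile likelihood on a grid
refined by golden-section search, λ on [0, 1] (boundary candidates
checked explicitly), α on [10⁻⁶, 50/tree depth].

*Why REML rather than ML:* with ~20–30 taxa the ML profile estimate of λ
is biased toward the boundary, and confidence intervals built on the
plug-in covariance undercover badly (the package's own recovery harness
measures ~66–74% coverage of a true trait effect for nominal 95% under
ML, ~93% under REML). ML remains available (`reml=False`).

Numerical safeguards: Cholesky factorizations add an escalating
diagonal jitter (at most 10⁻⁸ of the mean diagonal) because birth–death
trees routinely contain near-zero branches that make the Brownian matrix
numerically semi-definite; and the OU α-search excludes covariances with
condition number above 10⁷, since the stationary OU matrix tends to a
singular equicorrelation matrix as α → 0 and the profile likelihood
spikes spuriously there. If the whole α range is ill-conditioned the OU
fit is reported as failed and excluded from model selection.

Inference: coefficients are GLS `(XᵀV⁻¹X)⁻¹XᵀV⁻¹y`; the trait test is a
GLS F-test of the trait design against intercept-only under the same
fitted covariance; model choice is by AIC (`2k − 2ℓ`, k counting
coefficients, σ² and any estimated λ/α; ties broken toward fewer
parameters — so a λ fit that lands exactly on λ̂ = 1 loses to Brownian
by its one extra parameter). AICc is not used by default given the
AIC convention of the source analyses; at n ≈ 18 its correction would be
material, which is noted as a limitation. Limits are pinned by tests:
λ = 0 and star trees reproduce OLS coefficients, F and p to 10⁻⁸, and a
three-taxon fit matches the closed-form matrix-algebra solution.

## Shift classification and assemblage summaries

With per-entity slopes and p-values: *advanced*/*delayed* = mean-date
slope sign with `p ≤ shift_alpha`; *prolonged*/*shortened* likewise for
duration. `shift_alpha` defaults to **0.07** so that marginal shifts
(p = 0.06, 0.07) are counted, matching the source reporting; it is
configurable. For taxon-level counts the two sex entities of a split
taxon merge — the taxon counts once if either sex qualifies.

Population summaries use `trend_alpha = 0.05`: the denominator per trait
level is the entities with converged, significant trends; the numerator
is those with positive trends; percentages are rounded half-up. The
community-wide share is reported against the *taxon* count (the two sex
rows collapse to one taxon in the denominator) while each entity's trend
direction contributes to the numerator — with the packaged table this
gives 11 increasing entities over 16 taxa with usable trends. The
denominator conventions are the package's own, stated here because the
source reporting never defines its own; alternative conventions
(all-rows denominators, strictly entity-level counting) give values a
few points different, which is the dominant uncertainty in these
percentages.

## Synthetic data: what it emulates and what it does not

Flight curves are Gaussian in day-of-year — the weighted mean/SD metrics
are exactly the first two moments of such a curve, so estimator
consistency can be checked against truth. Counts at a visit are Poisson
with mean `n_per_year × site effect × e^{pop_beta·Δy} × N(t; μ_y, σ_y) × Δt`
(Δt = 7-day visit interval); μ and σ shift linearly with year and
optionally with a temperature cue; two-brood taxa are equal mixtures of
two kernels. The survey window is weekly visits May 1–Oct 31 at 5 sites
with fixed multiplicative site effects (0.6–1.6, log-spaced) and
optional per-visit dropout. Climate is a sinusoidal seasonal cycle
(base 11 °C, amplitude 12 °C, peak late July, 10 °C diurnal range) with
a linear year trend (default 0.02 °C/yr over 1981–2016), a per-year
random effect (SD 0.3 °C), daily noise (SD 2 °C), and gamma-distributed
daily precipitation normalized to a trending annual total (1100 mm,
+2 mm/yr). Default community: 18 taxa, 500 expected individuals per
year, true mean-date shifts spread over ±1.5 day/yr, duration shifts
±0.3 day/yr, log-abundance trends ±0.05/yr — magnitudes of the order
reported for temperate butterfly communities.

Not emulated: weather-dependent detectability, observer effects,
overdispersed counts (a negative-binomial switch is an extension
point), within-season movement between sites, and non-Gaussian
(skewed) flight curves. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative assumptions,
not robustness to all field realities.

## Problem sizes

The default suite simulates 18 taxa × 10 years × 5 sites at 500
expected individuals per year for end-to-end recovery, 10,000 series for
Mann–Kendall calibration, 200 replicates at 30 tips for PGLS recovery,
and 40 random trees for covariance validity — sizes chosen so each check
has clear Monte-Carlo resolution while the suite stays quick to run.
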