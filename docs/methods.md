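# Methods

## The analysis in one paragraph

`seasonmix` analyzes a genus × sample count table collected on a crossed
field design — survey sites at distinct elevations, monthly sampling dates,
and discrete soil-depth layers. Seasonality enters every model through a
pair of harmonic covariates, Sc = cos(2πd/365) and Ss = sin(2πd/365), where
d is the calendar-day index from the first sampling date; together with
standardized elevation (Ele) and the depth-layer midpoint (Dep) they form
the covariate set of four analyses: (1) Gaussian linear regressions of
genus richness and total abundance with group likelihood-ratio importance
tests and semi-partial ΔR²; (2) a finite mixture of negative-binomial (NB)
regressions over genus count series, fit by EM and selected by BIC, that
clusters genera by their joint seasonal/spatial response; (3) a
compositional indicator-genus analysis scoring each genus's fidelity to its
cluster with a permutation p-value; and (4) NB/Gaussian GLMs of community
responses on reduced environmental predictors (soil temperature, soil water
content, and the first principal components of soil-chemistry and
plant-trait blocks) with backward-AIC selection and explained-deviance
decomposition.

## Covariates and phase back-calculation

The harmonic pair lets a linear model place a seasonal peak on any calendar
day: a fitted seasonal term a·cos(ωd) + b·sin(ωd) (with a, b mapped back to
the raw basis by dividing each coefficient by its covariate's raw standard
deviation) peaks at d* = (365/2π)·atan2(b, a) mod 365 and bottoms out
exactly 182.5 days later. The period is fixed at 365 days even across leap
years; d itself is an exact calendar difference. Standardization uses the
sample standard deviation (n−1) over all supplied rows, and the raw
means/sds are stored so the z-scoring is exactly invertible.

Because sampling is monthly, `SeasonalExtrema` reports two month
attributions: the calendar month of the fitted extremum itself, and the
month of the nearest monthly sampling occasion (origin date plus whole
months). They differ only when an extremum falls within a day or two of a
month boundary — which happens for the worked diversity-regression example,
where coefficients printed at two decimals put the fitted peak at the
Mar 31/Apr 1 boundary and the trough at Sep 30; the sampling-occasion
attribution (April, October) is the one that matches what a monthly survey
observes.

Depth layers map to their midpoints: 0–5 cm → 2.5, 5–10 → 7.5,
10–20 → 15, 20–30 → 25 cm. The default design crosses 3 sites
(1831.8, 1334.2, 880.4 m a.s.l.) × 12 monthly dates from 2016-07-03 × 4
layers = 144 samples.

## The NB-regression mixture

Counts for genus g in sample s follow
y_gs ~ NB(μ = exp(x_s'β_{z_g}), θ_{z_g}) with variance μ + μ²/θ, where
z_g ∈ {1..K} is the genus's latent component. Responsibilities are computed
at the genus level — the component likelihood of a genus is the product
over all of its samples — because the clusters are interpreted as sets of
genera (their abundance-rank ranges and pooled regressions are reported per
cluster). There are no per-genus intercepts inside the mixture by default;
within-cluster abundance heterogeneity is absorbed by θ_k. The generator
offers per-genus lognormal offsets (`genus_offset_sd`) for misspecification
studies.

EM details:

* **E-step** in the log domain with log-sum-exp; responsibility rows sum to
  1 within 1e-12.
* **M-step**: mixing weights are responsibility means; each component is
  refit by responsibility-weighted NB regression. Because all genera share
  the same covariate rows, the weighted score equations collapse exactly to
  an S-row GLM on responsibility-averaged counts, making the M-step cost
  independent of the number of genera. θ_k is then profiled by maximum
  likelihood on the full weighted table, using the fact that the
  Γ-function terms depend on the data only through the multiset of observed
  count values (a weighted histogram over unique counts).
* **Initialization**: a uniform random hard partition of genera followed by
  one M-step; 5 random restarts by default, best final log-likelihood wins.
* **Convergence**: relative log-likelihood change < 1e-6 or 500 iterations.
  The update is a generalized EM (each M-step weakly increases the
  complete-data objective), so the log-likelihood trace is non-decreasing
  up to the inner GLM tolerance (asserted at 1e-8 relative).
* **Degeneracy**: a component whose weight falls below 1/(2G) is eliminated
  and the fit continues with K−1 (logged; both requested and effective K
  are reported).
* **BIC** = −2·loglik + p·ln(N) with p = (K−1) + K·(5 coefficients + 1
  dispersion) and N = genera × samples observations. The grouped
  alternative N = genera would change selection; the choice is stated in
  the model output (`n_obs`).

Printed per-cluster effect tables come from post-hoc pooled NB refits of
each hard cluster's observations, not from the soft-weighted component
parameters — that makes Wald p-values, D and ΔD those of an ordinary single
regression. Both parameter sets are serialized.

## Regression core

* NB GLM: log link; coefficients by IRLS at fixed θ (statsmodels), θ
  profiled by bounded maximum likelihood in [1e-3, 1e6], the two alternated
  to joint convergence. A θ at ≥ half the upper bound flags the fit
  `poisson_like`. Likelihood weights (fractional allowed) multiply each
  observation's log-likelihood term.
* Explained deviance D = 100·(null − residual)/null deviance; for Gaussian
  fits the deviances are sums of squares so D = 100·R². ΔD (and ΔR²) are
  semi-partial full-minus-reduced drops, refitting the reduced model; NB
  reduced fits hold θ at the full model's value so nesting makes ΔD ≥ 0 by
  construction.
* Group importance is a likelihood-ratio test of the full model against
  the model lacking the group, χ² with df = group size; the default
  grouping is {Sc, Ss}, {Ele}, {Dep}. Coefficient p-values are Wald (t for
  Gaussian, z for NB).
* AIC = −2·loglik + 2k with k counting all estimated parameters including
  the Gaussian scale or NB dispersion. Backward selection drops one
  predictor per step (the drop that most decreases AIC) and stops when no
  drop decreases it; the intercept is never dropped and the path is
  logged. Note the textbook operating characteristics: a single spurious
  Gaussian predictor survives with probability P(χ²₁ > 2) ≈ 0.157, so
  "noise elimination" rates concentrate near 84% per predictor — the tests
  assert at that attainable level.
* PCA reduction standardizes the block first (correlation-matrix PCA;
  the blocks mix pH, percentages and concentrations, so covariance PCA
  would be scale-dominated) and orients PC1 so an anchor variable loads
  positively: total carbon for the soil block (a fertility gradient reads
  positive) and canopy openness for the plant block.
* VIF_j = 1/(1−R²_j); exact collinearity reports ∞ rather than raising.
  The conventional screen (< 10) is reported, not enforced.

## Indicator genera

The indicator value of a genus is the mean proportional similarity —
Σ_s min(p_s, q_s) over sample-normalized profiles, bounded in [0, 1] —
between the focal genus and the other members of its cluster (self
excluded to avoid inflation). Significance: random genus sets of the same
size are drawn from the whole pool, the same focal-to-members statistic is
recomputed, and p = (1 + #{null ≥ observed})/(1 + n_permutations). The
null distribution depends only on the cluster size, so it is drawn once
per cluster and shared by its members. With the default 99 permutations
the smallest attainable p is 0.01. This statistic scores genera within
clusters *of genera*; the Dufrêne–Legendre IndVal (indicators of sample
groups) is deliberately out of scope. (The literature this design follows
describes the statistic as a mean similarity within a cluster, which is
what is implemented; it is not the classic site-group indicator value.)

## Synthetic-data generator

The generator is the test bench: it draws the design grid, environmental
drivers, and counts from exactly the model the mixture assumes, with known
component labels, coefficients, dispersions and weights returned as ground
truth.

* Defaults: 3 sites at the elevations above, 12 months, 4 depths (144
  samples); 500 genera; K_true = 3 components with mixing weights
  (0.40, 0.35, 0.25), distinct sign patterns over (Sc, Ss, Ele, Dep) with
  |β| in 0.2–1.2 (the magnitude range typical of genus-level count
  regressions on standardized covariates) and θ = 5 per component; genus
  offsets off by default (model-matched generation). Offsets at sd 1.5
  produce the left-skewed rank-abundance curves of real genus tables (top
  decile of genera carrying > 50% of reads).
* Counts are gamma–Poisson draws (exact for the mean/dispersion NB
  parameterization, stable as θ → ∞).
* Environmental drivers are linear in the raw harmonics, elevation and
  depth plus Gaussian noise, with the sign structure the analysis should
  detect: ST = 9 + 6·Sc + 6·Ss − 0.005·(elev − min) (°C; summer peak,
  elevational lapse); SWC ∈ [0, 100]% falls with Sc and depth, rises with
  elevation; a latent fertility score falls with Ss and depth and rises
  with elevation; a latent phenology score falls with Sc, Ss and
  elevation. Soil-chemistry variables (pH, C, N, C:N, anions, cations) and
  plant traits (canopy openness, leaf/shoot C and N) load on the latent
  scores with fixed signs plus observation noise, so a first principal
  component recovers each score; C:N ratios are computed from the
  generated C and N, keeping them internally consistent.
* One master seed expands deterministically into per-stage substreams
  (community, environment, rarefaction, mixture restarts, permutations);
  fixing it makes every output bit-reproducible.

What the generator does **not** emulate: sequence-level artifacts (reads,
chimeras, taxonomy error), spatial autocorrelation within plots, temporal
autocorrelation beyond the annual harmonic, and compositional coupling
between genera (counts are independent across genera given the design).
Passing recovery tests therefore show the estimation machinery is correct
under the model's own assumptions, not that real communities satisfy them.

## Preprocessing

Rarefaction subsamples each sample's reads without replacement to a common
depth (multivariate hypergeometric draw), in a single pass with the seed
recorded in output provenance; samples below the depth are dropped with a
warning, never padded. Defaults: 21,307 reads (fungal ITS2 libraries) and
19,998 (bacterial 16S), each the minimum observed depth of its library.
Richness is the count of genera with nonzero reads. Rank abundance ranks
genera by total reads, ties broken lexicographically by genus id so ranks
are a deterministic permutation of 1..G.

## Problem sizes and numerical choices

The test suite and acceptance script run the full machinery at reduced
but structurally identical sizes chosen for quick iteration: recovery
studies use 300 genera × 144 samples with a K sweep over 2–6 (the
collapsed M-step makes a full 2–20 sweep on 500+ genera a matter of
minutes, and the CLI default remains 2–20); EM contract checks use 30–60
genera; the permutation calibration uses 500 label shuffles of a 40-genus
table; stepwise behavior uses 100 replicates at n = 500.

Tie-breaks and degenerate inputs are deterministic and explicit: argmax
cluster assignment breaks ties toward the lowest component index; constant
vectors, all-zero counts and zero null deviance raise degenerate-input
errors; rank-deficient designs raise a singular-design error; exact
collinearity in VIF reports ∞.

## Known limitations

* The mixture assumes conditional independence of counts across samples
  and genera given the component; overdispersion from genus-level random
  effects is only representable via the optional offsets.
* Backward AIC is greedy single-term elimination; it is not guaranteed to
  find the global AIC minimum over subsets.
* Wald p-values for NB fits condition on the profiled θ (its estimation
  uncertainty is not propagated), matching common GLM practice.
* Gene-copy–style abundance responses are modeled Gaussian for
  comparability of the printed tables despite being positive quantities.
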