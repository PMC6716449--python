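# seasonmix

Seasonal and spatial analysis of soil-microbiome genus count tables.

Ecologists surveying soil fungi and bacteria across a year face a joint
question: how much of the variation in diversity, abundance and taxonomic
composition is *seasonal*, and how much is *spatial* (elevation, soil
depth)? `seasonmix` implements a complete statistical pipeline for crossed
site × month × depth designs:

* **Harmonic seasonal regressions** — richness and abundance are regressed
  on Sc = cos(2πd/365) and Ss = sin(2πd/365) (d = days from the first
  sampling date) plus standardized elevation and depth, with group
  likelihood-ratio importance tests, semi-partial ΔR², and
  back-calculation of the calendar day of the fitted seasonal peak.
* **Model-based clustering of genera** — a finite mixture of
  negative-binomial regressions, y_gs ~ NB(exp(x_s'β_{z_g}), θ_{z_g}),
  fit by EM with random restarts and genus-level responsibilities; the
  number of clusters K is chosen by BIC over a sweep (2–20 by default).
  Per-cluster effect tables report coefficients, Wald p-values, explained
  deviance D = 100·(null − residual)/null and per-covariate ΔD.
* **Indicator genera** — each genus is scored by its mean proportional
  similarity to its cluster mates, with a permutation p-value from random
  genus sets of the same size (minimum p = 0.01 at the default 99
  permutations).
* **Environmental GLMs** — richness, abundance and per-cluster counts are
  regressed on soil temperature, soil water content and the first
  principal components of soil-chemistry and plant-trait blocks, with
  VIF screening, backward-AIC selection and D/ΔD decomposition.
* **A synthetic-study generator** — the crossed design (144 samples by
  default), seasonally/elevationally structured environmental drivers, and
  count tables drawn from a known NB-regression mixture, so every stage
  can be checked for ground-truth recovery.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Where does a fitted seasonal cycle peak? Feed the harmonic coefficients of
a diversity regression (here: richness falling steeply with Ss) to the
phase calculation:

```python
>>> import seasonmix as sx
>>> ext = sx.peak_day(-0.24, -6.61, origin="2016-07-03")
>>> ext.peak_date, ext.trough_date
(datetime.date(2017, 4, 1), datetime.date(2016, 9, 30))
>>> ext.peak_sampling_month, ext.trough_sampling_month
(4, 10)
```

The fitted maximum lands on April 1 and the minimum half a period
(182.5 days) later at the September/October boundary; attributed to the
nearest monthly sampling occasion, richness peaks in April and bottoms out
in October.

A full run on simulated data with a known 3-component mixture:

```python
>>> from seasonmix import AnalysisConfig, SimulationParams, run_analysis
>>> cfg = AnalysisConfig(simulation=SimulationParams(n_genera=100),
...                      k_min=2, k_max=4, n_restarts=4, seed=7)
>>> bundle, manifest = run_analysis(cfg)
>>> manifest["selected_k"]
3
>>> bundle["bic_curve"]["bic"].round(1)
k_requested
2    118778.2
3    105421.3
4    105487.0
>>> bundle["cluster_effects"][["n_genera", "coef_Ss", "p_Ss", "deltaD_Ss", "D"]].round(3)
         n_genera  coef_Ss   p_Ss  deltaD_Ss       D
cluster
1              26   -0.690  0.000     18.166  89.080
2              32    0.890  0.000     60.833  78.240
3              42    0.007  0.317      0.002  85.467
```

BIC bottoms out at the generating K = 3. The effect table reads like a
field report: cluster 2 rises steeply with the sine season score
(coefficient 0.89, ΔD ≈ 61 percentage points of deviance), cluster 1 moves
oppositely, and cluster 3 has no seasonal sine response (p = 0.32,
ΔD ≈ 0) — matching the three generating components (true β_Ss of 0.9,
−0.7, 0.0). `bundle["indicator_top"]` then names each cluster's most
faithful genus (indicator values ≈ 0.75–0.77, p = 0.01 at 99
permutations).

The same pipeline runs from the shell, exchanging TSV files between
stages:

```sh
seasonmix simulate --seed 1 --out-dir sim/
seasonmix cluster --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --k-min 2 --k-max 8 --seed 1 --out-dir fit/
seasonmix all --config analysis.yaml --out-dir report/
```

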