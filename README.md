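# yieldbayes

Bayesian two-group analysis of precision-agriculture **yield-monitor data**:
did a field treatment — for example a winter field-pea cover crop ploughed in
as green manure — raise the dry yield of the following commercial crop, and on
what share of the harvested area is the effect evident?

The package is for agronomists and data scientists running on-farm experiments
where a combine harvester records one georeferenced dry-yield measurement per
harvested polygon (area = swath width × speed × logging interval), across
treated ("test") and untreated ("control") fields. It provides the whole
pipeline: a synthetic-data generator with the spatial structure of real
yield maps, outlier filtering, balanced stratified sampling, posterior
estimation by MCMC, and effect summaries.

## Model

Within each group g ∈ {test, control}, filtered polygon-level dry yields are
modelled as i.i.d. normal,

    y_i | μ_g, σ_g  ~  N(μ_g, σ_g²),

with weakly informative data-scaled priors μ_g ~ N(ȳ, 10·s) and
σ_g ~ HalfNormal(10·s) (ȳ, s the sample mean and sd). Posteriors
p(μ_g, σ_g | y) are sampled with a self-contained random-walk Metropolis
sampler (on (μ, log σ), burn-in-only adaptation, split-R̂ and ESS
diagnostics). The treatment effect is summarised by the **contrast
distribution** — the posterior of the test-minus-control difference — in two
modes:

* **parameter** contrast: draw-wise μ_test − μ_control, the posterior of the
  difference in mean yield;
* **predictive** contrast (default): differences ỹ_test − ỹ_control of
  matched simulated measurement pairs, one pair per posterior draw.

From the contrast draws come the contrast mean, the **highest-density
interval** (shortest interval holding 95% of the mass), the **probability of
superiority** P(test > control) — interpretable as the percentage of observed
area where the effect is evident — and the relative **gain**
100·(μ_test − μ_control)/μ_control in percent.

## Worked example

```python
from yieldbayes import PipelineConfig, run_pipeline

cfg = PipelineConfig(location="DEMO", seed=1,
                     n_test_fields=2, n_control_fields=2,
                     field_width=140.0, field_length=300.0)
report, results = run_pipeline(cfg)
print(results.summary())
```

prints

```
Bayesian two-group yield comparison — DEMO
==========================================================
group           n   post. mean mu  post. mean sigma
----------------------------------------------------------
test          996          3438.2             503.9
control       996          2365.9             491.9
----------------------------------------------------------
contrast mean (predictive): 1077.9 kg/ha
95% HDI: [-263.1, 2492.7] kg/ha
P(test > control): 0.937
gain: 45%
----------------------------------------------------------
diagnostics: test rhat(mu)=1.0028 ess(mu)=2201, control rhat(mu)=1.0010 ess(mu)=2209
```

Here the simulated truth is a 2550 kg/ha baseline with a +990 kg/ha additive
treatment effect on top of smooth within-field fertility variation and
measurement noise. After 3-sigma filtering and per-field stratified balancing
(996 measurements per group), the posterior mean yields are ≈3440 vs
≈2370 kg/ha, a 45% gain; a simulated treated measurement beats its matched
control 93.7% of the time, while the wide predictive HDI shows the
measurement-level spread. The same run is available from the shell:

```sh
yieldbayes run --seed 1 --output out/demo
```

and the stages individually as `yieldbayes simulate | filter | sample | fit |
contrast | report`, all exchanging a plain CSV
(`field_id,group,x,y,area_m2,dry_yield_kg_ha`) or GeoJSON points.

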