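# Methods

## Problem and data model

On-farm trials compare treated ("test") and untreated ("control") fields using
yield-monitor telemetry: each harvested polygon — dimensioned by the
harvester's swath width, speed and logging interval — carries one dry-yield
measurement in kg/ha. The analysis asks how much the treatment shifted mean
yield and how often a treated measurement beats a matched control one.

The measurement table is a tidy DataFrame with columns
`field_id, group, x, y, area_m2, dry_yield_kg_ha`; planar metre coordinates
only (no geodesy — trial layouts are km-scale at most).

## Synthetic data generator

Because raw yield-monitor datasets of this kind are rarely public, the
generator is first-class, tested code that every downstream stage runs
against. One simulated measurement is

    y = baseline_mean + treatment_effect·1[test] + f(x, y) + ε,   clipped at 0,

where `f` is a smooth fertility surface and ε measurement noise, replaced with
probability `outlier_rate` by a gross error of ±`outlier_magnitude`·`noise_sd`
(random sign) to emulate sensor faults. Clipping events are logged; at the
default conditions (yields ≈ 2550–3540 ± 500 kg/ha) they essentially never
occur.

The fertility surface is a lattice of i.i.d. standard-normal nodes (spacing =
`fertility_scale`, padding 3 scales) smoothed with a Gaussian kernel of
bandwidth `fertility_scale` and renormalised pointwise, so the marginal sd
equals `fertility_sd` everywhere while points within a correlation length are
strongly positively correlated. Any smooth seeded surface with a controlled
correlation length would serve; this construction was chosen because the
pointwise normalisation makes the marginal-sd contract exact rather than
approximate. One shared seed drives independent substreams (surface, noise,
outliers), so each component is reproducible in isolation.

Defaults, chosen once as the study conditions and not revisited:

| parameter | default | rationale |
|---|---|---|
| swath_width | 7.0 m | common combine header width |
| harvester_speed | 1.75 m/s | ≈ 6.3 km/h harvest speed |
| measurement_interval | 7 s | gives 85.75 m² polygons, matching the ~86.6 m² observational units of real yield maps |
| baseline_mean | 2550 kg/ha | control-group wheat yield on poor heavy-clay soils |
| treatment_effect | 990 kg/ha | a realistic green-manure response (≈ +39%) |
| fertility_scale | 80 m | within-field fertility patches |
| fertility_sd | 300 kg/ha | smooth heterogeneity, ≈ 12% CV |
| noise_sd | 400 kg/ha | per-measurement monitor + micro-scale noise |
| outlier_rate / magnitude | 0.002 / 8σ | rare gross sensor errors |

What the generator does **not** emulate: harvester kinematics beyond
straight passes, moisture correction, GPS artefacts (overlap passes, fill
delays), non-normal yield distributions, or treatment-by-fertility
interactions. Passing tests therefore demonstrate the statistical machinery,
not robustness to every real-world artefact.

## Preprocessing

**3-sigma filter.** Within each scope — by default each treatment group
separately — the mean and sd of dry yield are computed once from the
unfiltered data and measurements outside mean ± 3·sd are excluded, in a single
pass (no iterative re-estimation). Per-group scoping prevents a genuine large
treatment effect from being mistaken for outliers; the scope is recorded in
the `FilterReport` and configurable (`pooled` available). A zero-variance
scope keeps everything; a scope with fewer than two measurements raises an
error naming the scope.

**Stratified balancing.** Each field is a stratum. Within each group a target
number of measurements (default: the smaller group's size) is allocated to
strata proportionally by largest-remainder rounding — deterministic ties
broken lexicographically by `field_id` — and drawn uniformly without
replacement with a seeded generator. Both groups end with identical sample
sizes and no large field dominates.

## Inference

Per group, yields are i.i.d. N(μ, σ²) with data-scaled weakly informative
priors μ ~ N(ȳ, c·s), σ ~ HalfNormal(c·s), c = `prior_scale_factor` = 10.
At the hundreds-to-thousands sample sizes of this problem the likelihood
dominates; c is configurable and recorded in output.

The sampler is random-walk Metropolis, implemented in-repo so the package owns
the computation: σ is sampled on the log scale with the +log σ Jacobian
(no boundary rejections, better mixing, identical posterior); proposals are
diagonal Gaussians started at the asymptotic posterior scales (s/√n for μ,
1/√(2n) for log σ, × 2.4); a per-chain scale multiplier adapts every 50
iterations **during burn-in only** toward ≈ 0.3 acceptance, so post-burn-in
transitions leave the posterior exactly invariant. The likelihood is evaluated
through sufficient statistics (n, Σy, Σy²), making each step O(1) in the data.
Defaults: 4 chains, 5 000 iterations, 1 000 burn-in.

Diagnostics: split-chain R̂ implemented in-repo (each chain halved; the raw
statistic is clamped at 1.0 from below, since it can dip marginally under 1
for finite well-mixed chains — degenerate zero-variance chains return 1.0 with
a warning); ESS via arviz. `fit_group` refuses to return (raises
`ConvergenceError` carrying the diagnostics) when any R̂ exceeds 1.01.

The sampler was validated two independent ways: dense grid integration of the
same unnormalised posterior on a 50-point dataset (moments agree within
Monte-Carlo error) and the conjugate normal closed form with σ held fixed.

## Contrast and effect summaries

Both contrast modes are provided because "difference between groups" is
genuinely ambiguous for this design: the posterior of μ_test − μ_control
(**parameter** mode), and the distribution of differences between matched
simulated measurement pairs ỹ_test − ỹ_control, ỹ_g ~ N(μ_g[i], σ_g[i])
(**predictive** mode, the default — it is the polygon-level paired comparison
this design is built around). The mode is recorded in every output.

* HDI: the shortest contiguous window of ⌈mass·n⌉ sorted draws (unimodal
  estimator); default mass 0.95, configurable. Verified against exhaustive
  window search.
* Probability of superiority: fraction of contrast draws > 0, ties at exactly
  0 weighted ½ (unbiased under continuous distributions, deterministic).
  ×100 it is reported as the percentage of observed area where the effect is
  statistically evident — meaningful in predictive mode, where each draw is a
  matched polygon pair.
* Gain: 100·(μ_test − μ_control)/μ_control, half-up rounded to integer
  percent. Yields are displayed rounded to 10 kg/ha; machine-readable output
  keeps full precision.

## Pipeline and reproducibility

`run_pipeline` chains simulate/ingest → filter → balance → fit → contrast.
One top-level seed derives, via `numpy.random.SeedSequence`, the sub-seeds of
every stochastic stage (simulation, sampling, the two samplers, predictive
draws); the report's provenance block carries the resolved config, derived
seeds, filter reports, sampling plan and convergence diagnostics, and
re-running a saved `config_resolved.yaml` reproduces the report bit-for-bit.
Reports contain no timestamps for exactly this reason. Stage failures
propagate wrapped with the stage name and seed.

## Calibration checks and their scope

The replicate-based acceptance checks (95% HDI of the parameter contrast
covering a known +990 kg/ha effect in ≥ 18/20 runs at n = 500/group;
null-effect predictive superiority ≈ 50%) simulate with `fertility_sd = 0`.
This is deliberate: the likelihood is i.i.d. normal, and spatially correlated
fertility induces extra between-field variance that a pooled two-group model
does not represent — with few fields per group the effective number of
independent fertility patches, not the number of polygons, limits precision,
and no finite-sample coverage statement holds under that misspecification.
The well-specified runs test the estimation machinery; the default conditions
keep the heterogeneity on, and the mitigation for it in practice is the
paired-neighbour field layout (`make_layouts` alternates groups along a strip)
rather than a richer likelihood.

Replicate problem sizes (n = 500/group, 20 + 12 replicates; 10⁶ draws for the
retention and HDI-endpoint checks) keep the whole suite under a minute on one
core while leaving Monte-Carlo error well inside every asserted tolerance.

## Known limitations

* No hierarchical field-level model and no spatial covariance in the
  likelihood; between-field heterogeneity is a design concern (pair fields),
  not a model term.
* Normal likelihood taken literally; heavy-tailed yields would inflate σ and
  widen predictive contrasts.
* The 3-sigma filter is the only cleaning step — no GPS-artefact handling.
* Balanced sampling equalises counts, not acreage; `area_m2` is carried but
  not used as a weight.
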