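# Methods

## Selection model and estimand

The competition of two strains is modelled as one-locus haploid selection:
with relative fitness w = W_AA / W_aa, the focal strain's proportion obeys
p_{t+1} = p_t w / (p_t w + 1 − p_t), equivalently a constant shift of
log(w) per generation on the log-odds scale. The estimand is the
per-generation fitness ratio w and the selection coefficient s = w − 1
(the two published scales coincide under this identity, which the package
adopts throughout). Time is counted in transfers, with one generation per
transfer by default; `FitConfig.generations_per_transfer` rescales the
slope if that assumption is to be probed.

Assumptions worth stating: fitness is constant over the experiment
(no frequency dependence), the two strains do not interbreed into scorable
intermediates at the marker (proportions are read from genomic allele
counts), and measurement times are known exactly.

## Fitting

Default (`per_replicate_slopes`): per replicate, OLS of logit(p) on t with
a free intercept — founding proportions need not be exactly 0.5 because
ten picked L4 animals per strain need not contribute offspring equally.
log ŵ is the unweighted mean of replicate slopes; the 95% CI is a
Student-t interval over those slopes (df = replicates − 1), computed on
the log-w scale and mapped monotonically to s. This treats the replicate,
not the time point, as the unit of independent information — correct here
because drift makes within-replicate residuals serially dependent.
Alternatives: `pooled_fixed_intercepts` (one shared slope, one intercept
per replicate, single OLS; CI from the slope's standard error) and a
seeded replicate bootstrap (percentile interval, default 2000 resamples).
With a single replicate the replicate-t interval is undefined and is
returned as absent with a warning rather than fabricated.

Boundary proportions (0 or 1) carry no logit information; the default
policy drops them with a warning, leaving the remaining points to fit. An
epsilon-clamp policy (clamp into [ε, 1−ε], ε = 10⁻⁶ by default) exists
for users who prefer to keep fixated points at the cost of slope bias. A
trajectory with fewer than two finite-logit points is excluded; an
experiment with no fittable trajectory raises `UnfittableTrajectoryError`.

## ddPCR measurement layer

The trajectory estimator is the raw count ratio n_A / (n_A + n_a) over
positive droplets, the quantity the wet protocol computes. A droplet
containing both alleles counts in both channels. The raw ratio is accurate
only at low template occupancy; the standard Poisson correction
λ_c = −ln(1 − n_c/N_total) is provided (`poisson_corrected_proportion`)
and is consistent at any occupancy, erroring on saturated channels.

The simulator draws each channel's positive count as
Binomial(N_total, 1 − exp(−λ p_c)): per-droplet template counts of the two
alleles are independent Poissons (thinning), so channel positivities are
independent and this is the exact distribution of the per-droplet model,
without looping over droplets. Defaults — occupancy 0.1 templates/droplet,
15000 accepted droplets — sit in the instrument's recommended operating
range; the study reports no droplet statistics, so these are the package's
choice of a typical reaction, fixed once. At these settings the raw
ratio's saturation bias is ≲ 0.005, an order of magnitude below the
per-experiment noise.

## Protocol simulator

Each transfer cycle collapses within-plate growth into one deterministic
selection step followed by one binomial bottleneck of `bottleneck_n`
founders (default 1500, the middle of the ~1000–2000 larvae transferred
per passage); this matches the resolution of the fitted model, which is
also why nothing finer (age structure, overlapping broods, egg-laying
schedules) is simulated. Fixation is absorbing. Measurements apply the
ddPCR simulator to the post-bottleneck frequency at the scheduled
generations (default 1, 3, 5, 7 — DNA is collected at odd generations;
generation 0 is not measured, consistent with a free intercept). Defaults:
p0 = 0.5, seven transfers, four replicates.

What the simulator deliberately does not emulate: behaviorally structured
transfer bias (e.g. bordering animals being under-sampled by washing),
plate-to-plate environmental covariates, ddPCR pipetting/threshold
artifacts, and any frequency dependence of fitness. Passing recovery tests
therefore shows the estimator is calibrated *under the stated stochastic
model* — drift plus counting noise — not that real experiments are free of
systematic transfer bias.

## Parameter recovery and calibration

`parameter_recovery_experiment` simulates and refits complete experiments
and reports mean bias, RMSE and empirical 95% CI coverage of ŝ. At the
default study conditions, 200 experiments per effect size across
s_true ∈ {0, 0.10, 0.17, 0.30, 0.61} give |bias| < 0.01 at every level and
pooled coverage ≈ 0.94; coverage of a 95% interval estimated from 200
replicate experiments has Monte-Carlo sd ≈ 0.015, which is why calibration
claims in the test suite either pool across effect sizes (1000 CIs) or use
500 experiments. These problem sizes keep the whole suite and the
acceptance script in the seconds-to-a-minute range while leaving
Monte-Carlo error well below the tolerances being asserted.

## Consumption normalization

Control wells (bacteria, no animals) follow F0 = β · F18 with no
intercept, so β is estimated by least squares through the origin,
β = Σ F0·F18 / Σ F18² — for a single control well this reduces to the
ratio F0/F18. A with-intercept variant is available for diagnosing
additive background, but the origin-constrained fit is the default because
the decay model itself has no intercept. Test-well consumption is
F0 − β·F18 in fluorescence units; negative values are reported, never
clipped, so downstream group means stay unbiased. Both β and consumption
are scale-equivariant in the expected way (gain changes cancel in β).
The liquid assay summarizes OD600 series as daily first differences and
cumulative clearing, erroring on non-contiguous day series.

## Behavioral metrics and statistics

Bordering fraction = animals within 1 mm of the lawn edge / animals
scored, at a single timepoint; exploration fraction = grid squares with
tracks / 105 (the full-plate grid). Group comparisons are thin
orchestration over scipy and statsmodels: one-way ANOVA with Tukey HSD
(the only multiplicity adjustment applied, matching how multi-strain
panels are analyzed), exact-capable Mann-Whitney for pairs, Friedman for
matched blocks. Fully tied Friedman blocks return the conventional zero
statistic rather than scipy's NaN. Roaming/dwelling scoring has no stated
formula at the source and enters only as pre-scored values.

## Numerical choices and edge cases

- Frequency prediction works on the log-odds scale (logit0 + t·log w) to
  avoid overflow of wᵗ; p0 ∈ {0, 1} is returned exactly (absorbing).
- All randomness flows from one integer seed; the CLI derives per-stage
  substreams via `numpy.random.SeedSequence`, so identical seeds give
  byte-identical output files (floats are serialized with `repr` for
  lossless round trips).
- Readers tolerate comma- and tab-separated dialects and `#` metadata
  lines; validation errors name 1-based data rows.

## Known limitations

- The replicate-t CI assumes replicate slopes are approximately normal;
  with two replicates the interval is valid but very wide.
- The raw-ratio estimator inherits a small deterministic occupancy bias;
  at the default occupancy it is negligible relative to drift noise, but
  users running saturated reactions should use the Poisson-corrected
  estimator.
- s = w − 1 is one of several conventions for the selection coefficient;
  comparisons to sources that use s = log(w) (≈ w − 1 only for small s)
  should convert explicitly, especially at s ≳ 0.3.
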