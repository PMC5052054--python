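# Methods

This note documents the models implemented in `wormcycle`, their
assumptions, the tunable parameters and their defaults, what the
simulators do and do not emulate, and the numerical choices that matter.

## Stage grid and embryo-age distributions

Development is discretized onto a uniform grid of standard stages,
30 min apart by default (`stages.stage_grid`).  A bulk sample collected
`t` minutes into an experiment is modelled as a population of embryos
whose ages are Gaussian with mean `t0 + g·t` and variance `σ0² + v·t`:

* `t0` — initial mean developmental age of the population (minutes);
* `g` — growth rate relative to the standard clock (dimensionless);
* `σ0²` — initial variance of the stage distribution (minutes²);
* `v` — growth of that variance per minute of experiment (min²/min).

The Gaussian is discretized by integrating over stage bins; the first
and last bins extend to ±∞, so mass outside the grid is absorbed at the
boundaries and every composition row sums to one exactly.  Zero
variance produces a point mass on the bin containing the mean.  The
Gaussian family is an assumption: any unimodal age distribution with
drifting mean and growing spread would serve, and the Gaussian is the
minimal two-moment choice.

## Phase 1 — staging

Observation model, for inference gene `g` in sample `j`:

```
log x_gj ~ Normal( log( Σ_k w_jk(θ) E_gk ),  σ_g² )
```

with `θ` the staging parameters of the sample's series and `E` the
per-gene stage profiles.  Inference genes are the most highly expressed
(by mean dcpm across all samples; default ¾ of genes in the validation
runs — in a genome-scale run a few thousand).  The sampler alternates

1. vectorized per-stage random-walk updates of `log E` across all genes
   at once (adaptive step sizes, target acceptance 0.35);
2. conjugate inverse-gamma Gibbs updates of `σ_g²`
   (prior IG(2, 0.08) — weak, prior mean σ ≈ 0.28 on the log scale);
3. adaptive scalar Metropolis–Hastings updates of each staging
   parameter (target acceptance 0.3).

Priors: the model has two exact or near symmetries that data cannot
resolve — a common *stretch* of all clocks (all `g`, `t0` scaled,
profiles re-indexed) and a common *translation*.  Both are anchored by
priors: `g ~ lognormal(0, 0.25)` (replicate cultures grow near the
standard rate) and `t0 ~ Normal(grid start + ½ step, 20 min)`, bounded
by the grid span (the standard clock's origin is defined by where the
series start).  Variances get half-normal priors (scales 400 min² and
2 min²/min) with log-parameterization Jacobians.  The profile
smoothness prior penalizes squared second differences of `log E` with
scale 2.0 per stage step — deliberately weak, because a strong profile
prior biases composition widths upward (smooth profiles and wide
mixtures are partially exchangeable explanations of smooth data).

Chains are started from a coordinate-ascent warm start (greedy profile
sweeps alternating with 1-D conditional optimization of each staging
parameter, multi-started from narrow and wide composition widths, with
a final joint rescan of each series' (t0, g) against near-point-mass
compositions).  Without it, chains stall in smooth-profile/wide-width
modes.  Split-R̂ per parameter is reported; values above 1.1 set
`converged=False` on the series model (flagged, not fatal).

Known limitation: with ~12 samples per series and fully free profiles,
the composition *width* parameters (`σ0²`, `v`) are weakly identified;
on some data realizations the fitted widths are too narrow and the
worst-sample composition error grows to ~0.2 total-variation distance,
even though growth rates stay within a few percent.  More samples per
series, or replicate samples at the same time point, resolve this.

## Phase 2 — deconvolution

With compositions fixed at their posterior medians, each gene's stage
profile is re-sampled under the same lognormal likelihood, now for all
genes (not only inference genes).  Differences from phase 1: the
smoothness prior becomes Student-t (4 degrees of freedom, scale 0.5)
on second differences of `log E` — Gaussian-like regularization for
ordinary curvature, but a saturating penalty at genuine corners such as
expression collapsing to the detection floor, which a quadratic penalty
would flatten even against a decisive likelihood (the noiseless
identity limit exposes this as a slowly growing bias);
observed dcpm is floored at 1e-3 (a detection floor: exact zeros would
otherwise put unbounded log-residuals into the fit, and values this
small are unmeasurable anyway); the noise prior is IG(1, 1e-4) so the
noiseless limit can shrink σ to ~0; σ² is initialized from the
back-projection residuals (a fixed large initialization lets the
smoothness prior erode sharp profiles before the noise level calibrates,
a runaway that ends in a prior-only fit).  Posterior means and central
credible intervals (default 95%) per stage form the unified series.
Stages receiving total composition weight < 0.01 across all samples are
reported as unidentified.

Regulation calls between adjacent stages: *up* when the lower credible
bound at stage k+1 exceeds the upper bound at stage k **and** the
posterior-mean fold change is ≥ 1.5 (the fold filter is a package
choice; set `min_fold=1` to disable); *down* symmetric.

Pseudotime-to-minutes calibration is a least-squares affine fit to
anchor samples (`calibrate_time`), mirroring anchoring a relative clock
to an external reference series.

## Change-point detection

Unified trajectories (log1p scale by default; raw via
`RjmcmcConfig(log_scale=False)`) are modelled as continuous
piecewise-linear with K ≤ 3 knots on interior grid points:

```
y_i = a + b·t_i + Σ_j c_j (t_i − τ_j)+ + ε_i,   ε ~ N(0, σ²)
```

Coefficients carry `N(0, σ²·v·I)` with `v = 100` on internally
standardized axes, and `σ² ~ IG(1, 0.01)`; both are marginalized
analytically, so the reversible-jump sampler moves only over knot sets
with birth (0.3) / death (0.3) / move (0.4) proposals and an exponential
prior `p(K) ∝ e^(−λK)`, λ = 1, knot sets uniform within K.
Standardization makes the K posterior invariant to shifting/scaling
either axis.  `v = 100` matters: a tighter coefficient prior shrinks
steep slopes and the model compensates with spurious knots.

Point estimates: K̂ is the argmax of the marginal K posterior, and the
knot configuration is the most-visited one of that size — a plain
most-visited-configuration argmax undercounts large K because its mass
splits over neighboring knot sets.  On a 20-point grid the
configuration space is small enough to sum exactly;
`enumerate_posterior` does so and is the reference the sampler is
validated against.  Birth/death acceptance rates are reported and sit
in (0.05, 0.6) under the defaults.

## Junction analytics

* **Filter**: observed (≥ 2 spanning reads) in ≥ 2 samples, and — within
  a gene with other junctions — aggregate reads ≥ 1% (inclusive) of the
  mean aggregate of the *other* junctions.  Single-junction genes pass
  the relative rule vacuously; intergenic junctions face only the
  sample rule.  The per-sample detection cutoff of 2 reads is a stand-in
  for an upstream per-sample FDR call.
* **Pairs**: at each shared donor/acceptor site, the top junction by
  total reads is the major form (ties: shorter intron, then
  coordinate); every other junction yields one (minor, major) pair.
  A minor form is *rare* when ≤ 100 total reads **and** ≤ 5% of its
  major form.
* **Usage runs**: ρ = minor/(minor+major) per sample (undefined at zero
  coverage — counted as an exception, never a pass).  A run starts and
  ends on passing samples (ρ > 0.85 for high, ρ < 0.15 for low),
  contains ≤ 2 exceptions, and is maximal; runs are ranked by length
  then mean excess beyond the threshold, top two per direction.
  Eligibility: ≥ 10 minor spanning reads and minor ≥ 1% of major.
* **Junction-seeded models**: exons grow outward from orphan-junction
  flanks while coverage ≥ 0.01 dcpm (the intergenic block threshold,
  reused); junctions with overlapping grown exons chain into one
  fragment; the spliced sequence is screened for its longest
  ATG-initiated ORF (strand from GT..AG dinucleotides when
  recognizable, otherwise both strands); > 80 aa flags a coding
  candidate.

## Operons

R = SL2/(SL1+SL2) per gene per time point (undefined at zero total SL,
propagated as missing and skipped, never imputed).  Second genes with
mean dcpm ≥ 0.1 over the first seven time points are ranked by mean R
over the same window and split into 8 equal bins (remainder to the last
bins).  TSS metaprofiles average strand-oriented signal over TSS ± 500
bp (the TSS base opens the downstream half; chromosome-edge windows are
trimmed with per-position weight correction).  Per-bin structure stats:
mean gene1→gene2 distance, and mean per-operon Pearson correlation of
first/second gene expression (≥ 3 finite sample pairs required).

## Pervasive transcription

Blocks are maximal runs of intergenic bases at ≥ 0.01 dcpm (inclusive)
strictly longer than 200 bases; in multi-sample mode a base counts when
above threshold in ≥ `min_shared` samples.  Windows tile each
chromosome from coordinate 0 (default 80 kb; a ragged final window is
kept if at least half-length); per window and annotation class
(precedence coding > noncoding > intergenic) the dcpm is the mean depth
over that class's bases scaled by mapped reads per million.  The
intergenic vector is permuted 1000 times within the chromosome;
Z = (ρ_obs − mean ρ_perm)/sd ρ_perm, with an add-one empirical
two-sided p.  Spearman uses average ranks, so the statistic is
invariant to monotone transforms.

## Histones

Families must be aligned and length-matched (no-indel model; histone
paralogs are length-conserved — indels raise an error).  Discriminating
bases are positions where ≥ 2 copies differ; copies identical over the
whole gene are an equivalence class.  A read is assigned to the copies
whose subsequence it matches exactly: one copy → unique; k copies → 1/k
each, kept as exact rationals so total mass is conserved bit-for-bit;
zero copies → excluded as a mismatch and tallied.  Read fractions are
reported separately for unique and ambiguous mass.  Cluster patterns:
*maternal* if the first time point is already ≥ 50% of peak, *zygotic*
if it is < 10% of peak with the peak inside 150–350 min, else *other*
(thresholds configurable; they encode "deposited in the oocyte" vs
"induced during the cell-proliferation phase").

## Simulators

`synthetic_data` generates every input with known truth: mixed-stage
expression series (archetype programs — 25% maternal, 30% zygotic, 15%
flat, 30% generic piecewise-linear in log1p space with 0–3 knots;
amplitudes lognormal over ~4 orders of magnitude; multiplicative
lognormal noise, default sd 0.2); junction tables with designed
minor-fraction trajectories (constant-low, maternal-minor, late-minor,
mid-minor, balanced) and Poisson counts; an annotated genome with
operons (12% carry internal promoters: boosted SL1 at gene 2, +700 bp
gene1→gene2 gap, decorrelated expression), single and noncoding genes,
intergenic background whose rate couples to local coding expression
(coupling 0 gives a calibrated null), chromatin peaks at promoters, and
histone clusters of near-identical copies; and reads drawn from
families at known copy proportions.  The default three-series design
(growth 0.9/1.0/1.15, t0 20/0/10 min, σ0 12–18 min, 12 samples at
45-min spacing over a 20-stage grid) is the package's standard
validation condition.

Not emulated: read-level sequencing error and alignment artifacts,
fragment-length and positional coverage biases, isoform structure
beyond junction pairs, batch effects between library protocols, and
genuine biological covariance between genes.  Passing recovery tests
therefore demonstrates correctness of the inference under the stated
generative assumptions, not robustness to every real-data pathology.

## Validation sizes and determinism

The test suite and `scripts/acceptance.py` run the samplers at reduced
budgets chosen to converge at the validation problem sizes: staging on
3×200 genes with 2 chains × (400 burn-in + 1200 kept, thin 2);
deconvolution 1 chain × (600 + 1500, thin 3) — the noiseless identity
check uses 1000 + 2500 to reach its 1% tolerance; change points 800 +
3000 per gene with per-gene marginal-likelihood memoization.
`McmcConfig` defaults (4 chains, 5000 + 20000, thin 5) are sized for
production-scale runs.  All randomness flows through
`numpy.random.default_rng` seeded per component, so every pipeline
output is bit-reproducible for a given seed.
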