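# wormcycle

Bayesian staging and deconvolution of bulk embryo RNA-seq time courses,
with the downstream analytics of a whole-life-cycle *C. elegans*
transcriptome study — change-point detection, splice-junction usage,
operon internal-promoter inference, pervasive-transcription statistics
and histone-family read assignment — plus a ground-truth simulator that
makes every stage testable end to end.

## The problem

Bulk RNA-seq of "synchronized" embryo populations is never actually
synchronous: each sample is a mixture of developmental stages whose mean
age drifts and whose spread grows over the experiment.  Given several
replicate time series collected on slightly different clocks, we want
(i) each series' staging parameters — initial mean age `t0`, growth rate
`g` relative to a standard clock, initial stage-distribution variance
`σ0²` and its growth rate `v` — and (ii) the expression of every gene at
every *stage*, not every sample.

The observation model is a composition-weighted mixture with lognormal
noise:

```
w_jk  = discretized N(t0 + g·t_j,  σ0² + v·t_j)  over stage bins k
log x_gj ~ Normal( log Σ_k w_jk E_gk ,  σ_g² )
```

Phase 1 samples the staging parameters jointly with the per-gene stage
profiles `E` (Metropolis–Hastings, profiles on the log scale under a
smoothness prior, conjugate noise updates).  Phase 2 fixes the
compositions and deconvolves all series into a unified per-gene
per-stage posterior with credible intervals, from which up/down
regulation between adjacent stages is called.  Unified trajectories are
then summarized by reversible-jump MCMC over continuous piecewise-linear
models with K ≤ 3 change points (exponential prior on K, coefficients
and noise marginalized analytically).

Around this core sit the study's other bespoke statistics: dcpm
quantification (depth of coverage per base per million mapped reads),
the splice-junction filter and minor/major usage-run scan
(ρ = minor/(minor+major), runs above 0.85 / below 0.15 with ≤2
exceptions), SL2/(SL1+SL2) ranking of operon second genes into equal
bins, above-threshold intergenic block finding, permutation Z-scores
for 80-kb window correlations, and exact-match read assignment among
near-identical histone gene copies.

## Worked example

The `analysis/` scripts run the whole study on simulated data with
known truth (all output below is printed by the scripts):

```
python analysis/01_simulate.py --seed 11     # series, junctions, genome
python analysis/02_quantify.py
python analysis/03_unify.py --seed 11
python analysis/04_changepoints.py --seed 11
python analysis/05_junctions.py
python analysis/06_operons.py
python analysis/07_pervasive.py --seed 11
python analysis/08_histones.py --seed 11
```

Staging and deconvolution (`03_unify.py`) recover the generator's
parameters — the three series were simulated with growth rates
0.9 / 1.0 / 1.15 and start ages 20 / 0 / 10 min:

```
series0: growth=0.904 t0=20.0 min sigma0^2=293 var_rate=0.32 (worst-sample composition TV 0.046)
series1: growth=1.005 t0=-0.7 min sigma0^2=194 var_rate=0.23 (worst-sample composition TV 0.046)
series2: growth=1.153 t0=9.9 min sigma0^2=412 var_rate=0.32 (worst-sample composition TV 0.035)
deconvolution: Pearson r = 0.981 vs truth over 128 well-expressed genes
```

i.e. growth rates within ~0.5%, per-sample stage compositions within
total-variation distance 0.05 of the truth, and unified stage
expression correlating at r = 0.981 with the hidden stage programs.
Downstream, `06_operons.py` shows the internal-promoter signal the
SL-ratio binning is designed to find (fraction of truly
internal-promoter operons per SL2 bin, lowest bin first):

```
internal-promoter fraction per bin: [0.79, 0.29, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
bin 0 vs bin 7: mean gap 670 vs 120 bp, expression correlation 0.54 vs 0.97
```

and `07_pervasive.py` detects the designed coupling of intergenic
background to coding expression (`chr1 intergenic~coding: rho=0.736
Z=2.64 p=0.0060`).

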