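# stresstiming

Timing statistics for single-cell stress responses in bacterial
microcolonies.

When a stressor hits a growing microcolony, each cell switches on
stress-response genes at its own moment.  `stresstiming` quantifies that
timing from tracked time-lapse fluorescence data and interprets it with
statistical kinetics: the ratio of the standard deviation to the mean of
single-cell response times, σ_t/μ_t, bounds the number of rate-limiting
molecular steps n between stress and response from below,

    σ_t / μ_t ≥ 1 / √n,   i.e.   n ≥ (μ_t/σ_t)²,

with equality for a linear chain of equal-rate memory-less steps, whose
completion times are Erlang(n) distributed.  A tight response (ratio
0.165) implies dozens of steps; a noisy one (ratio 0.54) only a few.  For
promoter *pairs* measured in the same cells, subsample-averaged Pearson
correlations and a strict-temporal-order permutation test distinguish
serial architectures (both responses on one causal chain: strict order,
correlated times) from parallel ones (independent chains: neither).

The package is aimed at quantitative microbiologists analysing
segmented-and-tracked microcolony movies (one table row per cell per
frame) and at modellers studying completion-time statistics.  It covers:

* **synthetic data** (`chains`, `colony`) — microcolony lineage trees of
  exponentially growing, dividing cells; latent activation times from
  serial/parallel chain models; rendered fluorescence with maturation,
  photobleaching, autofluorescence and noise, plus ground truth.
* **preprocessing** (`traces`) — trace-table I/O and validation,
  background/autofluorescence correction, normalisation, growth-rate and
  cumulative-doubling series.
* **response times** (`response`) — colony-threshold (25% of the
  responder-median range) and per-cell half-max measures, responder
  classification, non-responder exclusion.
* **lineage statistics** (`lineagestats`) — one-trajectory-per-founder
  subsampling, bootstrap errors, paired correlations, strict-order
  permutation test with exact enumeration for small colonies.
* **kinetics** (`kinetics`) — randomness parameter R = (σ_t/μ_t)²,
  step-count bounds, maximum-likelihood Erlang fits, simulated
  Kolmogorov–Smirnov consistency, precision-limit line.
* a thin **CLI** (`stresstiming simulate|preprocess|respond|stats|kinetics|run`)
  over the library for shell pipelines.

## Worked example

Simulate a colony whose founder lineages activate after an 8-step chain
with mean 3 h, then recover the timing statistics
(`examples/03_response_times.py`):

```python
from stresstiming import (ChainSpec, ReporterSpec, SimConfig, StatsConfig,
                          compute_expression, generate_dataset, response_times)
from stresstiming.pipeline import channel_summary

config = SimConfig(n_founders=25, seed=8, chain=ChainSpec(n_steps=8, mean_time=3.0),
                   reporters={"yfp": ReporterSpec(maturation_time=10/60, decay_rate=3.0,
                                                  noise_sd=0.3, autofluorescence=2.0)},
                   background={"yfp": 1.5}, post_stress_duration=9.0)
table, truth, _ = generate_dataset(config)
expr = compute_expression(table, autofluorescence={"yfp": 2.0})
rt = response_times(expr)
summary = channel_summary(table, rt, "yfp", StatsConfig(seed=1))
```

prints

```
mu_t = 2.94 +/- 0.16 h, sigma_t = 1.02 +/- 0.10 h (41 founders)
timing ratio sigma_t/mu_t = 0.347
ground truth: latent mean 2.69 h, sd 1.02 h
```

The detected mean exceeds the latent mean by the constant reporter offset
(maturation plus threshold rise, ≈ 0.25 h here) while the spread matches
the generator's; the ratio 0.347 gives ⌈1/0.347²⌉ = 9 ≈ 8 rate-limiting
steps.  `examples/04_dual_reporter_order.py` runs the dual-reporter
comparison and prints, for the same seeds,

```
  serial: r = +0.81 +/- 0.00, ordered fraction = 1.00, permutation P = 0.000
parallel: r = +0.02 +/- 0.00, ordered fraction = 0.70, permutation P = 0.712
```

— the serial architecture shows strict order in every cell with strongly
correlated times; the parallel one shows neither.  Each script in
`examples/` is a short, runnable walk-through of one capability.

The same pipeline runs from the shell:

```sh
stresstiming run --config examples/demo_config.toml --out results/demo --seed 3
```

writing TSV tables (traces, expression, response times, timing summaries)
and a JSON kinetics report stamped with the config hash and seed;
rerunning with the same config and seed reproduces every artifact byte
for byte.

## Documentation

`docs/methods.md` describes the model, the detection and subsampling
procedures, the synthetic-data generator and its limitations, and the
numerical conventions.
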