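# Methods

## The scientific problem

When a microbial population meets a sudden stress, different gene-expression
responses switch on at different times, and the same response fires at
different times in different cells.  Two quantities organise this
variability for a promoter under a given stress: the mean response time
μ_t (hours after stress addition until a reporter crosses a detection
threshold) and its cell-to-cell standard deviation σ_t.  This package
implements the timing analysis end to end: extracting response times from
tracked microcolony fluorescence traces, summarising them with
lineage-aware statistics, comparing two reporters within the same cells,
and interpreting the dimensionless ratio σ_t/μ_t with statistical
kinetics.

## Statistical-kinetics model

A response is modelled as the completion of a chain of discrete molecular
steps triggered at stress addition (uptake of the stressor, transcription
factor activation, transcription initiation, accumulation of enough mature
reporter to detect, ...).  Each step is memory-less, i.e. has an
exponentially distributed waiting time.  For a linear chain of n
equal-rate irreversible steps the completion time is Erlang(n)
distributed — a gamma distribution with integer shape — with

    σ_t / μ_t = 1 / √n        (equality for the ideal chain)

and, for arbitrary topologies with reversibility, branching or feedback,

    σ_t / μ_t ≥ 1 / √n.

The *randomness parameter* R = (σ_t/μ_t)² therefore bounds the number of
rate-limiting steps from below: n ≥ 1/R.  The package reports n_min = 1/R
and the integer estimate ⌈1/R⌉ (the bound rounds up).  Two corollaries are
used as checks throughout:

* **upper bound** — at least one step always exists, so σ_t ≤ μ_t for any
  response generated this way;
* **precision limit** — across promoters, the smallest observed σ_t/μ_t
  defines a line σ_t = c·μ_t through the origin below which no response
  falls.  `slope_in_minutes` expresses c as minutes of timing spread
  gained per hour of mean delay.

Model adequacy is checked rather than assumed: `fit_erlang` fits a gamma
distribution by maximum likelihood with the location fixed at zero, rounds
the shape half-up to an integer (the rounding direction is a convention;
half-up is used) and re-solves the scale at that shape (scale = mean/shape,
the ML solution for fixed shape).  `ks_consistency` then simulates many
datasets of the same size from the fitted integer-shape gamma and reports
the fraction that a two-sample Kolmogorov–Smirnov test at α = 0.05 cannot
distinguish from the data.  Because the fit absorbs part of any
discrepancy before the test is run, this consistency fraction is
optimistic; it is reported as a descriptive adequacy measure, not a
calibrated p-value, and no correction is attempted.

## Response-time detection

Expression is total cell fluorescence divided by cell area, minus the
per-pixel background outside cells and minus autofluorescence (a constant,
or — when autofluorescence drifts — the per-frame mean of control cells
lacking the fluorophore).  Corrected expression may be negative and is not
clamped: clamping at zero would bias threshold crossings near zero
upward.

The primary response-time measure is colony-based.  Within a microcolony
and channel, trajectories whose maximum post-stress expression exceeds
`responder_fold` (default 3×) their baseline are classed as fold-change
responders; the baseline is the mean pre-stress expression floored at a
small ε (default 10⁻⁶ expression units) because autofluorescence
subtraction can leave baselines at or below zero.  The threshold is the
post-stress minimum of the pointwise-median trace over these responders
plus `threshold_fraction` (default 25%) of that median trace's post-stress
range.  A trajectory's response time is its first post-stress upward
crossing of the threshold, linearly interpolated between the bracketing
frames by default (`interpolation="frame"` reproduces frame-resolution
readout; a value exactly at the threshold returns that frame's time).  The
first crossing is used with no persistence requirement.  Trajectories that
never reach the threshold are flagged as non-responders, counted in the
responder fraction, and excluded from timing statistics.  The alternative
per-cell measure (`measure="halfmax"`) uses half of each trajectory's own
post-stress maximum.  Response times can be expressed in hours or in
cumulative cell doublings (`time_axis="doublings"`), which normalises away
cell-to-cell growth-rate differences.

Growth rates are Δlog(size)/Δt between frames, smoothed with a centered
moving average of window 3; cumulative doublings come from log2(area) made
continuous across divisions by linearly extrapolating the last 3
pre-division points (the count is configurable; the source procedure
leaves it unquantified), anchored to 0 doublings at stress addition and
smoothed with window 5.  Moving-average windows shrink *symmetrically* at
series edges so the filter stays unbiased on linear trends.

## Lineage-aware statistics

A tracked microcolony is a forest of lineage trees; every cell present at
stress addition (a *founder*) gives rise to many descendants whose
response times are strongly correlated.  Treating each final cell as
independent would understate variance and overstate significance.  All
statistics therefore operate on *subsamples*: one random root-to-leaf
trajectory per founder, choosing uniformly among the two daughters at
every division (equivalently, sampling leaves with probability 2^-depth),
repeated S times (default 1,000).

* `timing_summary`: μ_t is the average over subsamples of per-sample
  means, σ_t the average of per-sample standard deviations (ddof = 1).
  Standard errors come from B (default 1,000) bootstrap replicates that
  resample founders with replacement, recompute the per-sample statistics
  and average over subsamples.  The bootstrap nesting (founder-level,
  within subsamples, averaged across them) is one of several defensible
  readings of the source procedure and is the package's convention.
* `paired_correlation`: per subsample, Pearson's r and its two-sided
  p-value over founders with both channels' times present; reported are
  the mean and sd of r over subsamples and the median p.  Samples with
  fewer than three complete pairs or zero variance are skipped with a
  warning.
* `strict_order_test`: the statistic is the number of founders with
  t_B > t_A (ties count as non-ordered).  Per subsample, channel-B times
  are randomly re-paired with channel-A times across founders and the
  fraction of pairings at least as strictly ordered as observed is
  recorded; the p-value is the mean of those fractions over subsamples.
  For ≤ 7 founders all m! pairings are enumerated exactly instead of
  Monte-Carlo sampling (m! ≤ 5,040); the "at least as strict" comparison
  defines the one-sided test.

Subsampling, bootstrap and permutation randomness are independent
substreams derived from one seed, so every result is reproducible.

## Synthetic microcolonies

The generator provides ground truth for every stage.  It emulates:

* **growth and division** — each cell elongates exponentially at a
  per-cell rate drawn from a normal truncated at zero (the field standard
  in the absence of a stated distribution) and divides into two
  equal-sized daughters on reaching `division_size_ratio` (nominally 2)
  times its birth size, perturbed lognormally.  The n_founders initial
  cells are born at −pre_stress_duration with a uniformly random
  cell-cycle phase; cells dividing before time zero make both daughters
  founders, so the founder count can slightly exceed n_founders.
* **latent activation times** — one completion-time draw per founder from
  a `ChainSpec` (single channel) or `DualChainSpec` (two channels, serial
  or parallel architecture), inherited by all descendants.  Optional
  per-division Gaussian jitter models imperfect inheritance; its magnitude
  has no empirical anchor and defaults to zero.  Treating activation as a
  founder-lineage property matches the subsampling unit of the analysis.
* **reporter optics** — mature reporter accumulates at
  `production_rate × area` once activation plus `maturation_time` has
  passed (≈ 10 min for YFP/CFP-class proteins, ≈ 40 min for mCherry-class),
  optionally decays at first order (`decay_rate`, see below), is split
  between daughters in proportion to their (equal) sizes — conserving
  total signal and matching dilution-by-growth physics — and loses
  `bleach_per_frame` of its amount at each imaging event (≈ 3% per frame
  is a realistic worst case for YFP; over 40 frames that leaves
  0.97⁴⁰ ≈ 30%).  Emitted totals add (autofluorescence + trend·t +
  per-pixel background) × area and Gaussian noise; noise on totals is the
  simplest model adequate for exercising the threshold logic (shot-noise
  refinements are out of scope).  No bleaching correction is applied in
  preprocessing, matching common practice for rising signals.

With turnover λ = `decay_rate`, per-area expression after activation
follows the universal curve e(τ) = (r/(g+λ))·(1 − e^{−(g+λ)τ}) for every
cell, so the 25%-threshold crossing trails the latent activation time by
the exact constant −ln(0.75)/(g+λ) (plus maturation).  This matters for
parameter recovery: with dilution-only kinetics (λ = 0) the rise rate is
the growth rate g alone and the constant detection delay ≈ 0.29/g h
inflates the inferred mean response time — and hence the inferred step
count ⌈(μ/σ)²⌉ by a factor (1 + Δ/μ)² — substantially at realistic growth
rates.  Recovery experiments therefore use a reporter whose observable
rise is fast compared with the latent-time spread (λ ≈ 3/h, i.e. full
response within ≈ 1 h, as real stress-response traces show); the residual
delay (≈ 5 min) is the documented reporter offset that round-trip tests
subtract.  Real stable fluorescent proteins correspond to λ = 0, in which
case the inferred step count deliberately includes reporter-accumulation
steps, exactly as in real experiments.

What the generator does **not** emulate: spatial colony geometry and
signal diffusion between neighbours, image formation and segmentation
error, plasmid copy-number fluctuation, intrinsic bursting of the reporter
(activation is a single latent time per lineage), and growth-rate changes
after stress.  Passing tests on synthetic data therefore validate the
*statistical machinery* — detection, subsampling, bootstrap, permutation
and kinetics arithmetic — not robustness to those real-data artefacts.

## Numerical conventions and degenerate inputs

* Threshold crossing: linear interpolation between bracketing frames;
  exact hits return the frame time; first crossing wins.
* Step counts: ⌈1/R⌉ with a 10⁻⁹ guard against floating-point ceilings;
  σ_t = 0 yields a flagged unbounded estimate rather than a number.
* Gamma fitting requires ≥ 10 strictly positive, non-identical times.
* `timing_summary` requires at least one subsample with ≥ 2 responding
  founders; subsamples below that are skipped.
* All stochastic procedures take explicit seeds; simulation, activation,
  rendering, subsampling, bootstrap and permutation use independent
  seed-sequence substreams.

## Default problem sizes

The test suite and worked examples use microcolonies of 6–300 founders
simulated over 4.5–10 h at 10–15 min frames, 100,000–200,000 draws for
distribution-level recoveries, and the full S = B = 1,000 replicates for
subsampling and bootstrap where the procedure's defaults are exercised.
These sizes give Monte-Carlo errors comfortably below the tolerances
asserted while keeping the suite fast.

## Known limitations

* The KS-consistency fraction inherits the fit-then-test optimism noted
  above.
* The sample estimate of σ_t/μ_t sits exactly at 1 for a single-step chain
  with no reporter offset, so the empirical σ_t ≤ μ_t check is run on
  response sets that include a positive detection offset, as every
  rendered response does.
* Published error bars of the source analyses (e.g. on correlation
  coefficients) depend on raw data that are not redistributable; the
  procedures that produced them are implemented and exercised on synthetic
  data instead.
* The founder of a trajectory is identified from frame times alone (first
  cell with a frame at or after time zero); a cell that is alive at time
  zero but whose frames all fall before it is attributed to its child.
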