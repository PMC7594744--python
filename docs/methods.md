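# Methods

## Exit-time estimation

Each cell's reporter time course is fitted by unweighted least squares
to the four-parameter logistic decay

    I(t) = lo + (hi − lo) / (1 + exp((t − τ) / k)),

with `hi ≥ lo ≥ 0` and steepness `k > 0` enforced by bounds. The exit
time τ is the inflection of this curve, which for a logistic is exactly
the midpoint parameter. "First inflection" could in principle also be
read as the decay *onset*; since a logistic has a single inflection we
take the midpoint as the definition and expose the onset reading
(τ − 2k) as `SigmoidFit.onset` for sensitivity analyses, never as the
default.

Initialization: `hi` from the first three samples, `lo` from the last
three, τ at the first half-crossing, `k` at 10% of the time span.
`sigma_tau` is the square root of the τ entry of the Jacobian-based
parameter covariance at the optimum; a singular covariance yields
`sigma_tau = ∞`, which the filter always discards. Non-convergence is
reported as a flag, never an exception, so one bad cell cannot abort a
batch.

The quality filter keeps a fit iff it converged, `sigma_tau <
max_ratio · τ` (default `max_ratio = 1`, i.e. an error of fit on the
order of τ itself disqualifies the cell), and τ lies inside the
observed time window. Shrinking `max_ratio` can only shrink the kept
set (tested property). Trajectories need at least 6 samples; fewer is
an error, since a 4-parameter fit on fewer points is meaningless.

## Division–exit coupling

The *latest division* of a cell is the largest division time at most
`grace = 2.5 h` after τ; the grace window absorbs the uncertainty in τ
itself. Cells with no qualifying division are excluded from the
regression and counted in the report. When two divisions both qualify,
the later one is taken. Exit-versus-division coupling is the R² of the
OLS regression of τ on latest division time.

The null is a reassignment bootstrap: in each of `n_boot = 1000`
replicates, every τ_i is re-paired with the division time(s) of an
independently, uniformly drawn cell j (with replacement; j = i
allowed); where cell j has two divisions, the one *closest to τ_i* is
used. The observed-data rule (latest + grace) and the replicate rule
(closest) are deliberately kept distinct — they are stated separately
in the measurement protocol the pipeline mirrors. The empirical p is
the one-sided raw exceedance fraction `#{R²_boot ≥ R²_obs} / n_boot`;
a `(1 + count)/(1 + n_boot)` corrected variant is available by flag.
The bootstrap is fully vectorized (replicates × cells index matrix),
so 10⁶ replicate regressions run in seconds.

A selection effect worth knowing about: if τ is independent of division
times *and* some divisions can fail the grace window, the exclusion
rule truncates the retained sample toward positive coupling, making the
test anticonservative. This does not arise in the regime the pipeline
is built for — cells that exit after a division, so a qualifying
division essentially always exists — and the test suite documents both
the calibrated regime (type-I rate ≈ 5% when all divisions qualify) and
the truncated one.

Exit classification relative to divisions uses ±4 h windows around the
first and second division ("between" otherwise; a τ within both windows
goes to the nearer division, exact ties to the second), and the
cell-cycle stage splits at 12 h: a first division strictly more than
12 h after the trigger means exit was triggered early in the cycle; a
first division exactly at 12 h counts as late-cycle (tie rule).

## Sister statistics

All curves are first normalized so their first sample is 1, removing
cell-to-cell differences in absolute reporter expression. The *global*
variance is the across-cells variance at each time point, averaged over
time; the *local* (pair) variance is the same quantity computed between
the two sisters of a pair. Both use the population (divide-by-n)
convention, so a sister pair and a two-cell population give identical
numbers — the two statistics are compared directly as a fold-ratio
(global / mean pair), and mixing conventions would bias that ratio by
construction (the constant-curves test would catch it). Whether the
original analysis used n or n−1 is not stated; the population
convention is our documented choice. For cells that exit at the first
division and then divide again, pair variance is computed on the grid
truncated at the next division.

Random-pair |Δτ| baselines draw uniformly among distinct unordered
non-sister pairs, without repetition, with the number of random pairs
defaulting to the number of sister pairs; distributions are compared by
a two-sided Mann–Whitney rank-sum test. Asymmetry correlations use the
smaller/larger daughter volume ratio against the identically ordered
exit-time ratio (or the ratio of reporter decrease over the 6 h after
division), as a Pearson correlation; zero variance in either variable
is flagged as undefined rather than raised.

## Bridge kinetics

Bridge width from cytokinesis end follows

    w(t) = w_∞ + (w_0 − w_∞) · exp(−t / τ_c),

fitted per bridge by bounded least squares (`w_0, w_∞ ≥ 0`, `τ_c > 0`).
The plateau w_∞ reflects the finite widths electron microscopy shows
for mature bridges; a pure exponential is the `w_∞ = 0` special case,
which can be pinned (`fix_winf`) for sparse traces (< 6 points) where
three free parameters overfit. Constant traces and traces with fewer
than 4 points are errors.

The between-condition comparison is implemented twice because the
statistical test behind the published p < 0.0001 is unstated:

* **F test (default)**: extra sum of squares on the pooled point
  clouds, null = per-condition amplitudes with one shared τ_c
  (5 parameters), alternative = separate τ_c (6 parameters);
  F(1, N−6). This matches standard curve-fitting practice for nested
  models.
* **Permutation**: statistic |log(τ_A/τ_B)| from per-condition pooled
  fits, null built by shuffling condition labels across whole traces
  (traces, not points, are the exchangeable units).

The two agree on reject/accept at α = 0.05 in ≥ 90% of synthetic runs
under the preset difference (tested).

Abscission durations are summarized as sample mean and sd (n−1); the
duration is timed from cytokinesis end to *microtubule-bridge
dissolution*, which may precede actual membrane severing — the pipeline
records only the tubulin-based definition. Bridge prevalence is the
per-frame fraction of cells with bridges, pooled as mean ± sem across
frames (zero-cell frames excluded with a warning); midbody-remnant
densities reuse the same machinery as counts per cell per frame.
Density trends use Spearman rank correlation.

## FRAP exchange

Bleached cell and connected sister follow the symmetric two-compartment
exchange `dc_b/dt = k(c_s − c_b)`, `dc_s/dt = k(c_b − c_s)` with
`c_b(0) = b` (bleach depth) and `c_s(0) = 1`, giving the closed form
`c_s(t) = (1+b)/2 + (1−b)/2 · e^(−2kt)`. Traces are normalized to the
mean of all pre-bleach samples (one pre-bleach frame is the common
case; averaging generalizes it without changing that case) and smoothed
with a *trailing* 4-point moving average — an even window has no
natural centered alignment, so the causal choice is made and the
minimum can also be read off the raw trace (`smooth=False`). The
transfer readout is the post-bleach minimum: 1 for an unconnected
neighbor, `(1+b)/2` in the long-time limit for a fully equilibrating
sister. Whether smoothing preceded the minimum in the original analysis
is unstated; smoothing-first is the default, with the flag to disable.

## Synthetic-data generator

The generator emulates the study's measurement design, not its images:

* **Lineages.** Each family's mother sits at a uniform-random cell-cycle
  phase at trigger time (t = 0); cycle lengths are normal (mean 14 h,
  sd 2 h, truncated at 10% of the mean) — the cycle-length and phase
  distributions are not reported for the original cells, so these are
  declared defaults representative of ES cells in these conditions, not
  inferred ones. A family whose first division falls more than 12 h
  after trigger gates its exit at that division, otherwise at the
  second — reproducing the early/late-cycle rule. True exit time =
  gating division + lag (normal, mean 3 h, sd 2.5 h, clipped at 0);
  each sister adds independent jitter (sd 1.25 h) around the shared
  family exit. Trajectories are the logistic decay (hi = 1, lo = 0.2,
  k = 1.5 h) sampled every 0.5 h to 40 h with Gaussian noise
  (sd 0.02), clipped at 0. The lag/jitter defaults are calibrated so
  the exit-vs-division regression on fitted, filtered synthetic cells
  has median R² ≈ 0.75 over seeds, matching the reported R² = 0.73 for
  the real dataset within its acceptance band; the jitter ≪ population
  spread likewise yields the observed ≥ 2-fold global/sister variance
  reduction. Daughter volumes are lognormal (cv 0.15), independent of
  exit times — matching the finding that division asymmetry does not
  predict exit order.
* **Bridges.** Exponential thinning with additive Gaussian width noise,
  clipped at 0; presets `naive` (τ_c = 45 min, n = 22) and `exiting`
  (τ_c = 15 min, n = 55) carry the published characteristic times and
  group sizes; w_0 = 1.0 µm, w_∞ = 0.2 µm, 5-min sampling over 3 h,
  noise sd 0.05 µm.
* **Abscission durations.** Lognormal, moment-matched to the published
  mean ± sd (8.2 ± 3.8 h naive ES, 1.5 ± 0.5 h HeLa): only mean and sd
  are reported, and durations must be positive, so a normal would be
  wrong in the tail.
* **FRAP.** The closed-form two-compartment solution plus noise, frame
  interval 1.1 s (full-speed confocal acquisition), ≥ 1 pre-bleach
  frame at level 1.
* **Counts.** Binomial bridge counts per frame at a set fraction.

With all noise terms zero every generator output equals its closed
form exactly, and identical seeds reproduce identical tables (tested).
What the generator does *not* emulate: colony geometry and spatial
crowding, photobleaching of the reporter over hours of imaging,
segmentation/tracking errors, cell death, and heavy-tailed intensity
noise. Passing recovery tests on this generator therefore demonstrates
the correctness of the estimators under the stated model, not
robustness to those real-data artifacts.

## Problem sizes and numerical choices

Default analyses use 30 families (60 terminal cells), 1000 bootstrap
replicates, and 100 generator seeds for seed-median statistics; the
acceptance script uses the published bridge group sizes (22/55). All
optimizations are bounded trust-region least squares; sigmoid and
exponential fits recover noiseless parameters to better than 1e-4
relative error (tested to 1e-6 absolute on τ). Ties: equidistant
divisions classify to the second; a first division exactly at the 12-h
boundary is late-cycle; within-replicate closest-division ties take the
earlier division. Degenerate inputs (constant traces, zero variance,
empty event lists, zero-cell frames) are either flagged results or
typed errors, per operation, and never silent numbers.

## Known limitations

* The pipeline consumes already-quantified tables; no image
  segmentation or intensity extraction is included.
* The bootstrap's grace-window selection effect (above) means the test
  should not be applied to datasets where many cells lack a qualifying
  division without first checking the exclusion count in the report.
* The F test assumes i.i.d. Gaussian residuals across pooled points,
  ignoring within-trace correlation; the permutation test, which
  respects trace identity, is the conservative cross-check.
* Abscission timing by microtubule dissolution may lead membrane
  scission; absolute durations should be read with that caveat.
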