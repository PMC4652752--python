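# Methods

## Coordinate model

A single circular chromosome, 0-based base-pair coordinates in
`[0, L)`, default `L = 4,640,000`.  "Clockwise" means increasing
coordinate.  GFF3 input/output converts to and from the standard 1-based
closed convention.  Circular intervals with `start > end` wrap through 0.

The bundled annotation (`data/ecoli_dual_origin.gff3`) encodes an
MG1655-derived dual-origin model: *oriC* at 3.923 Mbp, the ectopic *oriZ*
at 0.344 Mbp, polar terminators terA–terJ, the seven rRNA operons
(rrnA–E, G, H) as replication slow zones, and *dif* at 1.589 Mbp.  The
*oriC* coordinate is 3.923 rather than the often-quoted 3.92 Mbp because
3.923 is the unique value jointly consistent with the published arithmetic
midpoints 1.603, 2.664 and {2.1335, 4.4535} Mbp given *oriZ* = 0.344 and
`L/2 = 2.32`.  ter and rrn coordinates are approximate literature values
rounded to 1 kb; analyses depend on their polarity and orientation
semantics, not on the exact base.  Strain configurations are subsets of
the origin list (`subset_origins`), leaving all other annotation intact.

## Forward model of replication

Every configured origin fires once, simultaneously, at `t = 0` — a single
synchronous initiation round.  This deliberately omits overlapping rounds
(multifork replication) of fast-growing cells: the analyses consume only
relative copy-number gradients, which the single-round model already
produces; absolute origin-to-terminus ratios of rich-medium cultures are
therefore not reproduced.

Each origin launches a clockwise and a counterclockwise fork moving at
`fork_speed_bp_per_s` (default 1000 bp/s, the upper end of measured
elongation rates).  Inside a slow zone a fork runs at
`head_on_factor × v` when it opposes the zone's transcription direction
and `codirectional_factor × v` otherwise.  Defaults 0.25 and 0.9 are free
parameters chosen to give clearly visible head-on signatures with a mild
co-directional cost; neither is anchored to a measured value.  The
`rpo_star` flag models an RNA-polymerase-destabilising mutation by moving
every factor toward 1: the speed deficit `1 − f` is multiplied by
`1 − rpo_star_relief` (default relief 0.5).

A polar ter site arrests an opposing fork with probability `efficiency`
(default 1; the Bernoulli draw uses the run's seed).  An arrested fork
waits at the site until the converging fork arrives; the two fuse there.
With `tus_active = False` every ter site is transparent.  Barrier elements
(repressor-bound operator arrays) impose a fixed direction-independent
pause.  A configuration whose opposing traps seal off part of an arc
raises `UnreachableRegionError`.

Between consecutive origins the two enclosed forks are traced as
piecewise-linear arrival-time functions over the arc (breakpoints at zone
edges, traps, barriers); the fusion point is the crossing of the two
curves, or the trap position when one fork waits.  Per-bin replication
time `t_rep` is evaluated at bin-start coordinates, so an origin placed on
a bin boundary gives its bin `t_rep = 0` exactly; origins off the bin grid
shift that identity by up to one bin.

**Copy number.**  In a steady-state exponential population with doubling
time `τ_d`, a locus replicated at time `t` after initiation has relative
abundance `M = 2^(−t/τ_d)` (origin bins = 1).  This law is a modelling
choice — the minimal one generating exponential origin-to-terminus
gradients — not a measured quantity.  Doubling-time defaults follow the
measured growth of the strains being emulated (19.9 min wild-type-like,
39.8 min for the single-ectopic-origin strain).

**Sequencing counts.**  A per-bin lognormal bias (`bias_sd_log`) is drawn
once and shared by both libraries, emulating mappability/GC effects.  The
replicating library draws counts with mean `depth · M·b / mean(M·b)`, the
stationary control with mean `depth · b / mean(b)`, from Poisson or
negative-binomial (size `nb_dispersion`) distributions.  All randomness
derives from one seed through named substreams (bias, exponential counts,
stationary counts, trap Bernoullis), so runs are exactly reproducible.

**What the generator does not emulate:** multifork replication,
replication restart and fork collapse, origin-firing asynchrony between
cells, fragment-length and GC-dependent coverage structure beyond a static
per-bin bias, mapping artifacts at repeats.  Tests passing on synthetic
data therefore validate the analysis algebra and its noise robustness at
the stated depths, not the full error structure of real libraries.

## Marker frequency

`E_i = (c_i/Σc)/(s_i/Σs)` with library totals taken over mutually
unmasked bins, so the stationary-weighted mean of `E` is exactly 1 and the
statistic is invariant to rescaling either library.  Bins with zero
control counts are masked (`zero_control`), user exclusions as
`user_exclusion`; masks propagate — masked bins never enter LOESS fits or
minima searches.  No genome-wide rescaling beyond the library-size ratio
is applied.  Input counts are assumed to come from uniquely mapped reads;
alignment and filtering are upstream of this package.

## Periodic LOESS

At every bin centre the `q = round(frac · n_unmasked)` circularly nearest
unmasked points are selected (ties at the q-th distance all included —
deterministic and symmetric), weighted by tricube on circular distance
with `d_max` = the largest included distance, and a local quadratic in
coordinates re-centred at the evaluation point is fit by weighted least
squares; the fitted value is the polynomial at offset 0.  Re-centring
makes the fit continuous across the coordinate origin (periodic boundary
conditions); the implementation is validated against an explicit
O(n·m) oracle (≤1e−9) and against a non-periodic LOESS on the
three-fold tiled profile (≤1e−6).  Default `frac = 0.10`; on the
4640-bin model genome that is 464 bins, reported as a ≈460 kbp window
(nearest 10 kbp).  Local coordinates are scaled by `d_max` before forming
the normal equations; a 1e−12 ridge guards degenerate windows.

Outlier handling: fit, drop points with squared residual above
`outlier_threshold` (default 0.02, applied on the linear enrichment
scale), refit on the retained points.  One removal pass by default
(`refit_passes` configurable); removed points still receive fitted values.
`q` is recomputed from the retained count on refit.

## Terminus and replichore analytics

With one origin the termination point is the global minimum of the fitted
curve; with two origins the circle is split at the origins and each open
arc searched separately.  Arcs are open: a bin containing an origin is
never reported.  Ties break toward the smaller coordinate; a minimum on an
arc-boundary bin is flagged `suspect`.  Minima are taken on the
outlier-refit curve, at bin resolution, reported in Mbp to 3 decimals
(half-up rounding throughout, so 3.275 reports as 3.3 at one decimal).

Because LOESS averages across the sharp copy-number step at an occupied
fork trap, the fitted minimum is displaced clockwise of the trap by up to
roughly half a smoothing window on noise-free input; measured profiles
show the same displacement.  Recovery tests therefore reference the
noise-free fitted minimum, not the raw fusion point, except in symmetric
trap-free configurations where the two coincide to one bin.

Shifts are signed clockwise offsets from the arithmetic midpoint of an arc
to its minimum, in kb, the representative chosen in `[−L/2, L/2)`.
Replichore lengths are clockwise/counterclockwise arc lengths from each
origin to its adjacent minima.

Gradient-deviation scores formalise "locally steeper than the arm":
per-bin central differences of `log₂(fit)`, `score(R) = mean |g| over R /
median |g| over the enclosing origin-to-minimum arm excluding all
annotated slow zones and query regions`.  A head-on zone with speed factor
`f` doubles the local timing slope at `f = 0.5` and scores ≈ 2.  Arms
whose baseline median is below 1e−6 log₂-units/bin raise `FlatArmError`
rather than returning an undefined ratio.

## Inversion detection

A profile measured on a rearranged chromosome but plotted in reference
coordinates shows two discontinuities; reversing the intervening segment
restores continuity.  Roughness is the mean squared difference across
unmasked adjacent bin pairs on the circle.  Candidates are the top-k local
maxima of |second difference| of the enrichment track, excluding ±20 kb
around annotated origins, ter sites and barriers (their steps are genuine).
Every ordered candidate pair, with a ±1-bin jitter (a curvature peak can
sit on either bin flanking a jump), is scored by reversing the clockwise
segment and re-measuring roughness; the best pair is refined exhaustively
within ±10 bins.  `improvement = 1 − roughness_after/roughness_before`;
an inversion is called at ≥ 0.2 (a free threshold — the procedure
formalises what was originally done by inspection, so no measured anchor
exists).

Two design points discovered during validation and worth recording:

- Detection runs on the **raw** enrichment by default.  Light
  pre-smoothing (the optional `detect_frac`) spreads a breakpoint step
  over the smoothing window; reversing the smoothed track can then no
  longer restore continuity, and the curvature peaks migrate to the ramp
  shoulders.  On noise-free or deep profiles raw detection is exact.
- A reversal changes only the two junction terms of the roughness sum —
  interior adjacent pairs are preserved, reversed.  Static steps (the
  occupied trap, origin peaks) therefore cancel between before and after,
  and no masking of annotated regions inside the objective is needed (an
  earlier masked variant let a near-whole-genome reversal hide a genuine
  trap step inside an excluded window).

On a circle, reversing a segment and reversing its complement produce
identical junction pairs, hence identical profiles of the objective: only
the unordered breakpoint pair is observable.  Calls are canonicalized to
the shorter clockwise segment.  Limits: single inversions only;
breakpoints within ~20 kb of an annotated element fall inside candidate
exclusion windows and are not detectable; an inversion roughly symmetric
about an origin leaves the profile nearly continuous and is intrinsically
invisible to any continuity criterion.

## Growth curves

`simulate_growth_curve` evaluates
`N(t) = N₀ Σ_k f_k 2^(t/τ_k)` for a mixture of subpopulations, sampled
every 30 min by default, with optional multiplicative lognormal counting
noise.  `N₀` defaults to 2×10⁷ CFU/ml (a 100-fold dilution of a saturated
LB culture).  A 1% fast subpopulation reproduces the convex, biphasic
log-curve of a slow strain being overtaken by suppressors.
`fit_doubling_time` is OLS of `log₂(CFU)` against time over a window
(default 60–180 min, where batch cultures are reliably exponential);
doubling time = 1/slope, `r²` reported.  Automatic window selection is out
of scope; zero counts inside the window invalidate the fit.  On the
biphasic default mixture the 60–180 min fit recovers the slow doubling
time with under 10% upward bias.

## Problem sizes and determinism

Analyses and tests run on the full 4640-bin model genome; a full LOESS
pass takes well under a second, and the noisy minima-recovery study uses
20 seeds at 100 reads/bin.  The acceptance script's pipeline (noise-free
simulation → inversion → detection) is deterministic; its `--seed` is
threaded through `SimulationParams` so stochastic variants remain
reproducible.

## Interface notes

The spec-level file surface is `io.py` (bedGraph/TSV coverage, GFF3/TSV
annotations, TSV profiles at 6 significant digits with `NA` masks,
versioned JSON reports) plus the `replichore` CLI (`simulate`, `mfa`,
`smooth`, `analyze`, `detect-inversion`, `growth-fit`).  The detector's
public signature takes the marker-frequency profile and the chromosome
model; it does not consume the analysis-grade LOESS curve, for the
smoothing reasons above.
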