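# Methods

This note records the models behind each pipeline stage, what the
synthetic-data generator does and does not emulate, the numerical choices,
and known limitations.

## Substrate geometry and region conventions

A fork substrate is described by its duplex length and the two
single-strand arm lengths; sequences are never modelled because no
downstream computation uses them — only lengths and marker positions
(roadblock, reporter) matter. Coordinates on the labelled strand are
1-based inclusive intervals counted from the labelled (duplex) end: from
the 5' end when the encircled 3'-arm strand carries the dye, from the 3'
end when the excluded strand does. The origin is stored per `RegionMap`
rather than assumed globally because it differs between substrates.

For the 50-nt labelled strands (20 bp duplex + 30 nt arm) the default
regions are bases 20–35 (assigned to N@duplex) and 36–50 (C@duplex) — the
single-strand window split at its midpoint, with the junction-proximal
half attributed to the orientation that places the C-terminal cleavage
probe near the junction-distal N-terminal face's footprint. This
assignment is a convention of the assay design, not derivable from
geometry alone, so it is configurable (`region_map_override`); shorter
strands default to a midpoint split of their single-strand window.

## Synthetic-data generator

One `BindingPopulation` — probabilities over (arm × orientation)
configurations plus an unbound remainder — drives all four streams, so the
quantities the pipeline recovers are linked the same way the real assays
are: the footprint F_N is the population's N@duplex weight on the labelled
strand, and the unwinding amplitude is the probability of the single
productive configuration (the 3'-arm-encircled hexamer whose leading face
matches the `productive_rule`). The rule is an explicit parameter, never
hard-coded, so the pipeline can be shown to discriminate N-first from
C-first truths.

**Footprint lanes.** Each configuration deposits `signal_mass` (default
200 densitometry units per unit probability) as a discretized Gaussian
kernel centred at the midpoint of the region its orientation maps to
(shiftable via `probe_offset`, default 0), truncated and renormalized to
the single-strand window, over a uniform `background_rate` (default 1.0).
Hexamers bound to the non-labelled arm cut the labelled strand with
probability `cross_strand_prob` (default 0.3), modelling the flexibility
of the C-terminal probe domain to reach the other strand at the junction;
this perturbs intensities but not the region assignment. Lane noise is
per-base lognormal with CV `noise_cv` (default 0.10) — per-base rather
than per-lane because a common lane factor cancels exactly in the
fraction and would leave replicates with zero variance. The control lane
carries background and noise only.

The kernel spread is `cleavage_sd` = 2.5 nt by default. With the 16/15-base
regions this keeps ≥ 99% of each orientation's mass inside its assigned
region; a broader kernel (4 nt) leaks 2–3% of mass across the region
boundary, which biases the recovered F_N by ≈ +0.02 at the 0.23 regime —
an order of magnitude larger than the standard error of a 5-replicate
mean at CV 0.10 — so the narrower default was chosen to make the
estimator's crosstalk bias negligible relative to its sampling error.
`footprint_span` (24 nt) is retained as descriptive metadata of the
hexamer's physical footprint; the kernel carries all positional spread.

**Unwinding time courses.** True fraction unwound F(t) = p·(1 − e^(−kt))
with p the productive probability. Band intensities are Is = F·S + leak
and Id = (1−F)·S + leak (S = 100, leak = 5 by default) with additive
Gaussian noise of sd `noise_sd`·S (default 0.02), plus noisy zero-time and
boiled rows so the normalization is exercised non-trivially. Default time
grid: 12 points over 0–240 min, chosen to resolve a rate of 0.07 min⁻¹
(several lifetimes with early curvature sampled); both grid and rate are
arguments.

**Anisotropy titrations.** Hill isotherm plus additive Gaussian noise
(default regime in the CLI: Amax 0.20, Kd 150 nM, n 2, noise 0.003 —
values of the order anisotropy experiments on labelled forks produce).

**Stopped-flow traces.** Two-exponential curves on a split time base
(default 0–10 s at 500 points, 10–300 s at 500 points) with signals on an
O(1) scale and 1% additive noise. The fast phase is always an increase
(helicase binding). The slow-phase sign follows the decision table: with
the roadblock, increase iff the labelled face leads under the true
direction, decrease otherwise (dissociation); without the roadblock,
decrease for either label (unwinding past the reporter); without ATP, no
slow phase. The slow-phase magnitude is not constrained by any reported
number, so `slow_amp` defaults to 0.4 — larger than the fast phase, as the
blocked leading-face traces show.

**What the generator does not emulate.** Gel smiling, lane-to-lane
background structure, band overlap, photobleaching, instrument dead time,
streptavidin displacement at long times, multi-hexamer loading, and any
sequence- or temperature-dependence. Passing recovery tests therefore
demonstrates that the estimators are correct and well-conditioned at
realistic noise levels, not that they are robust to every artefact of
real gels or stopped-flow optics.

## Footprint quantification

Background subtraction is per-base `max(lane − control, 0)`; densitometry
cannot be negative and the fraction presumes non-negative mass. Each
replicate is fractionated independently and the fractions averaged
(standard error over replicates), matching the per-experiment error bars
of 3–5 independent gels; lanes are never averaged first. Duplex-region
intensities are excluded entirely. Per-lane scale cancels in the ratio,
so no additional per-lane normalization is applied. The orientation
comparison is an unpaired two-tailed equal-variance t-test on the
replicate F_N vs F_C sets with the conventional star thresholds, and a
preference is called only at p < 0.05.

## Unwinding fits

The single exponential is implemented as F(t) = C + A·e^(−kt) and
reported in the rising parameterization A_f·(1 − e^(−kt)) with A_f = C =
−A, so the amplitude is directly the productive fraction. Bounds
0 ≤ A_f ≤ 1 and k > 0; initial guesses A_f⁰ = max F, k⁰ = ln 2 / t_half.
Fits use lmfit (Levenberg–Marquardt) with parameter standard errors from
the scaled covariance. A series with no signal (max |F| < 10⁻⁶) is
returned flagged degenerate with amplitude 0 and an undefined rate rather
than a spurious fit. Rates are reported in min⁻¹ for gel assays and s⁻¹
for stopped-flow; explicit converters are provided
(0.07 min⁻¹ = 1.1667×10⁻³ s⁻¹).

## Hill fits

Y(0) = 0 is enforced by the model form; the free-DNA baseline is expected
to be subtracted before fitting since the isotherm has no offset term.
The Hill coefficient is fitted freely within [0.25, 8] — wide enough for
hexamer cooperativity, bounded so shallow titrations cannot diverge. After
fitting, a titration lying entirely below 20% or above 80% saturation of
the fitted isotherm raises an identifiability error instead of returning
a meaningless Kd. No ligand-depletion (quadratic) model is offered: the
isotherm assumes free ≈ total protein.

## Multi-exponential stopped-flow fits

All split-time-base segments are fit jointly with per-point weights
proportional to each segment's time span divided by its point count
(inverse sampling density, normalized to mean 1). This reduces to uniform
weighting when sampling density is uniform, and prevents the dense early
segment from dominating the slow phase.

Initialization is a coarse log-spaced grid search over rate combinations
(amplitudes and offset solved by weighted linear least squares), keeping a
handful of structurally distinct candidates and polishing each by
coordinate-wise rate refinement before the nonlinear fit. The distinct-
candidate step matters: under span weighting a pair of nearby slow rates
can out-score a fast/slow pair on the raw grid (the fast phase carries
little total weight), and refining only from that candidate lands in a
degenerate amplitude-cancellation minimum. Fits whose adjacent rates end
up within a factor of 3 are flagged degenerate rather than reported as
two phases.

The amplitude sign convention is fixed package-wide: a_i < 0 is a signal
increase (the exponential relaxes upward to the offset). Phases are
reported with rates descending.

Model order (1–3 exponentials) is selected by small-sample-corrected AIC
with a phase-resolution gate: a higher order is accepted only if its AICc
improves *and* every phase is resolved (rates separated ≥ 3-fold, each
amplitude exceeding twice its standard error). The gate is what gives
reliable order-1 selection on single-phase data — an information criterion
alone accepts a spurious extra phase a nontrivial fraction of the time at
thousands of points. An F-test (α = 0.01) is available as the alternative
criterion. Order 1 is always the fallback.

Quench curves are normalized as
quench(c) = 1 − [S_lab(c) − (S_unlab(c) − S_unlab(0))] / S_lab(0), i.e.
the fluorescence drift on adding unlabelled protein is subtracted before
normalizing to the zero-protein signal, so quench(0) = 0 by construction.

## Direction inference

The correspondence between a substrate's footprint fraction and its
unwinding amplitude is operationalized as z = |F − A_f| / √(SE₁² + SE₂²)
with consistency at z < 1.96. On the reported values this reproduces the
published calls: both fork substrates are consistent for F_N (z ≈ 0.7 and
0.9) and wildly inconsistent for the F_C complements (z ≈ 16–20).

A directional verdict requires two concordant streams: (a) amplitude
matches F_N (not F_C) on ≥ 1 substrate — or the mirrored pattern — and
(b) the blocked slow phase rises for exactly one label site. Slow-phase
calls use a 2×SE amplitude threshold (below it: flat); degenerate fits
are reported missing, never guessed. Anything short of two concordant
streams returns `indeterminate` with the failing evidence lines listed.
Substrates where the bound population cannot unwind (5'-long-arm forks)
are treated as controls, not direction evidence.

## Problem sizes and simulation scales

The packaged defaults are desk-scale versions of the assays: 5 replicate
lanes/time courses per condition, 12-point time courses, 800–1000-point
traces, 7-trace averages, 20 seeded end-to-end runs per truth in the
discrimination test, and 200 seeded fits in the amplitude-recovery
characterization. These sizes were chosen so each estimate's sampling
error is comfortably below the effect sizes being recovered.

## Known limitations

* The region→orientation assignment is a convention taken from the assay
  design; the generator's probe geometry is parameterized
  (`probe_offset`) rather than derived from structure.
* Fraction-unwound values are reported un-clamped, so noise can place
  individual points slightly outside [0, 1]; only the fitted amplitude is
  bounded.
* The multi-exponential fitter resolves rates separated ≥ 3-fold; phases
  closer than that are genuinely unidentifiable at these noise levels and
  are flagged, not split.
* The consistency z-test treats the two estimates as independent
  Gaussians; with 3–5 replicates the normal approximation is mildly
  anticonservative.
* No ligand-depletion binding model and no multi-phase unwinding model
  are provided; the assays' standard analyses use neither.
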