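# Methods

## The model

A seed-anchored microtubule plus end is modeled as a continuous-time Markov
chain over three states — growth (G), pause (P), shrinkage (S) — with
first-order transition rates `k_gs, k_gp, k_pg, k_ps, k_sg, k_sp` (min⁻¹).
Length changes at `+v_g` µm/min in G, `−v_s` in S, and not at all in P.
Two boundary behaviors make the process a microtubule rather than a free
random walk:

* shrinkage is truncated exactly at the stabilized seed (no sub-seed
  depolymerization, as for GMPCPP-stabilized seeds), entering a BARE state;
* a bare seed renucleates into growth after an exponential waiting time
  with rate `k_nuc`.

Catastrophes are transitions into S from either G or P; rescues are
transitions out of S into either G or P — the model deliberately allows
pauses to adjoin shrinkage on both sides.  Sampling is event-driven
(exact), so the ground truth carries no discretization bias; the camera's
3-s frame grid enters only when a path is converted to a trajectory.
Microtubule aging, tubulin-concentration and temperature dependence, and
protein–lattice binding are all outside the model.

### Closed-form expectations

For an irreducible rate set the stationary occupancies π solve πQ = 0 on
the class reachable from G.  Ignoring the seed boundary,

* pause fraction = π_P,
* rescue frequency `f_res` = `k_sg + k_sp` (exponential exit-rate identity),
* catastrophe frequency `f_cat` = (π_G·k_gs + π_P·k_ps) / (π_G + π_P) under
  the default denominator convention (growth-excursion time includes
  interleaved pauses), or divided by π_G alone under `growth_only`.

These are the oracles against which the estimators are validated.  The
seed boundary truncates shrinkage episodes, so finite-movie simulations
deviate from the closed form by a small occupancy shift; with the default
parameter sets this bias is ≤3%, which is why the estimator/oracle check
uses a 5% band.

### Default parameter sets

The assay literature reports no rate constants for this system, so the
defaults are illustrative, chosen once to give realistic episode structure
at 3 s / 20 min imaging (catastrophe-limited growth of a few µm, short rare
pauses, frequent rescue, shrinkage several-fold faster than growth):

| set | v_g | v_s | k_gs | k_gp | k_pg | k_ps | k_sg | k_sp | k_nuc |
|---|---|---|---|---|---|---|---|---|---|
| `BASELINE_PARAMS` | 1.2 | 5.0 | 0.25 | 0.10 | 3.0 | 0.40 | 1.3 | 0.1 | 3.0 |
| `PIPELINE_VALIDATION_PARAMS` | 1.2 | 4.0 | 0.20 | 0.08 | 0.70 | 0.08 | 1.2 | 0.1 | 2.0 |

(speeds µm/min, rates min⁻¹; seed length 1 µm.)  `bhc_like()` scales the
pause-entry rates (k_gp, k_sp) by 25 and the pause-exit rates (k_pg, k_ps)
by ½, emulating the synergistic pause promotion of the assembled
kinetochore module; with the baseline set the closed-form pause-fraction
fold change is ≈21.  The pipeline-validation set has longer episodes and
slower shrinkage so that every phase spans several frames, which is what a
per-microtubule equivalence check requires.

Calibration defaults: 3 s frame interval and 20-min movies (the assay's
acquisition settings) and 0.107 µm pixels (a typical TIRF value,
configurable).

## Rendering and tip detection

Kymographs are rendered with sub-pixel coverage: pixel j of the lattice
channel integrates the lattice over [j, j+1) in continuous column
coordinates, the seed channel is a static band, both are blurred with a
Gaussian PSF (default σ = 1.3 px), offset by a background level and
perturbed by i.i.d. Gaussian camera noise.  SNR means lattice amplitude
over noise σ.

Tip detection inverts this: the seed band's distal edge (half-maximum
crossing of the mean seed profile) defines the position origin; per row,
the farthest lattice column contiguous with the seed (gaps ≤ 2 px bridged)
above a threshold `background + max(5·noise_sd, 0.5·amplitude)` is refined
to sub-pixel precision by interpolating the threshold crossing.  For a
step edge blurred by a symmetric PSF the half-maximum crossing is unbiased,
giving ≈3 nm mean error on noiseless renders and ≈0.02 µm position noise
at SNR 10.  Below ≈2–3 px of polymer the blurred peak falls under the
threshold: this **optical blind zone** is the resolution floor that several
design choices below respond to.  Rows with a visible seed but no lattice
signal are reported as position 0 (a bare seed is a real measurement in
this geometry); a flag restores missing-value semantics for channels with
no signal at all.

## Segmentation

Frame velocities are estimated as local least-squares slopes
(Savitzky–Golay, half-width 3 frames) over a running-median prefilter
(half-width 1) — the median preserves corners at phase transitions, and
the wide slope window puts the velocity noise floor (~0.09 µm/min at
SNR 10) well below the pause band.  Frames are classified by the
0.25 µm/min pause threshold; runs shorter than 3 frames are merged into
the longer neighbor; boundaries are then refined by local least-squares
changepoint fits and each segment's slope refit on the raw positions, with
label-change hysteresis (1.5× band) so noise cannot flip marginal runs.
Boundary frames belong to the later segment, making durations additive.

Two recovery passes address events the run-length floor would silently
delete:

* **Sub-frame shrink excursions.**  A depolymerization episode shorter
  than the frame interval leaves a one-frame step in the trace, not a
  multi-frame run.  Short growth/shrink runs with net displacement
  ≥ 0.4 µm are exempt from merging, and isolated single-frame drops beyond
  `max(0.2 µm, 6·robust sd)` of the within-run differences are split into
  their own shrink segment.  Without this, 20–30% of catastrophe/rescue
  pairs vanish at the baseline rates.
* **Merged pauses.**  A 3–4-frame pause offsets the entire subsequent
  trace by ~8σ of the tip-localization noise, yet per-frame velocity
  thresholds cannot see it.  An exhaustive two-changepoint least-squares
  search over each moving run (BIC-like acceptance, middle piece ≥ 3
  frames and slope inside the pause band) restores such pauses.

Missing positions are bridged by linear interpolation when the gap is
shorter than the run floor; longer gaps split the trace, and a lifetime
open at a gap is censored there.

## Lifetimes

A lifetime runs from emanation at the seed to complete depolymerization
back to it.  Operationally, a record opens during a growth segment at the
frame where the tip first exceeds `min_excursion` (default 0.5 µm ≈ 5 px)
— excursions inside the optical blind zone cannot be seen by any
image-based analysis, so opening at one pixel would create phantom
lifetimes — and closes when a shrink segment ends within
`seed_return_tolerance` (default 1 px) of the seed, with the terminal
shrink clipped where it leaves the observable zone.  The symmetric
clipping matters statistically: shrinkage time below the blind zone cannot
contribute observable rescues, so excluding it keeps the pooled rescue
frequency an unbiased thinned-Poisson estimator instead of ~15% low.
Movies ending before closure yield censored records, which contribute
their observed times and events by default (a flag excludes them).

## Statistics

Per lifetime: `f_cat` = catastrophes / growth-excursion time (interleaved
pauses included, shrinkage excluded; `growth_only` retained as an
alternative convention), `f_res` = rescues / time spent shrinking (missing
when no shrinkage was observed), percent time in pause = pause time /
lifetime (terminal shrink included under the default `seed_return`
convention), growth rate = duration-weighted mean of growth-segment
slopes.

Condition summaries report the mean/SD/SEM over microtubules of each
statistic — the convention used for dot plots and events-per-microtubule
histograms — *and* pooled frequencies (total events / total exposure
time).  The two answer different questions: per-microtubule means of ratio
statistics are biased estimators of the chain's rate constants at 20-min
movies (mean-of-ratios ≠ ratio-of-means), so all oracle comparisons use
the pooled form.

Many-to-one comparisons implement Dunnett's test (scipy), one-way
ANOVA/Kruskal–Wallis overall tests with Holm-adjusted pairwise tests
against the reference, the unpaired t-test, and a max-|t| permutation
procedure (default 10,000 draws) that controls the family-wise error rate
without distributional assumptions.

## Fluorescence and viability assays

The intensity correction is a ratio, not a subtraction: integrated signal
over *mean* background.  On a uniform image this equals the ROI pixel
count, so values are only comparable between equal-sized ROIs — which is
why background linescans reuse the signal linescan's length and width and
spindle background reuses the spindle ROI shape in the cytoplasm.  A
subtract-then-integrate variant is deliberately not the default.  Spindle
density and area are measured on sum projections of 4 z-planes at the
frame nearest 45 s before anaphase onset; area is mask-only (independent
of intensities).  Viability is L4/adults over eggs/L1 per plate, pooled as
summed counts (always between the per-plate extremes).

## Validation design and what it does and does not show

Three routes share the downstream accounting: `truth` (exact
continuous-time episodes), `trace` (exact tip positions at the frame
interval, segmented like data — the ground truth *at acquisition
resolution*), and `image` (the full render/detect/segment pipeline).

* Estimator/oracle: pooled statistics from the truth route on 300
  microtubules × 20 min match the closed form within 5% (residual =
  seed-boundary truncation + Monte-Carlo error).
* Pipeline equivalence: `pipeline.validate_pipeline` compares image vs
  trace route per microtubule on noiseless renders.  Whole-movie event
  counts must agree exactly and phase times to a frame per boundary,
  *except* where the ground truth itself sits inside a stated band of a
  decision threshold; those allowances are censused from the truth route
  alone (sub-threshold "grey" excursions and their seed dwell, blind-zone
  dip rescues, blind or run-length-marginal pauses, sub-frame shrinks,
  1–2-frame drops near the dip-detection threshold).  Across 1000
  microtubules (10 seeds) at the validation rate set, 998 pass and ~40%
  are reproduced with all-zero allowances; the ~0.2% residual is closure
  boundary placement flipping on blind-zone-distorted frames, which is a
  stochastic refinement outcome not identifiable from truth-side data.
* Recovery under noise: at SNR 10 (200 microtubules × 10 seeds) the image
  route recovers pooled `f_cat`, `f_res` and pause fraction within ~12–13%
  of the continuous-time truth, biased low — the irreducible loss of
  events shorter than the 3-s frame and pauses under the 3-frame floor.
  Bias and RMSE tables are part of the acceptance output.

Passing these tests shows the pipeline is faithful *to the stated optical
and temporal resolution* for this class of synthetic data.  It does not
show robustness to features the generator does not emulate: uneven
illumination and photobleaching, curved or crossing microtubules, seed
detachment, stage drift, non-Gaussian camera noise, or two-end dynamics
(the geometry is seed-anchored, plus-end-only).  Real-data use should
treat the segmentation thresholds as reportable settings, not constants;
results are convention-dependent, and every CLI run writes a manifest
recording the conventions and seeds in force.

## Numerical choices

* Episode tiling tolerance 1e-9 s; lengths clamped at 0 with exact zeros
  during bare intervals.
* Per-microtubule RNG streams from `SeedSequence(master_seed, spawn_key=
  (index, stream))` — order-independent, stream 0 for paths, stream 1 for
  rendering noise.
* Changepoint searches use O(1) interval line fits via prefix sums; the
  pause-insertion middle is capped at 20 frames (longer pauses survive
  velocity classification on their own).
* Ties in boundary refinement resolve to the candidate nearest the
  original boundary; merge order is shortest-run-first, leftmost on ties,
  into the longer neighbor (later on ties).
* Problem sizes in the tests (100–300 microtubules, 10 master seeds) are
  the package's chosen desk-scale study conditions; all are configurable.
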