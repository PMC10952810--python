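# Methods

This note documents the models, conventions, parameters and design
choices behind `balloontrack`: what is simulated, what the detector
assumes, and what the tests do and do not demonstrate.

## Geometry and conventions

World coordinates are a right-handed patient-style frame in millimeters;
every public interface exchanges millimeters (the only pixel-space code
lives inside the detection module). A slice prescription is an oriented
slab: center `c`, unit normal `n`, in-plane unit axes `u` (rows) and `v`
(columns), thickness `t`, FOV and matrix size. The in-plane pixel grid
is centered on the slice center — pixel `((m−1)/2, (m−1)/2)` maps to
`c` — and the slab occupies the half-open interval
`[c·n − t/2, c·n + t/2)` along the normal, so a contiguous stack
partitions space without overlap or gaps. Whether a real scanner centers
or corners its reconstruction grid is a vendor detail; centering was
chosen and is used consistently on both the rendering and detection
sides. Defaults (FOV 450 mm, matrix 160 → 2.8125 mm pixels, 10 mm
thickness) match the acquisition protocol the framework targets.

A detection's through-plane coordinate is the winning slice's center
plane — no sub-slice interpolation is attempted, so through-plane
resolution is ±t/2 by construction. The evaluation criterion accounts
for this (below).

## Tracking parameters

| name | default | meaning |
|---|---|---|
| `d_cal`, `d_run` | 10 mm | slice thickness per mode |
| `n_cal` | 12 (allowed 10–20) | Calibration stack size |
| `n_run` | 3 (odd) | Runtime stack size |
| `alpha_cal` / `alpha_run` | 90° / 40° | pSAT flip angle per mode |
| `beta_fat` | 90° | fat-saturation angle |
| `theta_cal` / `theta_run` | 0.90 / 0.40 | binarization fraction of the stack maximum |
| `r_max` | 8 mm | balloon-radius upper bound (size/shape filter) |
| `d_disp_max` | 14 mm | maximum plausible inter-measurement displacement |
| `lost_limit` | 5 | consecutive lost Runtime measurements tolerated |

All are overridable through a flat configuration mapping (unknown keys
rejected), mirroring parameters adjustable at a scanner console.

## Detection pipeline choices

The seven steps run in a fixed order; in particular the temporal filter
(step 5) precedes the brightness vote (step 7), so a bright distractor
far from the previous position can never outvote a nearby balloon.
Decisions taken where the procedure is underdetermined:

- Threshold comparison is inclusive (`>=`).
- Connectivity is 8-connected and strictly 2D per slice; the per-slice
  and cross-slice selection steps reason about slices separately.
- "Brightest" means highest single-pixel original intensity in the
  region (peak), which is robust to partial-volume dimming at region
  edges; ties break by larger area, then lower slice index, then
  row-major first pixel — invented purely for determinism.
- Centers of mass are intensity-weighted with the original
  (pre-binarization) intensities.
- The temporal and per-slice distances are 3D world distances: regions
  live in different slices of a moving stack, so a purely in-plane
  distance would be ill-defined across slices.
- The shim-box restriction is applied in the binarization step and then
  re-applied after the morphological closing, because closing can
  dilate a region across the box boundary; this guarantees a detection
  is never reported outside the shim box.
- An all-zero (degenerate) stack yields "not found" rather than an
  exception, so the controller's lost-counter handles it uniformly.
- Without a previous position (Calibration), the per-slice selection
  falls back to the brightest region.

The morphological closing is computed as pad-by-one → dilate → erode →
crop, which equals the closing on the infinite background-padded plane.
This keeps the operator extensive (output ⊇ input) and idempotent;
library routines that erode against an implicit zero border lose
extensivity at image edges.

## Controller

The state machine has exactly five transitions: Calibration/found →
Runtime (stack centered on the balloon); Calibration/not-found →
re-issue Calibration; Runtime/found-central → identical request;
Runtime/found-outer → shift by exactly ±`d_run`; Runtime/not-found →
increment the lost counter, falling back to Calibration when it
*exceeds* `lost_limit` (strictly greater, honoring a "more than five
measurements" rule). The initial Runtime placement is continuous (the
balloon sits exactly on the central slab's mid-plane); all subsequent
shifts are quantized to one slice thickness, so every reachable offset
differs from the initial one by an integer multiple of `d_run`. On
fallback the stored position is cleared — Calibration re-detects
unconditionally — while the first Runtime measurement after Calibration
uses the Calibration position as its temporal prior. Feedback latency
is one measurement by default (the prescription emitted after
measurement k takes effect at k+1) and is configurable as an integer
for experimentation; with longer latencies the controller keys its
transition on the mode of the stack actually acquired.

A manual override (`force_calibration`) emulates an operator pedal.

## Simulator

The simulator's job is to produce the *contrast* the tracker consumes,
not MR physics. Signal is pure saturation recovery after a reduced-flip
saturation pulse, `S = M0·(1 − (1 − cos α)·exp(−ts/T1))` with recovery
time `ts = 300 ms`; there is no readout model. Tissue defaults (in
units of the noise standard deviation σ = 1): balloon M0 = 64.2 at
T1 = 50 ms (1% Gd), blood M0 = 12.4 at 1500 ms, myocardium/background
M0 = 11 at 1100 ms, fat M0 = 150 at 300 ms scaled by a residual factor
0.1 for fat suppression. At the Runtime working point this gives
balloon ≈ 64, blood ≈ 10, i.e. a balloon/blood contrast-to-noise ratio
of ≈ 54, the regime reported for pSAT imaging of Gd-filled balloons at
1.5 T. Two constraints shaped the absolute levels: blood must stay
below `theta_run` times the dimmest balloon peak that should still be
detected (a half-slab balloon at ≈ 32), or the adaptive threshold would
pull the vessel above threshold and merge the balloon into one
oversized blood region; and when the balloon is absent the brightest
remaining structures must be large, so the dropped threshold produces
only size-filter-rejected regions (this is what makes the
false-positive rate structurally zero, as in the physical experiment).

Tissue is sampled at each pixel's world position on the slab center
plane. The balloon is the one structure rendered with through-plane
partial volume: its in-slab disk (cross-section radius) is painted with
the spherical-cap volume-overlap fraction
`V(h) = π·h²·(3r − h)/3` relative to the full sphere, so overlap
fractions across a covering stack sum to exactly 1. Noise is Rician —
the magnitude of the noiseless signal plus complex Gaussian noise —
and every random draw is seeded (per measurement and slice), making a
whole closed-loop session bit-reproducible from one integer.

The default phantom is a 3D vessel polyline (tube radius 9 mm) with
substantial through-plane excursion, one blood-filled chamber sphere,
soft-tissue background, and an optional bright fat shell near the FOV
edge (outside the shim box). The vessel radius deliberately exceeds
`r_max`, so bare vessel cross-sections fail the size/shape filter in
balloon-absent frames. A `decoy` phantom variant (12 mm vessel, larger
chambers) is used for false-positive stress tests. The balloon radius
(5 mm) must stay at least 2 mm below `r_max` so a correctly rendered
balloon always passes the size filter. Trajectories move only the
balloon along the vessel: `stationary`, `crawl` (constant arc-length
speed, default 4 mm/measurement, reflecting at the path ends), `leap`
(one scripted displacement chosen so the through-plane coordinate jumps
≥ 40 mm, beyond the three-slice span), and `phantom99` (99 measurements
with two such leaps, emulating a navigation run with two deliberate
rapid displacements). Validation rejects any unflagged step larger than
`d_disp_max`.

What the simulator does **not** model: bSSFP steady-state and readout
physics, flow and in-flow artifacts, cardiac/respiratory motion of the
background, guidewires, coil sensitivity, or anatomically realistic
heart geometry. Passing tests therefore demonstrate the correctness of
the tracking logic and its closed-loop behavior under the stated
contrast assumptions — not performance on clinical images.

## Evaluation

Ground truth marks the balloon *present* in a measurement when its
sphere/slab volume overlap reaches at least 5% in some acquired slice
(a proxy for "visible in the magnitude image", which is judged by eye
in practice). A detection is *correct* when the estimated center lies
within the true balloon radius of the true center, plus `d_run/2`
through-plane slack for the slice-center reporting convention. The four
outcomes are: present∧correct → TP, present∧not-found → FN,
absent∧not-found → TN, absent∧found → FP. A found-but-mislocalized
detection (present, error beyond the bound) is also counted FP — the
conservative reading of "detected something that is not the balloon" —
and flagged separately in the metrics table. Detection accuracy is
`100·(TP+TN)/N` per mode, which makes accuracy ≡ TP% + TN% a structural
identity. Outcome denominators pool all measurements of the mode in the
log. Mode-time fractions weight each measurement by its slice count
(`n_cal` vs `n_run`) as a duration proxy; a count-based option exists.

## Problem sizes

The bundled studies use 20 sessions of 30 measurements (calibration
accuracy), 20 sessions of 99 measurements (Runtime accuracy under
compliant crawl motion), and 10 × 20 balloon-absent stacks against the
decoy phantom (false positives), with per-session seeds derived from
one base seed. These sizes give several thousand pooled classified
measurements while keeping a full reproduction run around a minute on a
single CPU.

## Known limitations

- Through-plane localization is quantized to slice centers (±5 mm at
  defaults); sub-slice interpolation from per-slice brightness would be
  a natural extension.
- The contrast model has no spatial signal variation within a tissue
  class beyond noise, making thresholding easier than in vivo.
- Hypo-intense (gas-filled) balloon tracking is out of scope; the
  pipeline assumes positive contrast.
- The simulator's static background means the true-negative behavior
  of the adaptive threshold (whole-image regions rejected by the size
  filter) is cleaner than it would be with moving anatomy.
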