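# Methods

## The model and what it assumes

`flypose` estimates the pose of a free-flying fruit fly
(*Drosophila melanogaster*) from calibrated multi-view high-speed video.
The fly is a deformable 3D model with 17 kinematic parameters per frame:

| group | parameters | units | meaning |
|---|---|---|---|
| body position | x, y, z | mm | centre of mass, lab frame |
| body attitude | yaw, pitch, roll | deg | intrinsic z–y–x Euler angles |
| wing angles | φℓ, φr, θℓ, θr, ψℓ, ψr | deg | stroke, elevation, pitch per wing, relative to a body-fixed stroke plane |
| hinge shift | δx, δy, δz | mm | one shared translation of both wing hinges, applied mirror-symmetrically about the sagittal plane |
| wing twist | αℓ, αr | deg/mm | linear twist rate, zero at the tip, maximal at the base, applied only to the trailing half of the chord |

The model assumes a rigid body, wings that deform only through the
kinematic twist above, exactly one fly in view, back-lit imaging (dark
fly on bright background), and calibrated cameras given as 3×4
projection matrices.  Legs and antennae are not modelled.  An optional
rigid rod on the thorax (for magnetic-perturbation studies) is carried
with the body.

Conventions decided by this package (the physical papers in this field
rarely pin them down): body rotation `R = Rz(yaw) Ry(pitch) Rx(roll)`;
a stroke plane inclined 45° about the body y axis (configurable in the
geometry); left-wing rotation `Rz(φ) Rx(θ) Ry(ψ)` in the stroke-plane
frame with the span along +y; the right wing is the exact sagittal
mirror of the left-wing construction, which makes bilateral symmetry
hold by construction.  The twist axis is the span axis and "the bottom
half" of the wing is the trailing (x < 0) chord side.

The body mesh is a parametric stand-in: three ellipsoids (abdomen,
thorax, head) along a *curved* axis — drooping abdomen, raised head —
about 2.5 mm long, with a 2.5 mm parametric wing outline.  The
curvature matters: a straight tube of ellipsoids is nearly
roll-symmetric in silhouette, whereas a real fly (and this stand-in)
is not.  All validation here is self-consistent (the renderer and the
tracker share the geometry), so the stand-in does not stand between
the tests and the estimation machinery they exercise; it does mean the
package ships no claim about absolute accuracy on real imagery.

## Segmentation

Background = pixel-wise maximum of the first and last frames (valid
when the fly does not overlap itself between them; for single-wingbeat
synthetic clips, where it does, the renderer's clean background is
passed explicitly).  Per frame: clipped difference (background −
frame), the contrast transform p → 1 − (1 − p)⁶ (brightens the
translucent wings, making the histogram bimodal), Otsu's threshold on
256 bins, then removal of connected components smaller than 8 px
(noise specks).  The filter is a *minimum size*, not
largest-component-only: a nearly edge-on wing can rasterize as thin
fragments detached from the body blob, and deleting them corrupts the
loss badly (this failure was observed directly).  On noiseless
synthetic renders the filter is disabled — there are no specks, and
any filtering bites real wing slivers — which makes the mask equal to
the ground-truth raster exactly.

## Loss

Per view, the model silhouette is the union of the convex hulls of the
projected body (+rod) and each wing, rasterized at camera resolution
(pixel centre in polygon); the loss is the XOR area against the binary
mask, normalized by mask area.  The multi-view loss is a weighted mean
with per-view weights proportional to the fraction of wing pixels not
occluded by the body at the initial pose, computed once and frozen.
Computation is cropped to a margin around each mask's bounding box;
model area falling outside that region is charged to the loss via
exact polygon clipping, so wings cannot "hide off-screen".

## Optimization

All 17 parameters are affinely scaled to [0, 1] over their per-frame
bounds.  Physiological box bounds constrain every angle; per frame,
roll is confined to ±2° around the frame's initial condition, and — as
frame-to-frame continuity constraints at ≥20 kHz frame rates — x, y, z
to ±0.5 mm and yaw/pitch to ±10°.

The binary XOR loss is a staircase: flat treads stall every local
derivative-free method well above the attainable accuracy.  The
optimizer therefore descends an **anti-aliased evaluation of the same
objective** — each convex part rasterized as signed-distance coverage
(transition band 1 px, sharpened to 1/4 px in a second stage, which
shrinks the band's sub-pixel bias on thin wing slivers) — using a
short coarse compass search followed by bounded Nelder–Mead stages,
then polishes on the exact binary loss with a compass search whose
poll steps are physically scaled per DOF (0.6° / 12 µm initial,
shrunk 8×), plus a short position-only refinement.  The reported loss
is always the exact binary XOR, and the result is guaranteed not to
exceed the initial condition's loss.  Everything is deterministic.

**Roll anchoring.**  Measured on this geometry and rig, a roll offset
of 1–2° that is optimally compensated by the other DOFs changes the
loss by only ~2–6 px across all three views — at the level of fit
noise.  An unconstrained fit therefore lets roll random-walk inside
its ±2° window, dragging ψ and θ with it.  After each fit, a candidate
with roll held at the frame's initial condition (rest re-polished) is
preferred unless moving roll lowered the loss by a clear margin
(6×10⁻³ in normalized loss).  This is a hysteresis deadband along the
least-observable direction, not a kinematic prior: strong evidence
still moves roll.

## Degeneracy detection and correction

Certain poses make two ψ values ~30° apart project to nearly identical
outlines; the optimizer can fall into the wrong branch.  Detection
flags a frame whose ψ jumps by >15° per frame (half the gap) against
the previous frame, or whose loss exceeds the median of the last 5
frames by >50% (evaluated above a floor of 0.012 so a near-zero loss
does not trigger; the median reference also catches gradual creep).
When error detection is enabled, a frame whose fitted loss exceeds
0.012 is additionally re-fitted from a constant-velocity extrapolation
of the two previous results, keeping the better fit.

Correction re-fits the flagged frame from 6 deterministic ψ-branch
candidates (±30° per wing, roll reset to the frame's initial
condition) and 15 random restarts seeded by k-means++ over the scaled
parameter cube (10,000 uniform candidates; each new start drawn with
probability proportional to the distance from the nearest chosen one,
as the method prescribes — distance, not squared distance), keeping
the lowest-loss result and stopping early once a candidate clearly
resolves the frame.  Preceding frames are then re-fitted backwards
from their corrected neighbour, but only while they look *suspected*
(ψ inconsistent with the corrected neighbour or elevated loss), up to
a depth of 5; a re-fit is kept only if it lowers that frame's loss.
The "naive" mode switches all of this off (detection, extrapolation
retry, MRS) and is what the corrected/naive comparisons run against.

## Synthetic validation

The generator emulates near-hovering flight: 220 Hz wingbeat sampled
at 100 frames/period (22 kHz), sinusoidal stroke of 140° peak-to-peak
about a 35° mean, elevation at twice the wingbeat frequency (12°
amplitude, the figure-8 tip path), a smoothed two-plateau ψ waveform
(±45° plateaus, max step ~6°/frame — below the detection threshold),
slow body drift (60/40/30 mm/s; 100/60/30 °/s), and optional hinge
(≤0.05 mm) and twist (≤4 °/mm) waveforms for the 17-DOF mode.  The
rig is three *exactly* orthogonal cameras — azimuths 0/120/240 at
elevation atan(1/√2) ≈ 35.3°, i.e. the Cartesian triad rotated about
its diagonal — at ~50 µm/pixel, so 10 µm ≈ 0.2 px.  Rendering uses
the same rasterizer as the loss (dark fly 0.1 on background 0.9,
optional Gaussian noise), making the generating pose an exact zero of
the loss on noiseless data.

What the generator does **not** emulate: grayscale texture, motion
blur, legs, lens distortion, real wing-membrane flexion beyond the
kinematic twist, or segmentation imperfections beyond additive noise.
Passing validation therefore demonstrates the estimation machinery —
geometry, loss, optimization, degeneracy handling — not robustness to
real-world imaging artifacts.

The validation protocol tracks self-rendered wingbeat videos (one per
body yaw over a grid), initialized from ground truth at frame 1, with
the basic 12-DOF configuration (deformation DOFs frozen): per-frame
signed errors per DOF (angles wrapped to (−180°, 180°]), the fraction
of frames with every angle within 2°, and the centre-of-mass error in
µm.  The degeneracy protocol restarts the optimization at a random 20%
of frames from a +30° ψr offset and compares detection-on versus
naive tracking.

## Problem sizes

`scripts/acceptance.py` runs the validation at 3 videos × 100 frames
at 256×256 (yaws 0/90/180 of the 90° grid) for both the
position/angle-accuracy ensemble and the provocation protocol.  The
test suite replicates the same experiments at 2 videos × 80 frames
and 192×192 (same pixel scale), with thresholds carrying the
tolerance of scaled-down stochastic replications.  These sizes are
the package's validation configuration; all knobs are ordinary
function arguments.

## Known limitations

- Roll (and, through the exchange mode, ψ and θ) is observable from
  hull silhouettes only at the ~2° level; the anchoring hysteresis
  trades a small lag in genuine roll motion for drift immunity.
- During wing rotation the wing passes near edge-on in some views and
  ψ is transiently under-determined; errors of 2–4° in those phases
  are information-limited, not optimizer-limited.
- The convex-hull silhouette discards concavities of the true wing
  outline; no grayscale appearance term is used.
- First-frame initialization must be supplied (config or ground
  truth); no automatic bootstrap is provided.
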