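# Methods

This note records the model, the parameter choices, the numerical
decisions, and what the synthetic validation does and does not
demonstrate.

## Vesselness model

The enhancement stage assumes vessels are elongated intensity valleys
(clinical polarity) of roughly 2–12 px width. At scale σ the image is
convolved with second derivatives of an isotropic Gaussian
(edge-replicated boundaries, kernel truncated at 6σ so the sampled
derivative kernels keep their zero-sum property to ~1e−9), each grid
multiplied by σ^γ. Eigenvalues are ordered by magnitude |λ₁| ≤ |λ₂|; when
the magnitudes tie, λ₂ takes the negative root so the polarity gate sees
it deterministically. The response combines a blobness ratio λ₁²/λ₂²
(with 0/0 := 0) and a structureness term, gated to zero where λ₂ < 0
(`dark` polarity) or λ₂ > 0 (`bright`); the response is clamped below 1
to keep the open bound where the structureness factor saturates in
floating point.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| scales | 1–6 px, unit steps | σ range; spans the vessel radii of interest on 512×512 angiograms |
| α | 0.5 | blobness sensitivity (standard for 2D) |
| β | auto | per scale, half the maximum Hessian Frobenius norm observed on the image at that scale — structureness then adapts to image contrast |
| γ | 1 | scale normalization exponent applied once per derivative grid |
| polarity | dark | clinical angiograms; phantoms are rendered bright and inverted before the pipeline so one default serves both |

Because γ-normalization is applied as a single σ^γ factor, the response
magnitude decays with scale and the per-pixel argmax favors small σ; the
per-scale automatic β makes responses comparable across scales, and ridge
*position* — the only thing downstream stages consume — is unaffected.

## Seeds

A seed is a subpixel RE maximum: within a 2×2 cell, the gradient must
reverse across a diagonal corner pair and both Hessian eigenvalues of the
RE image (derivative scale 1 px) must be negative at all four corners.
Two numerical details matter. First, structures aligned exactly with the
pixel grid make the diagonal gradient products exactly zero rather than
negative; a cell with both products exactly zero but nonzero corner
gradients is counted as a reversal (flat cells still never fire). Second,
the subpixel position is the least-squares zero crossing of the bilinear
gradient interpolant linearized at the cell center; a bilinear fit of the
RE *values* has its critical point at a saddle and is ill-conditioned
along a ridge, whereas the gradient solve simply keeps the center
coordinate in any flat direction.

Candidates are thinned (2 px merge radius, stronger wins), thresholded at
τ = 0.05 on the [0,1) RE scale, and validated by requiring the mean RE
value over a 7×7 rectangle to reach the same threshold — this removes
isolated noise spikes that survive the pointwise test. Directions come
from a 360-sample circle scan of radius 5 px: the global maximum gives
one ridge intersection, the local maximum on the antipodal arc
(half-width π/6) gives the other, and the one with cos φ ≥ 0 is labeled
forward. Bilinear sampling limits the angular accuracy of the scan to a
few degrees (measured on a noise-free straight phantom: median 0.6°,
maximum 7°); tracking re-estimates its direction at every step, so this
does not propagate. Seeds are visited in descending RE order (an optional
seeded shuffle exists for robustness experiments); with a fixed
configuration the whole module is deterministic.

## Tracking

State per walk: position p_k, angle θ_k, diameter D_k. The step radius is
d_k = clamp(D_k/2, 2, 6) px — half the local diameter tracks tight
curvature on thin vessels without wasting steps on wide ones. The arc
spans θ_k ± π/4 at 61 samples. Edge estimation samples the bright-vessel
intensity at 0.5 px steps over ± max(10, 2·D_k) px; coarse edges are the
|gradient| maxima on each side (central differences), the vessel/
background means over the regions they delimit set the half level, and
the refined edges are the first outward crossings of that level with
linear interpolation between samples. A walk terminates when

1. the next point or more than half of either scanline side leaves the
   image;
2. the RE response at the chosen arc point falls below τ, edge detection
   fails (no crossing, inverted contrast, flat profile), or the diameter
   leaves [1, 48] px;
3. the candidate lands on territory already claimed by another walk.

Territory is a per-pixel ownership grid stamped with disks of radius
D̂/2 around every accepted point (first owner wins). A walk ignores its
own last 3 stamps (otherwise the next step, one arc radius ahead, can
fall inside its own trail), and a bifurcation branch ignores its parent's
stamps for its first 2 steps, since the branch necessarily starts inside
the junction stamp. A criterion-3 stop is treated as a junction: the
candidate point is kept (but not stamped) and the identity of the line
run into is recorded, so refinement can link abutting tracks exactly
rather than by a distance heuristic.

Bifurcations are two arc maxima above half the arc maximum, at least 20°
apart, separated by a genuine valley (the arc minimum between them below
0.9× the weaker maximum). The valley requirement is what distinguishes a
real branch from interpolation ripples on a single wide ridge; without it
a clean straight vessel spawns spurious two-point stubs. The stronger
maximum continues the current branch, the second is centered the same way
and enqueued as a new walk.

## Refinement

Lines are linked when an endpoint lies within 6 px of another line or
when a recorded junction/parent relation exists; 6 px (rather than a
tighter tolerance) reflects that a criterion-3 stop ends about one
occupancy-mask radius (~D/2 ≈ 4 px) short of the line it ran into. Lines
shorter than 20 px are pruned shortest-first, except where removal would
split a component; the component with the largest summed arc length is
kept (ties resolved by lowest line index, deterministically). Each kept
polyline is resampled through a cardinal spline (tension 0 =
Catmull–Rom, 4 samples per segment, one-sided tangents at the ends,
diameters linearly interpolated); the spline interpolates every tracked
point, so smoothing redistributes samples and removes step-quantization
jaggedness without denoising the point estimates themselves.

## Synthetic phantoms

A vessel is a cylinder of radius r(l) along a planar curve; its
projection adds 2μ√(r² − x²) at perpendicular distance x. Perpendicular
distance is evaluated against the curve sampled at 0.25 px via a k-d
tree, which caps the geometric error at ~0.03 px and gives rounded end
caps. Overlapping vessels sum, as attenuation projections do. The
diameter law D(l) = D₀e^(−al) − cσ·exp(−π(l−μ)²/(σc)²), c = D₀e^(−aμ)
yields D(μ) = c(1−σ): σ is the stenosis fraction, σ = 1 total occlusion.

Concrete geometry (512×512 canvas, scaled proportionally for other
sizes): vessel length 400 px, diameter 8 px, background 60/255, peak
vessel intensity 120/255 above background, default pose oblique at 12°
(nothing axis-aligned, which would be both unrealistic and degenerate
for grid-aligned tests), sinusoid amplitude 40 px over two full periods,
branch angle ±25° with child diameter 6.5 px, crossing vessels at 70–75°
with diameter 7 px, 50% stenosis (σ = 0.5) at mid-length. "Noise power"
is the standard deviation of additive zero-mean Gaussian pixel noise on
the 0–255 scale; images are clipped to [0,1] after adding it. Randomized
instances draw orientation uniform in [0, π) and jitter the center by
±5% of the canvas.

Ground truth stores, per 1 px arc-length sample, both the geometric
diameter 2r and the full width at half maximum of the projected profile,
r√3. Evaluation defaults to the half-max convention because that is what
profile-based edge detection measures; even so the estimator carries a
small positive bias (~0.1r) because its half level is set from the mean
vessel intensity rather than the peak — visible as the ~0.2–0.5 px mean
diameter errors on clean phantoms.

What the phantoms do not emulate: perspective projection geometry of a
C-arm, heart motion, catheters and bone background, Poisson/quantum
noise, and uneven contrast-agent perfusion. Passing the synthetic
protocol therefore demonstrates geometric correctness and noise
robustness of the tracking machinery, not clinical-grade performance;
the pipeline runs on clinical angiograms but is validated here only
synthetically.

## Evaluation protocol

Errors are one-directional, tracked → truth: Euclidean distance to the
nearest point of the truth polylines by segment-wise projection, and
|D̂ − D_truth| at the nearest truth sample. Tracked points within 12 px
(2·σ_max) of the border are excluded. Because a one-directional metric
cannot see under-tracking, every report also carries coverage — the
fraction of truth arc length with a tracked point within 2 px.

The two experiment protocols: (a) per-type accuracy — five randomized
phantoms per type V1–V9 at noise power 5, per-point errors pooled per
type, summarized as max/min/mean/RMS, plus a row averaging the
statistics over types; (b) noise robustness — a single straight vessel
per integer noise power, mean centerline and diameter error per power.
Both are deterministic given a master seed (per-phantom seeds are spawned
from it). Problem sizes — 45 + 21 pipeline runs on 512×512 images — keep
the full reproduction to a few minutes on one CPU.

## Known limitations

- End caps: tracking overshoots vessel ends by a few pixels before the
  off-vessel criterion fires (the rounded cap still looks vessel-like),
  which dominates the *maximum* error statistic while barely moving the
  mean.
- Crossings are traversed by whichever vessel is tracked first; the
  second is split at the junction and reconnected as a component, not
  resolved into two anatomically continuous vessels.
- Diameter estimates inherit the half-level bias discussed above and are
  unreliable below ~2 px diameter (profile support shrinks to a few
  samples).
- The seed-direction circle scan is bilinear-interpolation limited;
  occasional seeds near vessel ends carry direction errors up to ~7°.
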