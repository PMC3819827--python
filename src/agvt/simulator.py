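"""Synthetic angiogram phantoms with exact ground truth.

A vessel is modeled as a cylinder of radius r(l) along a planar centerline
c(l); its X-ray projection adds intensity

    p(x) = 2 mu sqrt(r^2 - x^2),   |x| <= r,

at perpendicular distance x from the centerline, mu being the linear
attenuation coefficient.  Stenosis and taper are injected through the
diameter profile

    D(l) = D0 exp(-a l) - c sigma exp(-pi (l - mu_s)^2 / (sigma c)^2),
    c    = D0 exp(-a mu_s),

so that at the stenosis center D(mu_s) = c (1 - sigma): sigma is the
stenosis fraction (sigma = 1 gives total occlusion).

Nine canonical geometries V1..V9 cover straight, tapered and sinusoid
vessels, each with and without a 50% stenosis, plus bifurcating,
overlapping, and bifurcating-and-overlapping configurations. Additive
zero-mean Gaussian pixel noise is parameterized by its standard deviation
on the 0-255 intensity scale ("noise power").

Ground truth records, per centerline sample, both the geometric diameter
2r and the full width at half maximum of the projected profile, r*sqrt(3)
(the projection of a cylinder crosses half its peak at x = r*sqrt(3)/2).
Diameter evaluation defaults to the half-max convention because that is
what profile-based edge detection measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .image import GrayImage

__all__ = [
    "StenosisParams",
    "VesselSpec",
    "Phantom",
    "diameter_profile",
    "project_vessel",
    "make_phantom",
    "noise_series",
    "VESSEL_KINDS",
    "HALF_MAX_FACTOR",
]

VESSEL_KINDS = tuple(f"V{i}" for i in range(1, 10))

#: FWHM of the projected circular profile, as a multiple of the radius.
HALF_MAX_FACTOR = math.sqrt(3.0)

# Default rendering constants (a concrete instantiation of the study
# geometry; all overridable through make_phantom keyword arguments).
_CANVAS = 512
_LENGTH = 400.0          # nominal vessel arc length, px
_D0 = 8.0                # nominal diameter, px
_BACKGROUND = 60.0 / 255.0
_PEAK = 120.0 / 255.0    # peak vessel intensity above background
_SINE_AMPLITUDE = 40.0   # V3: two full sine periods across the length
_BRANCH_ANGLE = math.radians(25.0)
_CURVE_STEP = 0.25       # arc-length sampling of analytic curves, px


class ParameterError(ValueError):
    """Invalid simulator parameter."""


@dataclass
class StenosisParams:
    """Taper + Gaussian-dip diameter profile parameters."""

    d0: float                 # initial diameter, px
    a: float = 0.0            # taper coefficient, 1/px
    mu_s: float = 0.0         # stenosis location (arc length), px
    sigma_s: float = 0.5      # stenosis fraction (dimensionless)

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ParameterError("sigma_s must be positive")

    @property
    def c(self) -> float:
        """Local (tapered) diameter at the stenosis location."""
        return self.d0 * math.exp(-self.a * self.mu_s)


def diameter_profile(p: StenosisParams, l: float | np.ndarray) -> np.ndarray | float:
    """Diameter D(l) of a tapered, stenosed vessel; floored at 0."""
    l = np.asarray(l, dtype=float)
    c = p.c
    dip = c * p.sigma_s * np.exp(-(np.pi * (l - p.mu_s) ** 2) / (p.sigma_s * c) ** 2)
    d = p.d0 * np.exp(-p.a * l) - dip
    d = np.maximum(d, 0.0)
    return float(d) if d.ndim == 0 else d


@dataclass
class VesselSpec:
    """One vessel: densely sampled centerline with per-sample radius."""

    points: np.ndarray                  # (N, 2) centerline samples, (x, y)
    radii: np.ndarray                   # (N,) radius at each sample, px
    mu_att: float                       # linear attenuation coefficient
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.radii = np.asarray(self.radii, float)
        if np.any(self.radii < 0):
            raise ParameterError("radii must be nonnegative")

    @property
    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Phantom:
    """Synthetic angiogram plus exact centerline/diameter ground truth."""

    image: GrayImage                    # bright-vessel rendering
    truth: list[dict] = field(default_factory=list)
    noise_power: float = 0.0
    seed: int | None = None
    kind: str = "custom"

    def angiogram(self) -> GrayImage:
        """Clinical-polarity (dark vessels on bright background) view."""
        return self.image.inverted()

    def truth_points(self) -> np.ndarray:
        return np.concatenate([t["points"] for t in self.truth])


def _resample(points: np.ndarray, radii: np.ndarray,
              spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline (+ radii) at uniform arc-length spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(math.floor(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, points[:, 0])
    y = np.interp(si, s, points[:, 1])
    r = np.interp(si, s, radii)
    return np.column_stack([x, y]), r


def project_vessel(spec: VesselSpec, canvas: np.ndarray) -> np.ndarray:
    """Add the cylinder projection of one vessel onto a canvas, in place.

    For every pixel within r of the centerline the added intensity is
    2 mu sqrt(r^2 - x^2) with x the perpendicular distance; overlapping
    vessels sum (attenuation projections are additive).
    """
    h, w = canvas.shape
    pts, radii = spec.points, spec.radii
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
        bad = int(np.argmax((pts[:, 0] < 0) | (pts[:, 0] > w - 1)
                            | (pts[:, 1] < 0) | (pts[:, 1] > h - 1)))
        raise ParameterError(f"vessel exits canvas near sample {bad}")
    rmax = float(radii.max())
    x0 = max(int(pts[:, 0].min() - rmax - 1), 0)
    x1 = min(int(pts[:, 0].max() + rmax + 2), w)
    y0 = max(int(pts[:, 1].min() - rmax - 1), 0)
    y1 = min(int(pts[:, 1].max() + rmax + 2), h)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)

    tree = cKDTree(pts)
    dist, idx = tree.query(pix, k=1, distance_upper_bound=rmax + 1.0)
    hit = np.isfinite(dist)
    r_loc = np.zeros_like(dist)
    r_loc[hit] = radii[idx[hit]]
    inside = hit & (dist <= r_loc)
    add = np.zeros(len(pix))
    add[inside] = 2.0 * spec.mu_att * np.sqrt(
        np.maximum(r_loc[inside] ** 2 - dist[inside] ** 2, 0.0))
    canvas[y0:y1, x0:x1] += add.reshape(ys.shape)
    return canvas


def _line(center: np.ndarray, angle: float, length: float,
          t0: float = 0.0) -> np.ndarray:
    """Straight centerline samples from t0..length along `angle`."""
    t = np.arange(t0, length + _CURVE_STEP / 2, _CURVE_STEP)
    d = np.array([math.cos(angle), math.sin(angle)])
    start = center - d * length / 2.0
    return start + t[:, None] * d


def _sine_curve(center: np.ndarray, angle: float, length: float,
                amplitude: float) -> np.ndarray:
    """Two full sine periods across `length`, rotated by `angle`."""
    t = np.arange(0.0, length + _CURVE_STEP / 2, _CURVE_STEP / 2)
    local = np.column_stack([
        t - length / 2.0,
        amplitude * np.sin(2.0 * np.pi * 2.0 * t / length),
    ])
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    pts = local @ rot.T + center
    pts, _ = _resample(pts, np.zeros(len(pts)), _CURVE_STEP)
    return pts


def _radii_for(points: np.ndarray, d0: float, taper_a: float,
               stenosis: StenosisParams | None) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    l = np.concatenate([[0.0], np.cumsum(seg)])
    if stenosis is not None:
        d = diameter_profile(stenosis, l)
    else:
        d = d0 * np.exp(-taper_a * l)
    return np.asarray(d) / 2.0


def _mu_for_peak(radius: float) -> float:
    """Attenuation giving the nominal peak intensity at the given radius."""
    return _PEAK / (2.0 * radius)


def _build_vessels(kind: str, rng: np.random.Generator | None,
                   randomize: bool, size: int = _CANVAS) -> list[VesselSpec]:
    """Assemble the V1..V9 geometry, optionally jittered in pose.

    Lengths scale with the canvas so smaller test canvases stay valid;
    diameters are absolute (pixels) as in the 512x512 default.
    """
    center = np.array([size / 2.0, size / 2.0])
    length = _LENGTH * size / _CANVAS
    base_angle = math.radians(12.0)  # oblique by default: nothing axis-aligned
    if randomize:
        if rng is None:
            raise ParameterError("randomize=True requires an rng")
        base_angle = rng.uniform(0.0, math.pi)
        center = center + rng.uniform(-0.05 * size, 0.05 * size, size=2)
    mu = _mu_for_peak(_D0 / 2.0)
    taper_a = math.log(2.0) / length        # D halves over the vessel
    amplitude = _SINE_AMPLITUDE * length / _LENGTH
    sten = StenosisParams(d0=_D0, a=0.0, mu_s=length / 2.0, sigma_s=0.5)
    sten_taper = StenosisParams(d0=_D0, a=taper_a, mu_s=length / 2.0,
                                sigma_s=0.5)

    def straight(sten_p=None, a=0.0, angle_off=0.0, shift=(0.0, 0.0),
                 vlen=None, d0=_D0):
        pts = _line(center + np.asarray(shift), base_angle + angle_off,
                    vlen if vlen is not None else length)
        return VesselSpec(pts, _radii_for(pts, d0, a, sten_p), mu, kind)

    if kind == "V1":
        return [straight()]
    if kind == "V2":
        return [straight(a=taper_a)]
    if kind == "V3":
        pts = _sine_curve(center, base_angle, length, amplitude)
        return [VesselSpec(pts, _radii_for(pts, _D0, 0.0, None), mu, kind)]
    if kind == "V4":
        return [straight(sten_p=sten)]
    if kind == "V5":
        return [straight(sten_p=sten_taper, a=taper_a)]
    if kind == "V6":
        pts = _sine_curve(center, base_angle, length, amplitude)
        return [VesselSpec(pts, _radii_for(pts, _D0, 0.0, sten), mu, kind)]
    if kind in ("V7", "V9"):
        # parent up to the branch point, two children at +/- branch angle
        d = np.array([math.cos(base_angle), math.sin(base_angle)])
        start = center - d * length / 2.0
        bp = start + d * (length / 2.0)
        t = np.arange(0.0, length / 2.0 + _CURVE_STEP / 2, _CURVE_STEP)
        parent_pts = start + t[:, None] * d
        vessels = [VesselSpec(parent_pts,
                              _radii_for(parent_pts, _D0, 0.0, None), mu, kind)]
        for sign in (+1, -1):
            ca = base_angle + sign * _BRANCH_ANGLE
            cd = np.array([math.cos(ca), math.sin(ca)])
            tc = np.arange(0.0, 0.425 * length + _CURVE_STEP / 2, _CURVE_STEP)
            cpts = bp + tc[:, None] * cd
            vessels.append(VesselSpec(
                cpts, _radii_for(cpts, 6.5, 0.0, None), mu, kind))
        if kind == "V9":
            cross = _line(center + d * 0.15 * length,
                          base_angle + math.radians(75.0), 0.75 * length)
            vessels.append(VesselSpec(
                cross, _radii_for(cross, 7.0, 0.0, None), mu, kind))
        return vessels
    if kind == "V8":
        v1 = straight()
        pts = _line(center, base_angle + math.radians(70.0), 0.85 * length)
        v2 = VesselSpec(pts, _radii_for(pts, 7.0, 0.0, None), mu, kind)
        return [v1, v2]
    raise ParameterError(f"unknown vessel kind {kind!r}")


def make_phantom(kind: str, noise_power: float = 0.0,
                 seed: int | None = None, size: int = _CANVAS,
                 randomize: bool = False,
                 background: float = _BACKGROUND) -> Phantom:
    """Render a ground-truthed phantom of one of the nine vessel types.

    ``noise_power`` is the standard deviation of additive zero-mean
    Gaussian noise on the 0-255 scale.  With ``randomize=True`` the pose
    (orientation, position) is drawn from the seeded generator, modeling
    the study protocol of independently regenerated phantoms.
    """
    if kind not in VESSEL_KINDS:
        raise ParameterError(f"kind must be one of {VESSEL_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    vessels = _build_vessels(kind, rng if randomize else None, randomize, size)
    canvas = np.full((size, size), background, dtype=np.float64)
    truth = []
    for spec in vessels:
        project_vessel(spec, canvas)
        pts, radii = _resample(spec.points, spec.radii, 1.0)
        truth.append({
            "points": pts,
            "diam_geom": 2.0 * radii,
            "diam_halfmax": HALF_MAX_FACTOR * radii,
        })
    if noise_power > 0:
        canvas = canvas + rng.normal(0.0, noise_power / 255.0, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return Phantom(image=GrayImage(canvas, bit_depth=8), truth=truth,
                   noise_power=noise_power, seed=seed, kind=kind)


def noise_series(kind: str, powers: Sequence[float],
                 master_seed: int | None = None,
                 randomize: bool = False) -> list[Phantom]:
    """One phantom per noise power, geometry shared, noise seeds derived."""
    if len(powers) == 0:
        raise ParameterError("powers must be nonempty")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(powers))
    out = []
    for power, child in zip(powers, children):
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(make_phantom(kind, noise_power=power, seed=sub,
                                randomize=randomize))
    return out


def truth_to_json(phantom: Phantom) -> dict:
    """JSON-serializable ground-truth record."""
    return {
        "kind": phantom.kind,
        "noise_power": phantom.noise_power,
        "seed": phantom.seed,
        "lines": [
            {"points": [[float(x), float(y), float(dg), float(dh)]
                        for (x, y), dg, dh in zip(t["points"],
                                                  t["diam_geom"],
                                                  t["diam_halfmax"])]}
            for t in phantom.truth
        ],
    }


def truth_from_json(obj: dict) -> list[dict]:
    """Inverse of :func:`truth_to_json` (lines part)."""
    truth = []
    for line in obj["lines"]:
        arr = np.asarray(line["points"], float)
        truth.append({
            "points": arr[:, :2],
            "diam_geom": arr[:, 2],
            "diam_halfmax": arr[:, 3],
        })
    return truth
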