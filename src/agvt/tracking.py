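"""Adaptive geometrical vessel tracking.

From each validated seed the tracker alternates two ideas:

1. *Ridge following on the RE image.*  Given the current centerline point
   p_k and tracking angle theta_k, the next ridge point is the intensity
   maximum of the RE image on the arc of radius d_k spanning
   [theta_k - dtheta, theta_k + dtheta].  Two well-separated arc maxima
   signal a bifurcation and spawn a second branch.

2. *Geometric centering on the original image.*  The ridge of the RE
   image need not coincide with the geometric vessel center when contrast
   is uneven, so each ridge point is corrected: the intensity profile
   along the scanline perpendicular to the step direction is measured,
   vessel edges are located where the profile crosses the midpoint
   between mean vessel and mean background intensity, and the point is
   moved to the mid-edge position.  The edge separation is the diameter
   estimate.

Tracking runs forward and backward from every seed and stops when the
path leaves the image, leaves the vessel (low RE response or failed edge
detection), or runs into an already-extracted centerline (an occupancy
mask with per-point ownership implements the third criterion without
blocking a path on its own recent trail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .enhancement import VesselnessMap
from .seeds import SeedPoint

__all__ = [
    "TrackingParams",
    "CenterlinePoint",
    "Centerline",
    "VisitedMask",
    "EdgeEstimate",
    "next_ridge_point",
    "detect_bifurcation",
    "scanline_profile",
    "estimate_edges",
    "adjust_center",
    "check_termination",
    "track_from_seed",
    "track_all",
]

_EPS = 1e-12


@dataclass
class TrackingParams:
    """Tunable parameters of the tracker (all lengths in pixels)."""

    tau: float = 0.05            # RE response floor (criterion 2)
    delta_theta: float = math.pi / 4.0   # arc half-width for ridge search
    step_min: float = 2.0
    step_max: float = 6.0
    arc_samples: int = 61        # samples across the search arc
    profile_step: float = 0.5    # scanline sampling step
    profile_halflen_min: float = 10.0
    bif_fraction: float = 0.5    # arc maxima above this fraction of max
    bif_sep_deg: float = 20.0    # minimum angular separation of maxima
    diameter_min: float = 1.0
    diameter_max: float = 48.0   # 2 * sigma_max * 4 for the default scales
    max_steps: int = 2000        # hard safety bound per walk
    recent_k: int = 3            # own trail length exempt from criterion 3
    grace_steps: int = 2         # junction-adjacent steps exempt per branch


@dataclass
class CenterlinePoint:
    x: float
    y: float
    ux: float
    uy: float
    theta: float
    diameter: float
    s_plus: float = 0.0
    s_minus: float = 0.0
    source: str = "tracked"      # seed | tracked | bifurcation

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Centerline:
    points: list[CenterlinePoint] = field(default_factory=list)
    origin_seed: int | None = None
    parent: int | None = None    # index of the line this branched from
    joins: list[int] = field(default_factory=list)  # lines this ran into
    term_forward: str = "open"
    term_backward: str = "open"

    def positions(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points]).reshape(-1, 2)

    def diameters(self) -> np.ndarray:
        return np.array([p.diameter for p in self.points])

    def arc_length(self) -> float:
        pos = self.positions()
        if len(pos) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


class VisitedMask:
    """Occupancy grid with per-pixel owner (walk token, point index)."""

    def __init__(self, shape: tuple[int, int]):
        self.owner = np.full(shape, -1, dtype=np.int32)
        self.index = np.full(shape, -1, dtype=np.int32)

    def stamp(self, p: np.ndarray, radius: float, token: int, idx: int) -> None:
        h, w = self.owner.shape
        r = max(1.0, radius)
        x0, x1 = int(math.floor(p[0] - r)), int(math.ceil(p[0] + r))
        y0, y1 = int(math.floor(p[1] - r)), int(math.ceil(p[1] + r))
        x0, x1 = max(x0, 0), min(x1, w - 1)
        y0, y1 = max(y0, 0), min(y1, h - 1)
        if x1 < x0 or y1 < y0:
            return
        ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        inside = (xs - p[0]) ** 2 + (ys - p[1]) ** 2 <= r * r
        free = self.owner[y0:y1 + 1, x0:x1 + 1] < 0
        put = inside & free   # first owner wins
        self.owner[y0:y1 + 1, x0:x1 + 1][put] = token
        self.index[y0:y1 + 1, x0:x1 + 1][put] = idx

    def lookup(self, p: np.ndarray) -> tuple[int, int]:
        h, w = self.owner.shape
        px = min(max(int(round(p[0])), 0), w - 1)
        py = min(max(int(round(p[1])), 0), h - 1)
        return int(self.owner[py, px]), int(self.index[py, px])

    def covered(self, p: np.ndarray) -> bool:
        return self.lookup(p)[0] >= 0


def _bilinear(arr: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Sample arr at (x, y) points with bilinear interpolation."""
    pts = np.atleast_2d(pts)
    return ndimage.map_coordinates(arr, [pts[:, 1], pts[:, 0]], order=1,
                                   mode="nearest")


def _in_image(p: np.ndarray, shape: tuple[int, int], margin: float = 1.0) -> bool:
    h, w = shape
    return (margin <= p[0] <= w - 1 - margin) and (margin <= p[1] <= h - 1 - margin)


def next_ridge_point(re: VesselnessMap | np.ndarray, p: Sequence[float],
                     theta: float, d: float, delta_theta: float,
                     n_samples: int = 61):
    """Sample the RE image on the search arc; return (angles, values).

    Samples falling outside the image are dropped.  Returns (None, None)
    if the entire arc is outside.
    """
    arr = re.response if isinstance(re, VesselnessMap) else re
    h, w = arr.shape
    p = np.asarray(p, float)
    angles = np.linspace(theta - delta_theta, theta + delta_theta, n_samples)
    pts = p + d * np.column_stack([np.cos(angles), np.sin(angles)])
    ok = ((pts[:, 0] >= 0) & (pts[:, 0] <= w - 1)
          & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1))
    if not ok.any():
        return None, None
    angles, pts = angles[ok], pts[ok]
    values = _bilinear(arr, pts)
    return angles, values


def detect_bifurcation(angles: np.ndarray, values: np.ndarray,
                       f_bif: float = 0.5, sep_deg: float = 20.0,
                       max_branches: int = 2,
                       valley_fraction: float = 0.9) -> list[tuple[float, float]]:
    """Qualifying arc maxima as (angle, value), strongest first.

    A maximum qualifies if it exceeds ``f_bif`` times the arc maximum, is
    at least ``sep_deg`` degrees from every stronger accepted maximum
    (closer pairs merge into the stronger one), and is separated from it
    by a genuine valley: the arc minimum between the two must drop below
    ``valley_fraction`` of the weaker one.  The valley requirement keeps
    interpolation ripples on a single wide ridge from reading as a
    bifurcation.  At most two maxima are kept: one continues the current
    branch, a second spawns a new one.
    """
    v = np.asarray(values, float)
    a = np.asarray(angles, float)
    if len(v) == 0:
        return []
    if len(v) == 1:
        return [(float(a[0]), float(v[0]))]
    # local maxima, endpoints included via one-sided comparison
    left = np.concatenate([[True], v[1:] >= v[:-1]])
    right = np.concatenate([v[:-1] >= v[1:], [True]])
    is_max = left & right
    idxs = np.flatnonzero(is_max)
    vmax = v.max()
    idxs = idxs[v[idxs] >= f_bif * vmax]
    order = idxs[np.argsort(v[idxs])[::-1]]
    sep = math.radians(sep_deg)
    picked: list[int] = []
    for i in order:
        ok = True
        for j in picked:
            if abs(a[i] - a[j]) < sep:
                ok = False
                break
            lo, hi = (i, j) if i < j else (j, i)
            valley = v[lo:hi + 1].min()
            if valley >= valley_fraction * min(v[i], v[j]):
                ok = False
                break
        if ok:
            picked.append(int(i))
        if len(picked) == max_branches:
            break
    return [(float(a[i]), float(v[i])) for i in picked]


def scanline_profile(img: np.ndarray, p: Sequence[float], u: Sequence[float],
                     halflen: float, step: float = 0.5):
    """Intensity profile perpendicular to u through p.

    The scanline direction is the left normal n = (-uy, ux); s > 0 on the
    +n side.  Returns (s, g) with samples clipped to the image; returns
    None when clipping removes more than half of either side (the
    support needed for edge detection has left the image).
    """
    p = np.asarray(p, float)
    u = np.asarray(u, float)
    n = np.array([-u[1], u[0]])
    s = np.arange(-halflen, halflen + step / 2, step)
    pts = p + s[:, None] * n
    h, w = img.shape
    ok = ((pts[:, 0] >= 0) & (pts[:, 0] <= w - 1)
          & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1))
    if ok.all():
        return s, _bilinear(img, pts)
    s_in = s[ok]
    if len(s_in) == 0 or s_in.min() > -halflen / 2 or s_in.max() < halflen / 2:
        return None
    return s_in, _bilinear(img, pts[ok])


@dataclass
class EdgeEstimate:
    s_grad_plus: float    # max-|gradient| location, s > 0
    s_grad_minus: float   # max-|gradient| location, s < 0
    vessel_mean: float
    background_mean: float
    s_plus: float         # half-level crossing, s > 0 (subpixel)
    s_minus: float        # half-level crossing, s < 0

    @property
    def diameter(self) -> float:
        return abs(self.s_plus - self.s_minus)

    @property
    def center_offset(self) -> float:
        return 0.5 * (self.s_plus + self.s_minus)


def estimate_edges(s: np.ndarray, g: np.ndarray,
                   halflen: float | None = None) -> EdgeEstimate | None:
    """Locate vessel edges on a scanline profile.

    Coarse edges are the maxima of |dg/ds| on either side of s = 0
    (central differences); they split the profile into vessel and
    background regions whose means define the half level
    (vessel_mean + background_mean) / 2.  The refined edges are the first
    crossings of that level walking outward from s = 0, with linear
    interpolation between samples.  Returns None when any stage fails
    (off-vessel profile).
    """
    s = np.asarray(s, float)
    g = np.asarray(g, float)
    if len(s) < 11:
        return None
    grad = np.gradient(g, s)
    pos = np.flatnonzero(s > 0)
    neg = np.flatnonzero(s < 0)
    if len(pos) < 5 or len(neg) < 5:
        return None
    # interior only: endpoints have one-sided differences
    pos_int = pos[(pos > 0) & (pos < len(s) - 1)]
    neg_int = neg[(neg > 0) & (neg < len(s) - 1)]
    if len(pos_int) == 0 or len(neg_int) == 0:
        return None
    i_p = pos_int[np.argmax(np.abs(grad[pos_int]))]
    i_m = neg_int[np.argmax(np.abs(grad[neg_int]))]
    sg_p, sg_m = float(s[i_p]), float(s[i_m])
    vessel = (s > sg_m) & (s < sg_p)
    backgr = ~vessel
    if vessel.sum() == 0 or backgr.sum() == 0:
        return None
    v_mean = float(g[vessel].mean())
    b_mean = float(g[backgr].mean())
    if v_mean <= b_mean:
        return None
    level = 0.5 * (v_mean + b_mean)
    i0 = int(np.argmin(np.abs(s)))
    if g[i0] < level:
        return None

    def outward_crossing(direction: int) -> float | None:
        i = i0
        while 0 <= i + direction < len(s):
            j = i + direction
            if g[j] < level:
                # linear interpolation between samples i (>= level) and j
                t = (g[i] - level) / max(g[i] - g[j], _EPS)
                return float(s[i] + t * (s[j] - s[i]))
            i = j
        return None

    s_hat_p = outward_crossing(+1)
    s_hat_m = outward_crossing(-1)
    if s_hat_p is None or s_hat_m is None:
        return None
    return EdgeEstimate(sg_p, sg_m, v_mean, b_mean, s_hat_p, s_hat_m)


def adjust_center(p_tilde: Sequence[float], u_tilde: Sequence[float],
                  s_plus: float, s_minus: float,
                  p_prev: Sequence[float] | None = None):
    """Move a ridge point to the mid-edge position on its scanline.

    Returns (p_hat, u_hat, diameter); u_hat is the unit step from the
    previous center, or the incoming direction when there is none (or the
    step is degenerate).
    """
    p_tilde = np.asarray(p_tilde, float)
    u_tilde = np.asarray(u_tilde, float)
    n = np.array([-u_tilde[1], u_tilde[0]])
    p_hat = p_tilde + n * 0.5 * (s_plus + s_minus)
    diameter = abs(s_plus - s_minus)
    if p_prev is None:
        return p_hat, u_tilde / np.linalg.norm(u_tilde), diameter
    step = p_hat - np.asarray(p_prev, float)
    norm = np.linalg.norm(step)
    if norm < _EPS:
        return p_hat, None, diameter
    return p_hat, step / norm, diameter


def check_termination(p: Sequence[float], re: VesselnessMap | np.ndarray,
                      visited: VisitedMask | None,
                      params: TrackingParams | None = None, *,
                      edges_failed: bool = False,
                      diameter: float | None = None,
                      token: int | None = None, idx: int = 0) -> str:
    """Classify a candidate centerline point.

    Returns 'out_of_image' when the point leaves the image, 'off_vessel'
    when the RE response there is below tau, edge detection failed, or
    the estimated diameter is implausible, 'revisited' when it falls on
    territory claimed by another walk (ownership by the same token within
    the recent-trail window does not count), else 'continue'.
    """
    params = params or TrackingParams()
    arr = re.response if isinstance(re, VesselnessMap) else re
    p = np.asarray(p, float)
    if not _in_image(p, arr.shape):
        return "out_of_image"
    if edges_failed or float(_bilinear(arr, p[None, :])[0]) < params.tau:
        return "off_vessel"
    if diameter is not None and not (
            params.diameter_min <= diameter <= params.diameter_max):
        return "off_vessel"
    if visited is not None:
        owner, oidx = visited.lookup(p)
        if owner >= 0 and not (token is not None and owner == token
                               and oidx >= idx - params.recent_k):
            return "revisited"
    return "continue"


@dataclass
class _WalkState:
    p: np.ndarray
    theta: float
    diameter: float
    token: int
    parent_token: int | None = None
    grace: int = 0


class _Tracker:
    """Work-queue driver shared by track_from_seed / track_all."""

    def __init__(self, re: VesselnessMap, img: np.ndarray,
                 params: TrackingParams):
        self.re = re
        self.re_arr = re.response
        self.img = img
        self.params = params
        self.mask = VisitedMask(self.re_arr.shape)
        self.lines: list[Centerline] = []
        self._next_token = 0
        self.token_line: dict[int, int] = {}

    def new_token(self) -> int:
        t = self._next_token
        self._next_token += 1
        return t

    # -- single centering step ------------------------------------------
    def _center_at(self, p_tilde: np.ndarray, u_tilde: np.ndarray,
                   prev_d: float, p_prev: np.ndarray | None):
        pr = self.params
        halflen = max(pr.profile_halflen_min, 2.0 * prev_d)
        prof = scanline_profile(self.img, p_tilde, u_tilde, halflen,
                                pr.profile_step)
        if prof is None:
            return "out_of_image", None
        edges = estimate_edges(*prof)
        if edges is None:
            return "off_vessel", None
        p_hat, u_hat, diam = adjust_center(p_tilde, u_tilde, edges.s_plus,
                                           edges.s_minus, p_prev)
        if u_hat is None:
            return "off_vessel", None
        if not (pr.diameter_min <= diam <= pr.diameter_max):
            return "off_vessel", None
        return "ok", (p_hat, u_hat, diam, edges)

    def _revisited(self, p: np.ndarray, state: _WalkState, idx: int,
                   steps_done: int) -> bool:
        owner, oidx = self.mask.lookup(p)
        if owner < 0:
            return False
        if owner == state.token and oidx >= idx - self.params.recent_k:
            return False
        if (state.parent_token is not None and owner == state.parent_token
                and steps_done < state.grace):
            return False
        return True

    # -- one walk (half a seed line, or a bifurcation branch) -----------
    def walk(self, state: _WalkState, line: Centerline, queue: list,
             line_id: int, start_idx: int = 1) -> str:
        pr = self.params
        idx = start_idx
        steps_done = 0
        while steps_done < pr.max_steps:
            d_k = min(max(state.diameter / 2.0, pr.step_min), pr.step_max)
            angles, values = next_ridge_point(
                self.re_arr, state.p, state.theta, d_k, pr.delta_theta,
                pr.arc_samples)
            if angles is None:
                return "out_of_image"
            if values.max() < pr.tau or values.max() - values.min() < 1e-12:
                return "off_vessel"
            cands = detect_bifurcation(angles, values, pr.bif_fraction,
                                       pr.bif_sep_deg)
            accepted = None
            branch = None
            fail = "off_vessel"
            for angle, val in cands:
                if val < pr.tau:   # criterion 2: RE response at the point
                    continue
                u_t = np.array([math.cos(angle), math.sin(angle)])
                p_t = state.p + d_k * u_t
                if not _in_image(p_t, self.re_arr.shape):
                    fail = "out_of_image"
                    continue
                status, result = self._center_at(p_t, u_t, state.diameter,
                                                 state.p)
                if status != "ok":
                    fail = status
                    continue
                if accepted is None:
                    accepted = result
                elif branch is None:
                    branch = result
            if accepted is None:
                return fail
            p_hat, u_hat, diam, edges = accepted
            if not _in_image(p_hat, self.re_arr.shape):
                return "out_of_image"
            if self._revisited(p_hat, state, idx, steps_done):
                # a criterion-3 stop is a junction: keep the junction
                # point (not stamped) and record which line was run into
                line.points.append(CenterlinePoint(
                    x=float(p_hat[0]), y=float(p_hat[1]),
                    ux=float(u_hat[0]), uy=float(u_hat[1]),
                    theta=math.atan2(u_hat[1], u_hat[0]), diameter=diam,
                    s_plus=edges.s_plus, s_minus=edges.s_minus,
                    source="tracked"))
                owner, _ = self.mask.lookup(p_hat)
                owner_line = self.token_line.get(owner)
                if owner_line is not None and owner_line != line_id:
                    line.joins.append(owner_line)
                return "revisited"
            theta = math.atan2(u_hat[1], u_hat[0])
            line.points.append(CenterlinePoint(
                x=float(p_hat[0]), y=float(p_hat[1]),
                ux=float(u_hat[0]), uy=float(u_hat[1]), theta=theta,
                diameter=diam, s_plus=edges.s_plus, s_minus=edges.s_minus,
                source="tracked"))
            self.mask.stamp(p_hat, diam / 2.0, state.token, idx)
            if branch is not None:
                bp, bu, bd, bedges = branch
                # bp typically falls inside the parent's fresh stamp; the
                # branch walk's grace period handles that, so only an
                # in-image check here
                if _in_image(bp, self.re_arr.shape):
                    queue.append((_WalkState(
                        p=bp, theta=math.atan2(bu[1], bu[0]), diameter=bd,
                        token=self.new_token(), parent_token=state.token,
                        grace=pr.grace_steps), line_id,
                        CenterlinePoint(
                            x=float(bp[0]), y=float(bp[1]), ux=float(bu[0]),
                            uy=float(bu[1]),
                            theta=math.atan2(bu[1], bu[0]), diameter=bd,
                            s_plus=bedges.s_plus, s_minus=bedges.s_minus,
                            source="bifurcation")))
            state.p, state.theta, state.diameter = p_hat, theta, diam
            idx += 1
            steps_done += 1
        return "max_steps"

    # -- seed handling ---------------------------------------------------
    def seed_center(self, seed: SeedPoint):
        """Adjust the seed itself to the geometric center."""
        u = np.array([math.cos(seed.forward_angle),
                      math.sin(seed.forward_angle)])
        p = np.array([seed.x, seed.y])
        status, result = self._center_at(p, u, 5.0, None)
        if status != "ok":
            return None
        return result

    def track_seed(self, seed: SeedPoint, seed_index: int | None = None):
        centered = self.seed_center(seed)
        if centered is None:
            return []
        p0, _u0, d0, edges0 = centered
        if not _in_image(p0, self.re_arr.shape) or self.mask.covered(p0):
            return []
        made: list[Centerline] = []
        fw_token = self.new_token()
        bw_token = self.new_token()
        line = Centerline(origin_seed=seed_index)
        line_id = len(self.lines)
        self.lines.append(line)
        made.append(line)
        self.token_line[fw_token] = line_id
        self.token_line[bw_token] = line_id
        seed_pt = CenterlinePoint(
            x=float(p0[0]), y=float(p0[1]),
            ux=math.cos(seed.forward_angle), uy=math.sin(seed.forward_angle),
            theta=seed.forward_angle, diameter=d0,
            s_plus=edges0.s_plus, s_minus=edges0.s_minus, source="seed")
        self.mask.stamp(p0, d0 / 2.0, fw_token, 0)

        queue: list = []
        fw_line = Centerline()
        line.term_forward = self.walk(
            _WalkState(p=p0.copy(), theta=seed.forward_angle, diameter=d0,
                       token=fw_token), fw_line, queue, line_id)
        bw_line = Centerline()
        line.term_backward = self.walk(
            _WalkState(p=p0.copy(), theta=seed.backward_angle, diameter=d0,
                       token=bw_token, parent_token=fw_token,
                       grace=self.params.grace_steps),
            bw_line, queue, line_id)
        line.points = bw_line.points[::-1] + [seed_pt] + fw_line.points
        line.joins = sorted(set(bw_line.joins + fw_line.joins))

        while queue:
            bstate, parent_id, first_pt = queue.pop(0)
            bline = Centerline(parent=parent_id)
            bline_id = len(self.lines)
            self.lines.append(bline)
            made.append(bline)
            self.token_line[bstate.token] = bline_id
            bline.points.append(first_pt)
            self.mask.stamp(np.array([first_pt.x, first_pt.y]),
                            first_pt.diameter / 2.0, bstate.token, 0)
            bline.term_backward = "bifurcation"
            bline.term_forward = self.walk(bstate, bline, queue, bline_id)
        return made


def track_from_seed(seed: SeedPoint, re: VesselnessMap, img: np.ndarray,
                    params: TrackingParams | None = None,
                    tracker: _Tracker | None = None) -> list[Centerline]:
    """Track bidirectionally from one seed; returns the created lines."""
    if tracker is None:
        tracker = _Tracker(re, img, params or TrackingParams())
    return tracker.track_seed(seed)


def track_all(seeds: Sequence[SeedPoint], re: VesselnessMap,
              img: np.ndarray,
              params: TrackingParams | None = None) -> list[Centerline]:
    """Track every seed in order, skipping seeds on covered territory.

    ``img`` must be the bright-vessel intensity image (invert a clinical
    dark-vessel angiogram first); the profile-based centering assumes the
    vessel is brighter than its background.
    """
    tracker = _Tracker(re, img, params or TrackingParams())
    for i, seed in enumerate(seeds):
        if not seed.valid:
            continue
        if tracker.mask.covered(np.array([seed.x, seed.y])):
            continue
        tracker.track_seed(seed, seed_index=i)
    return [ln for ln in tracker.lines if len(ln.points) > 0]
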