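"""Automatic seed detection on the RE image.

Tracking needs starting points on vessel ridgelines.  A subpixel local
maximum of the RE image satisfies grad = 0 with a negative-definite
Hessian; on the pixel grid such a point is bracketed by a 2x2 cell whose
diagonal corner pairs show a gradient reversal while both Hessian
eigenvalues are negative at all four corners.  Candidates are placed at
the critical point of the bilinear interpolant over the cell, thinned,
thresholded on RE intensity, and assigned forward/backward tracking
angles by scanning a circle around each seed for the two ridge
intersections.  A rectangle-mean test removes isolated noise responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .enhancement import VesselnessMap, eigen_decompose, hessian_at_scale

__all__ = [
    "SeedPoint",
    "SeedParams",
    "detect_seed_candidates",
    "threshold_seeds",
    "initial_directions",
    "validate_seed",
    "find_seeds",
]


@dataclass
class SeedParams:
    tau: float = 0.05            # RE intensity threshold for candidates
    tau_rect: float = 0.05       # rectangle-mean validation threshold
    circle_radius: float = 5.0   # direction-scan circle radius, px
    delta_theta: float = math.pi / 6.0  # backward-arc half width
    n_angles: int = 360          # angular samples on the circle
    rect_lx: int = 7
    rect_ly: int = 7
    sigma_seed: float = 1.0      # derivative scale on the RE image
    merge_dist: float = 2.0      # duplicate-suppression radius, px
    order: str = "intensity"     # 'intensity' or 'shuffle'
    shuffle_seed: int | None = None


@dataclass
class SeedPoint:
    x: float
    y: float
    re_value: float = 0.0
    forward_angle: float = 0.0
    backward_angle: float = math.pi
    valid: bool = False
    has_directions: bool = field(default=False, repr=False)

    @property
    def forward_dir(self) -> np.ndarray:
        return np.array([math.cos(self.forward_angle),
                         math.sin(self.forward_angle)])

    @property
    def backward_dir(self) -> np.ndarray:
        return np.array([math.cos(self.backward_angle),
                         math.sin(self.backward_angle)])


def _bilinear(arr: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(pts)
    return ndimage.map_coordinates(arr, [pts[:, 1], pts[:, 0]], order=1,
                                   mode="nearest")


def _cell_subpixel(gx: np.ndarray, gy: np.ndarray, x: int, y: int):
    """Zero crossing of the interpolated gradient inside a unit cell.

    Linearizes the bilinear gradient interpolant around the cell center
    and solves grad = 0 by least squares, so a direction in which the
    gradient is flat (along a ridge) simply keeps its center coordinate.
    Returns (u, v) clamped to [0, 1]^2.
    """
    cgx = gx[y:y + 2, x:x + 2]
    cgy = gy[y:y + 2, x:x + 2]
    # d/du: column differences; d/dv: row differences (u ~ x, v ~ y)
    a = np.array([
        [0.5 * (cgx[:, 1] - cgx[:, 0]).sum(), 0.5 * (cgx[1] - cgx[0]).sum()],
        [0.5 * (cgy[:, 1] - cgy[:, 0]).sum(), 0.5 * (cgy[1] - cgy[0]).sum()],
    ])
    b = -np.array([cgx.mean(), cgy.mean()])
    try:
        delta, *_ = np.linalg.lstsq(a, b, rcond=1e-6)
    except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely fails
        return 0.5, 0.5
    if not np.all(np.isfinite(delta)):
        return 0.5, 0.5
    u, v = 0.5 + delta[0], 0.5 + delta[1]
    return min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0)


def detect_seed_candidates(re: VesselnessMap,
                           params: SeedParams | None = None) -> list[SeedPoint]:
    """Subpixel ridge-maximum candidates from 2x2 cell tests.

    A cell (x..x+1, y..y+1) fires when the RE gradient vectors at one
    diagonal corner pair point against each other (negative dot product)
    and both Hessian eigenvalues of the RE image are negative at all four
    corners.  Gradients/Hessians are taken at a small fixed smoothing
    scale.  Candidates inside the border band are excluded; nearby
    candidates (< merge_dist) are merged keeping the stronger.
    """
    params = params or SeedParams()
    arr = re.response
    sg = params.sigma_seed
    gx = ndimage.gaussian_filter(arr, sg, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(arr, sg, order=(1, 0), mode="nearest")
    eig = eigen_decompose(hessian_at_scale(arr, sg, gamma=0.0))
    neg = (eig.lambda1 < 0) & (eig.lambda2 < 0)

    # diagonal corner pairs of each 2x2 cell
    d_main = gx[:-1, :-1] * gx[1:, 1:] + gy[:-1, :-1] * gy[1:, 1:]
    d_anti = gx[1:, :-1] * gx[:-1, 1:] + gy[1:, :-1] * gy[:-1, 1:]
    all_neg = neg[:-1, :-1] & neg[1:, :-1] & neg[:-1, 1:] & neg[1:, 1:]
    reversal = (d_main < 0) | (d_anti < 0)
    # a maximum aligned exactly with the pixel grid zeroes the gradient at
    # a corner, making both dot products exactly 0; count that as a
    # reversal when the cell is not flat
    gmag = gx ** 2 + gy ** 2
    cell_mag = np.maximum(np.maximum(gmag[:-1, :-1], gmag[1:, 1:]),
                          np.maximum(gmag[1:, :-1], gmag[:-1, 1:]))
    degenerate = (d_main == 0.0) & (d_anti == 0.0) & (cell_mag > 1e-20)
    fire = (reversal | degenerate) & all_neg

    band = re.border_band
    if band > 0:
        keep = np.zeros_like(fire)
        keep[band:-band or None, band:-band or None] = True
        fire &= keep

    ys, xs = np.nonzero(fire)
    cands = []
    for y, x in zip(ys, xs):
        u, v = _cell_subpixel(gx, gy, x, y)
        px, py = x + u, y + v
        val = float(_bilinear(arr, np.array([[px, py]]))[0])
        cands.append(SeedPoint(x=float(px), y=float(py), re_value=val))

    # duplicate suppression: strongest first, greedy 2-px exclusion
    cands.sort(key=lambda s: -s.re_value)
    kept: list[SeedPoint] = []
    md2 = params.merge_dist ** 2
    for c in cands:
        if all((c.x - k.x) ** 2 + (c.y - k.y) ** 2 >= md2 for k in kept):
            kept.append(c)
    return kept


def threshold_seeds(cands: Sequence[SeedPoint], tau: float) -> list[SeedPoint]:
    """Keep candidates whose RE intensity is at least tau."""
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must be in [0, 1)")
    return [c for c in cands if c.re_value >= tau]


def initial_directions(re: VesselnessMap, seed: SeedPoint,
                       params: SeedParams | None = None) -> SeedPoint | None:
    """Assign forward/backward tracking angles by a circle scan.

    RE intensity is sampled on the circle of radius r around the seed;
    the global maximum gives one ridge intersection, the other is the
    local maximum on the antipodal arc of half-width delta_theta.  The
    angle with cos >= 0 (pointing into the right half-plane) is called
    forward.  Returns None (seed dropped) if the circle does not fit in
    the image.
    """
    params = params or SeedParams()
    arr = re.response
    h, w = arr.shape
    r = params.circle_radius
    if not (r + 1 <= seed.x <= w - 2 - r and r + 1 <= seed.y <= h - 2 - r):
        return None
    thetas = np.arange(params.n_angles) * (2.0 * math.pi / params.n_angles)
    pts = np.column_stack([seed.x + r * np.cos(thetas),
                           seed.y + r * np.sin(thetas)])
    vals = _bilinear(arr, pts)
    phi = float(thetas[int(np.argmax(vals))])
    # antipodal arc search for the opposite intersection
    opp = phi + math.pi
    rel = (thetas - opp + math.pi) % (2.0 * math.pi) - math.pi
    arc = np.abs(rel) <= params.delta_theta
    psi = float(thetas[arc][int(np.argmax(vals[arc]))])
    if math.cos(phi) >= 0:
        fwd, bwd = phi, psi
    else:
        fwd, bwd = psi, phi
    seed.forward_angle = fwd % (2.0 * math.pi)
    seed.backward_angle = bwd % (2.0 * math.pi)
    seed.has_directions = True
    return seed


def validate_seed(re: VesselnessMap, seed: SeedPoint,
                  params: SeedParams | None = None) -> bool:
    """Rectangle-mean test: mean RE over Lx x Ly around the seed >= tau."""
    params = params or SeedParams()
    arr = re.response
    h, w = arr.shape
    hx, hy = params.rect_lx / 2.0, params.rect_ly / 2.0
    x0 = max(int(math.floor(seed.x - hx)), 0)
    x1 = min(int(math.ceil(seed.x + hx)), w - 1)
    y0 = max(int(math.floor(seed.y - hy)), 0)
    y1 = min(int(math.ceil(seed.y + hy)), h - 1)
    patch = arr[y0:y1 + 1, x0:x1 + 1]
    seed.valid = bool(patch.mean() >= params.tau_rect)
    return seed.valid


def find_seeds(re: VesselnessMap,
               params: SeedParams | None = None) -> list[SeedPoint]:
    """Full seed chain: detect, threshold, directions, validate, order."""
    params = params or SeedParams()
    cands = detect_seed_candidates(re, params)
    cands = threshold_seeds(cands, params.tau)
    seeds = []
    for c in cands:
        s = initial_directions(re, c, params)
        if s is None:
            continue
        validate_seed(re, s, params)
        if s.valid:
            seeds.append(s)
    if params.order == "shuffle":
        rng = np.random.default_rng(params.shuffle_seed)
        rng.shuffle(seeds)
    else:
        seeds.sort(key=lambda s: -s.re_value)
    return seeds


def seeds_to_csv(seeds: Sequence[SeedPoint], path) -> None:
    """Write seeds as CSV: x, y, phi, psi, re_value, valid."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["x", "y", "phi", "psi", "re_value", "valid"])
        for s in seeds:
            wr.writerow([f"{s.x:.4f}", f"{s.y:.4f}",
                         f"{s.forward_angle:.6f}", f"{s.backward_angle:.6f}",
                         f"{s.re_value:.6f}", int(s.valid)])
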