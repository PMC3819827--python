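"""Vasculature refinement: merge, prune, select, smooth.

Raw tracking yields many short polylines (one per seed walk plus
bifurcation branches).  Refinement links lines whose endpoints touch
other lines, removes short hair-like false tracks whose removal does not
split a connected set, keeps the connected component with the largest
total arc length, and smooths each kept polyline with an interpolating
cardinal (Catmull-Rom family) spline so the jagged per-step adjustments
do not survive into the final centerlines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .tracking import Centerline, CenterlinePoint

__all__ = [
    "RefinementParams",
    "VesselTree",
    "build_components",
    "prune_short",
    "keep_largest",
    "smooth_spline",
    "refine",
]


@dataclass
class RefinementParams:
    merge_tol: float = 6.0       # endpoint-to-line linking distance, px
    min_length: float = 20.0     # short false-track threshold, px
    tension: float = 0.0         # cardinal spline tension (0 = Catmull-Rom)
    samples_per_segment: int = 4
    keep_top: int = 1            # number of components to keep


@dataclass
class VesselTree:
    lines: list[Centerline] = field(default_factory=list)
    links: list[tuple[int, int]] = field(default_factory=list)
    components: list[list[int]] = field(default_factory=list)

    def all_points(self) -> np.ndarray:
        if not self.lines:
            return np.zeros((0, 2))
        return np.concatenate([ln.positions() for ln in self.lines])

    def all_diameters(self) -> np.ndarray:
        if not self.lines:
            return np.zeros(0)
        return np.concatenate([ln.diameters() for ln in self.lines])

    def total_length(self, component: Sequence[int] | None = None) -> float:
        idxs = range(len(self.lines)) if component is None else component
        return float(sum(self.lines[i].arc_length() for i in idxs))


def _point_to_polyline_dist(p: np.ndarray, poly: np.ndarray) -> float:
    """Distance from p to the polyline (segment-wise projection)."""
    if len(poly) == 1:
        return float(np.linalg.norm(p - poly[0]))
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - p, axis=1).min())


def build_components(lines: Sequence[Centerline],
                     merge_tol: float = 6.0) -> VesselTree:
    """Link lines whose endpoints touch another line; group by links.

    Two lines are linked when any endpoint of one lies within merge_tol
    of the other line (endpoint-to-polyline distance); explicit
    bifurcation parent links are honored as well.
    """
    lines = list(lines)
    g = nx.Graph()
    g.add_nodes_from(range(len(lines)))
    polys = [ln.positions() for ln in lines]
    ends = [(poly[0], poly[-1]) if len(poly) else None for poly in polys]
    for i, ln in enumerate(lines):
        if ln.parent is not None and 0 <= ln.parent < len(lines):
            g.add_edge(i, ln.parent)
        for j in getattr(ln, "joins", ()):   # criterion-3 junction links
            if 0 <= j < len(lines) and j != i:
                g.add_edge(i, j)
    for i in range(len(lines)):
        if ends[i] is None:
            continue
        for j in range(len(lines)):
            if i == j or ends[j] is None or g.has_edge(i, j):
                continue
            if any(_point_to_polyline_dist(e, polys[j]) <= merge_tol
                   for e in ends[i]):
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    return VesselTree(lines=lines, links=sorted(g.edges()),
                      components=comps)


def prune_short(tree: VesselTree, min_length: float = 20.0,
                merge_tol: float = 6.0) -> VesselTree:
    """Drop lines shorter than min_length whose removal keeps components whole."""
    if min_length <= 0:
        return tree
    g = nx.Graph()
    g.add_nodes_from(range(len(tree.lines)))
    g.add_edges_from(tree.links)
    keep = set(g.nodes)
    # remove shortest first so chains of hairs fall off progressively
    for i in sorted(keep, key=lambda k: tree.lines[k].arc_length()):
        if tree.lines[i].arc_length() >= min_length:
            continue
        sub = g.subgraph(keep)
        comp = nx.node_connected_component(sub, i)
        if len(comp) > 1:
            without = sub.subgraph(comp - {i})
            if not nx.is_connected(without):
                continue   # interior line: removal would split the component
        keep.discard(i)
    new_ids = {old: new for new, old in enumerate(sorted(keep))}
    lines = []
    for old in sorted(keep):
        ln = tree.lines[old]
        ln.parent = new_ids.get(ln.parent) if ln.parent in new_ids else None
        ln.joins = [new_ids[j] for j in ln.joins if j in new_ids]
        lines.append(ln)
    return build_components(lines, merge_tol)


def keep_largest(tree: VesselTree, keep_top: int = 1) -> VesselTree:
    """Retain the component(s) with the greatest total arc length.

    Ties prefer the component containing the lowest line index
    (deterministic).
    """
    if not tree.components:
        return tree
    ranked = sorted(tree.components,
                    key=lambda c: (-tree.total_length(c), c[0]))
    chosen = ranked[:keep_top]
    keep = sorted(i for c in chosen for i in c)
    new_ids = {old: new for new, old in enumerate(keep)}
    lines = []
    for old in keep:
        ln = tree.lines[old]
        ln.parent = new_ids.get(ln.parent) if ln.parent in new_ids else None
        ln.joins = [new_ids[j] for j in ln.joins if j in new_ids]
        lines.append(ln)
    links = sorted((new_ids[a], new_ids[b]) for a, b in tree.links
                   if a in new_ids and b in new_ids)
    comps = [sorted(new_ids[i] for i in c) for c in chosen]
    return VesselTree(lines=lines, links=links, components=sorted(comps))


def smooth_spline(line: Centerline, tension: float = 0.0,
                  samples_per_segment: int = 4) -> Centerline:
    """Cardinal-spline smoothing with uniform resampling.

    Hermite segments with tangents m_i = (1 - tension)/2 *
    (P_{i+1} - P_{i-1}) (one-sided at the ends) interpolate every input
    point; each segment is resampled at samples_per_segment points and
    diameters are linearly interpolated.  Lines with fewer than 4 points
    are returned unchanged.
    """
    pts = line.positions()
    n = len(pts)
    if n < 4:
        return line
    diam = line.diameters()
    scale = (1.0 - tension) / 2.0
    tangents = np.empty_like(pts)
    tangents[1:-1] = scale * (pts[2:] - pts[:-2])
    tangents[0] = scale * 2.0 * (pts[1] - pts[0])
    tangents[-1] = scale * 2.0 * (pts[-1] - pts[-2])

    k = max(int(samples_per_segment), 1)
    t = np.linspace(0.0, 1.0, k, endpoint=False)
    h00 = 2 * t ** 3 - 3 * t ** 2 + 1
    h10 = t ** 3 - 2 * t ** 2 + t
    h01 = -2 * t ** 3 + 3 * t ** 2
    h11 = t ** 3 - t ** 2

    out_pts: list[np.ndarray] = []
    out_d: list[np.ndarray] = []
    for i in range(n - 1):
        seg = (h00[:, None] * pts[i] + h10[:, None] * tangents[i]
               + h01[:, None] * pts[i + 1] + h11[:, None] * tangents[i + 1])
        out_pts.append(seg)
        out_d.append(diam[i] + t * (diam[i + 1] - diam[i]))
    out_pts.append(pts[-1:])
    out_d.append(diam[-1:])
    new_pts = np.concatenate(out_pts)
    new_d = np.concatenate(out_d)

    new_points = []
    for i, (p, d) in enumerate(zip(new_pts, new_d)):
        if i + 1 < len(new_pts):
            step = new_pts[i + 1] - p
        else:
            step = p - new_pts[i - 1]
        norm = np.linalg.norm(step)
        u = step / norm if norm > 0 else np.array([1.0, 0.0])
        new_points.append(CenterlinePoint(
            x=float(p[0]), y=float(p[1]), ux=float(u[0]), uy=float(u[1]),
            theta=math.atan2(u[1], u[0]), diameter=float(d),
            source="tracked"))
    return Centerline(points=new_points, origin_seed=line.origin_seed,
                      parent=line.parent, joins=list(line.joins),
                      term_forward=line.term_forward,
                      term_backward=line.term_backward)


def refine(lines: Sequence[Centerline],
           params: RefinementParams | None = None) -> VesselTree:
    """Full refinement chain: components -> prune -> largest -> smooth."""
    params = params or RefinementParams()
    tree = build_components(lines, params.merge_tol)
    tree = prune_short(tree, params.min_length, params.merge_tol)
    tree = keep_largest(tree, params.keep_top)
    tree.lines = [smooth_spline(ln, params.tension,
                                params.samples_per_segment)
                  for ln in tree.lines]
    return tree


def tree_to_json(tree: VesselTree) -> dict:
    """JSON-serializable vessel tree."""
    return {
        "lines": [
            {
                "parent": ln.parent,
                "termination": [ln.term_backward, ln.term_forward],
                "points": [[p.x, p.y, p.theta, p.diameter]
                           for p in ln.points],
            }
            for ln in tree.lines
        ],
        "links": [list(l) for l in tree.links],
        "components": [list(c) for c in tree.components],
    }


def save_tree(tree: VesselTree, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_json(tree), fh)
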