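"""End-to-end pipeline: enhancement -> seeds -> tracking -> refinement."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .enhancement import multiscale_enhance
from .image import GrayImage, save_image
from .refinement import VesselTree, refine, save_tree
from .seeds import find_seeds, seeds_to_csv
from .simulator import Phantom
from .tracking import track_all

__all__ = ["run_pipeline"]

log = logging.getLogger("agvt")


def run_pipeline(source: GrayImage | Phantom | np.ndarray,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> VesselTree:
    """Run the full extraction chain and optionally write artifacts.

    ``source`` may be a loaded angiogram (dark vessels by default; set
    enhancement.polarity accordingly), a Phantom (its clinical-polarity
    view is used so the default config applies uniformly), or a bare 2D
    array treated as a GrayImage.
    """
    config = config or PipelineConfig()
    if isinstance(source, Phantom):
        img = source.angiogram()
    elif isinstance(source, np.ndarray):
        img = GrayImage(source)
    else:
        img = source
    enh = config.enhancement

    t0 = time.perf_counter()
    re = multiscale_enhance(img, scales=enh.scales, alpha=enh.alpha,
                            beta=enh.beta, gamma=enh.gamma,
                            polarity=enh.polarity)
    t1 = time.perf_counter()
    seeds = find_seeds(re, config.seeds)
    t2 = time.perf_counter()

    # tracking measures intensity profiles on a bright-vessel image
    bright = img.pixels if enh.polarity == "bright" else 1.0 - img.pixels
    lines = track_all(seeds, re, bright, config.tracking)
    t3 = time.perf_counter()
    tree = refine(lines, config.refinement)
    t4 = time.perf_counter()

    if config.verbosity >= 1:
        log.info("enhancement %.2fs | %d seeds %.2fs | %d lines %.2fs | "
                 "%d kept %.2fs", t1 - t0, len(seeds), t2 - t1, len(lines),
                 t3 - t2, len(tree.lines), t4 - t3)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_image(re.response, out / "re_image.tiff", bit_depth=32)
        seeds_to_csv(seeds, out / "seeds.csv")
        save_tree(tree, out / "centerlines.json")
        _write_points_csv(tree, out / "centerlines.csv")
        _render_overlay(img, tree, out / "overlay.png")
    return tree


def _write_points_csv(tree: VesselTree, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("line_id,point_index,x,y,theta,diameter\n")
        for li, ln in enumerate(tree.lines):
            for pi, p in enumerate(ln.points):
                fh.write(f"{li},{pi},{p.x:.4f},{p.y:.4f},"
                         f"{p.theta:.6f},{p.diameter:.4f}\n")


def _render_overlay(img: GrayImage, tree: VesselTree, path: Path) -> None:
    """Centerlines and +/- D/2 boundary curves over the angiogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.pixels, cmap="gray", vmin=0, vmax=1)
    for ln in tree.lines:
        pos = ln.positions()
        if len(pos) < 2:
            continue
        ax.plot(pos[:, 0], pos[:, 1], "-", color="red", lw=1)
        d = ln.diameters()
        u = np.array([[p.ux, p.uy] for p in ln.points])
        n = np.column_stack([-u[:, 1], u[:, 0]])
        for sign in (+1, -1):
            edge = pos + sign * (d[:, None] / 2.0) * n
            ax.plot(edge[:, 0], edge[:, 1], "-", color="lime", lw=0.6)
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=120)
    plt.close(fig)
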