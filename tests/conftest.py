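"""Shared fixtures: phantoms and pipeline products reused across modules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from agvt.config import PipelineConfig
from agvt.enhancement import VesselnessMap, multiscale_enhance
from agvt.refinement import refine
from agvt.seeds import find_seeds
from agvt.simulator import make_phantom
from agvt.tracking import track_all


@pytest.fixture(scope="session")
def v1_clean():
    """Noise-free straight-vessel phantom (oblique pose, diameter 8 px)."""
    return make_phantom("V1", noise_power=0.0, seed=0)


@pytest.fixture(scope="session")
def v1_clean_re(v1_clean):
    return multiscale_enhance(v1_clean.angiogram())


@pytest.fixture(scope="session")
def v1_noisy():
    return make_phantom("V1", noise_power=5.0, seed=1)


@pytest.fixture(scope="session")
def v1_noisy_artifacts(v1_noisy):
    """Full pipeline products on the moderately noisy straight vessel."""
    cfg = PipelineConfig()
    img = v1_noisy.angiogram()
    re = multiscale_enhance(img)
    seeds = find_seeds(re, cfg.seeds)
    bright = 1.0 - img.pixels
    lines = track_all(seeds, re, bright, cfg.tracking)
    raw_positions = [ln.positions().copy() for ln in lines]
    tree = refine(lines, cfg.refinement)
    return {"re": re, "seeds": seeds, "lines": lines,
            "raw_positions": raw_positions, "tree": tree}


@pytest.fixture(scope="session")
def v7_clean():
    return make_phantom("V7", noise_power=0.0, seed=2)


@pytest.fixture(scope="session")
def v7_tree(v7_clean):
    from agvt.pipeline import run_pipeline

    return run_pipeline(v7_clean)


def make_ridge_re(shape=(96, 96), angle=0.0, center=None, width=2.0,
                  envelope=200.0, border_band=4) -> VesselnessMap:
    """Analytic straight-ridge RE map through `center` at `angle`.

    A Gaussian cross-section ridge with a broad intensity envelope along
    the axis (so the along-ridge curvature is mildly negative, as for any
    finite vessel).
    """
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dx, dy = X - center[0], Y - center[1]
    u = dx * math.cos(angle) + dy * math.sin(angle)       # along ridge
    v = -dx * math.sin(angle) + dy * math.cos(angle)      # across ridge
    resp = 0.9 * np.exp(-v ** 2 / (2 * width ** 2)) \
        * np.exp(-u ** 2 / (2 * envelope ** 2))
    return VesselnessMap(response=resp, best_scale=np.full(shape, 2.0),
                         scales=(2.0,), alpha=0.5, beta=None,
                         border_band=border_band)
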