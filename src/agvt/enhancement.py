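"""Multiscale Hessian vesselness ("ridge enhancement").

The first stage of the pipeline turns an angiogram into the RE image: a
per-pixel tubularity response in [0, 1). At every scale sigma the image is
convolved with second derivatives of an isotropic Gaussian, the 2x2
Hessian is diagonalized, and the eigenvalues are combined into the
Frangi-type response

    V(p, sigma) = exp(-lam1^2 / (2 alpha^2 lam2^2))
                  * (1 - exp(-(lam1^2 + lam2^2) / (2 beta^2)))

gated to zero on the wrong intensity polarity.  The RE image is the
pointwise maximum of V over the scale list; the winning scale is kept as a
per-pixel map.

Eigenvalues are ordered by magnitude, |lam1| <= |lam2|, so the first
factor is the blobness ratio (near 0 for a line, near 1 for a blob) and
the second is structureness (suppresses flat background).  For dark
vessels on a bright background (the usual angiographic polarity) the
transverse curvature across the vessel is positive, so the response is
zeroed where lam2 < 0; ``polarity='bright'`` flips the gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "HessianField",
    "EigenField",
    "VesselnessMap",
    "hessian_at_scale",
    "eigen_decompose",
    "vesselness_at_scale",
    "multiscale_enhance",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass
class HessianField:
    """Scale-normalized second derivatives of an image at one scale."""

    sigma: float
    gamma: float
    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray


@dataclass
class EigenField:
    """Per-pixel Hessian eigenvalues ordered by magnitude |lam1| <= |lam2|."""

    lambda1: np.ndarray
    lambda2: np.ndarray


@dataclass
class VesselnessMap:
    """The RE image: multiscale maximum response and the winning scale."""

    response: np.ndarray
    best_scale: np.ndarray
    scales: tuple[float, ...]
    alpha: float
    beta: float | None
    polarity: str = "dark"
    border_band: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.response.shape


def hessian_at_scale(img: GrayImage | np.ndarray, sigma: float,
                     gamma: float = 1.0) -> HessianField:
    """Hessian of the Gaussian scale-space image, times sigma**gamma.

    Boundary handling is edge replication. Note the (x, y) = (col, row)
    convention: ixx differentiates along columns.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    norm = sigma ** gamma
    # ndimage order tuples are (row, col) = (y, x); truncate=6 keeps the
    # sampled second-derivative kernel's zero-sum property to ~1e-9
    ixx = norm * ndimage.gaussian_filter(arr, sigma, order=(0, 2),
                                         mode="nearest", truncate=6.0)
    iyy = norm * ndimage.gaussian_filter(arr, sigma, order=(2, 0),
                                         mode="nearest", truncate=6.0)
    ixy = norm * ndimage.gaussian_filter(arr, sigma, order=(1, 1),
                                         mode="nearest", truncate=6.0)
    return HessianField(sigma=sigma, gamma=gamma, ixx=ixx, ixy=ixy, iyy=iyy)


def eigen_decompose(h: HessianField) -> EigenField:
    """Closed-form eigenvalues of the symmetric 2x2 Hessian per pixel.

    lam = (t +/- sqrt(t^2 - 4 d)) / 2 with t the trace and d the
    determinant; output ordered |lam1| <= |lam2|.  When the magnitudes tie
    (t = 0), lam2 takes the negative root so the polarity gate sees the
    negative eigenvalue, deterministically.
    """
    t = h.ixx + h.iyy
    # discriminant (ixx-iyy)^2 + 4 ixy^2 >= 0 always for symmetric input
    disc = np.sqrt(np.maximum((h.ixx - h.iyy) ** 2 + 4.0 * h.ixy ** 2, 0.0))
    hi = 0.5 * (t + disc)   # algebraically larger root
    lo = 0.5 * (t - disc)
    hi_dominates = np.abs(hi) > np.abs(lo)
    lam2 = np.where(hi_dominates, hi, lo)
    lam1 = np.where(hi_dominates, lo, hi)
    return EigenField(lambda1=lam1, lambda2=lam2)


def vesselness_at_scale(eig: EigenField, alpha: float, beta: float,
                        polarity: str = "dark") -> np.ndarray:
    """Single-scale vesselness response in [0, 1).

    ``dark`` zeroes the response where lam2 < 0 (enhances dark tubes on a
    bright background); ``bright`` zeroes where lam2 > 0.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    lam1, lam2 = eig.lambda1, eig.lambda2
    lam2_sq = lam2 ** 2
    s_sq = lam1 ** 2 + lam2_sq
    with np.errstate(divide="ignore", invalid="ignore"):
        blob_sq = np.where(lam2_sq > 0, lam1 ** 2 / lam2_sq, 0.0)
    resp = np.exp(-blob_sq / (2.0 * alpha ** 2)) * \
        (1.0 - np.exp(-s_sq / (2.0 * beta ** 2)))
    gate = lam2 < 0 if polarity == "dark" else lam2 > 0
    resp[gate] = 0.0
    # the structureness factor saturates to 1.0 in floating point for
    # beta << |lam|; keep the open upper bound of the response
    return np.minimum(resp, np.nextafter(1.0, 0.0))


def _auto_beta(eig: EigenField) -> float:
    """Half the maximum Frobenius norm of the Hessian over the image.

    Floored so beta**2 cannot underflow to zero on (near-)constant
    images, where the response is identically zero anyway.
    """
    s_max = float(np.sqrt((eig.lambda1 ** 2 + eig.lambda2 ** 2).max()))
    return max(0.5 * s_max, 1e-12)


def multiscale_enhance(img: GrayImage | np.ndarray,
                       scales: Sequence[float] = DEFAULT_SCALES,
                       alpha: float = 0.5,
                       beta: float | None = None,
                       gamma: float = 1.0,
                       polarity: str = "dark") -> VesselnessMap:
    """Compute the RE image: max response over the scale list.

    ``beta=None`` sets beta per scale to half the maximum Frobenius norm
    of the Hessian observed at that scale (structureness then adapts to
    the image contrast); a float fixes it globally.  Ties in the
    per-pixel argmax keep the smallest scale.
    """
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scale list must be nonempty")
    if any(s <= 0 for s in scales):
        raise ValueError("all scales must be positive")
    if list(scales) != sorted(scales):
        raise ValueError("scales must be sorted ascending")

    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    response = np.zeros_like(arr)
    best_scale = np.full(arr.shape, scales[0], dtype=np.float64)
    for sigma in scales:
        eig = eigen_decompose(hessian_at_scale(arr, sigma, gamma))
        b = _auto_beta(eig) if beta is None else beta
        resp = vesselness_at_scale(eig, alpha, b, polarity)
        better = resp > response  # strict: ties keep the smaller sigma
        best_scale[better] = sigma
        np.maximum(response, resp, out=response)
    band = int(math.ceil(3.0 * max(scales)))
    return VesselnessMap(response=response, best_scale=best_scale,
                         scales=scales, alpha=alpha, beta=beta,
                         polarity=polarity, border_band=band)
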