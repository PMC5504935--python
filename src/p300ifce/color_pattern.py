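"""Pixel-level color representations for the fuzzy color extractor.

A pixel is treated as a 3-vector in RGB space: the vector length encodes
illumination intensity, the direction encodes the color itself.  The
similarity pattern between two pixels is therefore the angle between their
RGB vectors, which is invariant under multiplicative illumination change.
This module provides that angle, the plain per-channel differences, the
squared Euclidean RGB distance used as a region-growing stop gate, and the
percentage variation-rate metric used to quantify illumination change.

Images are plain ``numpy`` arrays of shape ``(M, N, 3)`` with dtype
``uint8`` (row ``m``, column ``n``, 0-based row-major); single pixels are
any length-3 sequence of integers in ``[0, 255]``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "DegeneratePixelError",
    "as_pixel",
    "validate_image",
    "channel_differences",
    "vector_angle",
    "angle_map",
    "rgb_distance_sq",
    "variation_rate",
]


class DegeneratePixelError(ValueError):
    """The all-zero pixel has no direction; its angle is undefined."""


def as_pixel(p) -> np.ndarray:
    """Validate and return ``p`` as an int array of shape (3,)."""
    arr = np.asarray(p)
    if arr.shape != (3,):
        raise ValueError(f"pixel must have exactly 3 channels, got shape {arr.shape}")
    arr = arr.astype(np.int64)
    if (arr < 0).any() or (arr > 255).any():
        raise ValueError(f"channels must lie in [0, 255], got {tuple(arr)}")
    return arr


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check an (M, N, 3) raster of 8-bit pixels and return it as uint8."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"image must have shape (M, N, 3), got {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    if img.dtype != np.uint8:
        if (np.asarray(img) < 0).any() or (np.asarray(img) > 255).any():
            raise ValueError("image values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def channel_differences(p, q) -> tuple[int, int, int]:
    """Signed per-channel differences ``(pR-qR, pG-qG, pB-qB)``.

    The classical way to compare two pixels: three separate signed
    distances, one per channel, each in [-255, 255].
    """
    pa, qa = as_pixel(p), as_pixel(q)
    d = pa - qa
    return int(d[0]), int(d[1]), int(d[2])


def vector_angle(p, q) -> float:
    """Angle (radians) between the RGB vectors of two pixels.

    ``arccos`` of the normalized dot product; 0 for collinear pixels (same
    color under any illumination scale), pi/2 for orthogonal primaries.
    Symmetric in its arguments and confined to [0, pi/2] for non-negative
    channels.

    Raises
    ------
    DegeneratePixelError
        If either pixel is all-zero (zero-length vector).
    """
    pa, qa = as_pixel(p).astype(float), as_pixel(q).astype(float)
    np_len, nq_len = np.linalg.norm(pa), np.linalg.norm(qa)
    if np_len == 0.0 or nq_len == 0.0:
        raise DegeneratePixelError("vector angle undefined for the all-zero pixel")
    cosine = float(np.dot(pa, qa) / (np_len * nq_len))
    # clamp: rounding can push the cosine infinitesimally outside [-1, 1]
    return float(np.arccos(min(1.0, max(-1.0, cosine))))


def angle_map(image: np.ndarray, seed) -> np.ndarray:
    """Vector angle of every pixel of ``image`` to ``seed``, vectorized.

    Degenerate (all-zero) pixels are assigned ``+inf`` so they never win a
    minimal-angle selection and never match.
    """
    img = validate_image(image).astype(np.float64)
    s = as_pixel(seed).astype(np.float64)
    s_len = np.linalg.norm(s)
    if s_len == 0.0:
        raise DegeneratePixelError("vector angle undefined for an all-zero seed")
    lengths = np.linalg.norm(img, axis=2)
    dots = img @ s
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = dots / (lengths * s_len)
    angles = np.arccos(np.clip(cos, -1.0, 1.0))
    angles[lengths == 0.0] = np.inf
    return angles


def rgb_distance_sq(p, q) -> int:
    """Squared Euclidean RGB distance ``sum_i (p_i - q_i)^2``.

    Deliberately left un-rooted: the region-growing stop gate compares this
    quantity directly against its threshold ``r``, which therefore carries
    squared-intensity units.
    """
    pa, qa = as_pixel(p), as_pixel(q)
    d = pa - qa
    return int(np.dot(d, d))


def variation_rate(v_ref: float, v_alt: float) -> float:
    """Percent change of ``v_alt`` relative to ``v_ref``, one decimal.

    ``100 * |v_ref - v_alt| / v_ref`` rounded half-up to one decimal place.
    The reference is the first-measured (e.g. morning) value.

    Raises
    ------
    ValueError
        If ``v_ref`` is not strictly positive.
    """
    if v_ref <= 0:
        raise ValueError(f"reference value must be positive, got {v_ref}")
    rate = 100.0 * abs(v_ref - v_alt) / v_ref
    return float(Decimal(repr(rate)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
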