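"""Seeded object extraction by fuzzy subregion growing.

Pipeline: the pixel with the minimal RGB vector angle to the seed starts a
subregion; the subregion is the breadth-first closure of fuzzily matched
pixels under a chosen neighborhood pattern (4-adjacent, 4-diagonal or
8-neighbor); further subregions are grown from the next minimal-angle
unassigned pixel until the candidate either fails the fuzzy match or fails
the squared-RGB-distance gate ``d(p, seed) < r``; the largest subregion is
taken as the object; finally short unextracted runs bounded by extracted
pixels are filled along rows, then columns.

The per-pixel match is vectorized through the critical angle ``a*`` (the
defuzzified output is monotone in the angle, so "extract" is exactly
``angle < a*``); :func:`p300ifce.fuzzy_engine.match_decision` runs the full
chain and the two agree by construction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .color_pattern import angle_map, as_pixel, validate_image
from .fuzzy_engine import FuzzyParams, angle_match_threshold

__all__ = [
    "CONNECTIVITIES",
    "GrowthConfig",
    "Subregion",
    "NoObjectError",
    "UnmatchedStartError",
    "find_start_pixel",
    "grow_subregion",
    "extract_subregions",
    "select_object",
    "rasterize",
    "fill_gaps",
    "extract_object",
    "read_image",
    "write_mask",
    "read_mask",
]

#: Neighborhood offsets for the three growing patterns.
CONNECTIVITIES: dict[str, tuple[tuple[int, int], ...]] = {
    "4-adjacent": ((-1, 0), (1, 0), (0, -1), (0, 1)),
    "4-diagonal": ((-1, -1), (-1, 1), (1, -1), (1, 1)),
    "8-neighbor": ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


class NoObjectError(ValueError):
    """No subregion could be extracted for the requested seed."""


class UnmatchedStartError(ValueError):
    """Growth was started from a pixel that does not match the seed."""


@dataclass(frozen=True)
class GrowthConfig:
    """Region-growing configuration.

    ``r`` is the squared-RGB-distance gate applied to each new subregion's
    start candidate (``inf`` disables it); ``per_pixel_gate`` additionally
    applies the gate to every pixel during growth.  ``max_subregions``
    bounds pathological inputs.
    """

    connectivity: str = "8-neighbor"
    r: float = 1000.0
    gap_threshold: int = 3
    max_subregions: int = 512
    per_pixel_gate: bool = False

    def __post_init__(self) -> None:
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(
                f"connectivity must be one of {sorted(CONNECTIVITIES)}, got {self.connectivity!r}"
            )
        if not self.r > 0:
            raise ValueError(f"need r > 0, got {self.r}")
        if self.gap_threshold < 0:
            raise ValueError("gap_threshold must be >= 0")
        if self.max_subregions < 1:
            raise ValueError("max_subregions must be >= 1")


@dataclass(frozen=True)
class Subregion:
    """A connected set of raster coordinates matching one seed."""

    coordinates: frozenset[tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.coordinates)


def _matched_mask(image: np.ndarray, seed, params: FuzzyParams, cfg: GrowthConfig) -> np.ndarray:
    angles = angle_map(image, seed)
    a_star = angle_match_threshold(params)
    matched = angles < a_star
    if cfg.per_pixel_gate and np.isfinite(cfg.r):
        matched &= _dist_sq_map(image, seed) < cfg.r
    return matched


def _dist_sq_map(image: np.ndarray, seed) -> np.ndarray:
    diff = validate_image(image).astype(np.int64) - as_pixel(seed)
    return (diff * diff).sum(axis=2)


def find_start_pixel(image: np.ndarray, seed, remaining) -> tuple[int, int]:
    """Coordinate in ``remaining`` with the minimal vector angle to the seed.

    Ties are broken by row-major scan order; degenerate (all-zero) pixels
    carry angle ``+inf`` and are only chosen if nothing else remains.
    """
    coords = sorted(remaining)
    if not coords:
        raise ValueError("no remaining pixels to start from")
    angles = angle_map(image, seed)
    best = coords[0]
    best_angle = angles[best]
    for c in coords[1:]:
        if angles[c] < best_angle:
            best, best_angle = c, angles[c]
    return tuple(best)


def grow_subregion(
    image: np.ndarray,
    start: tuple[int, int],
    seed,
    params: FuzzyParams,
    cfg: GrowthConfig | None = None,
    *,
    _matched: np.ndarray | None = None,
    _available: np.ndarray | None = None,
) -> Subregion:
    """Breadth-first closure of matched pixels reachable from ``start``.

    Growth explores the neighborhood pattern named by ``cfg.connectivity``
    and stops when no matched pixel is adjacent to the subregion.
    """
    cfg = cfg or GrowthConfig(r=params.r, gap_threshold=params.gap_threshold)
    image = validate_image(image)
    M, N = image.shape[:2]
    matched = _matched if _matched is not None else _matched_mask(image, seed, params, cfg)
    if _available is not None:
        matched = matched & _available
    m0, n0 = start
    if not (0 <= m0 < M and 0 <= n0 < N):
        raise ValueError(f"start {start} outside the {M}x{N} image")
    if not matched[m0, n0]:
        raise UnmatchedStartError(f"start pixel {start} does not match the seed")

    offsets = CONNECTIVITIES[cfg.connectivity]
    seen = np.zeros((M, N), dtype=bool)
    seen[m0, n0] = True
    queue = deque([(m0, n0)])
    coords = []
    while queue:
        m, n = queue.popleft()
        coords.append((m, n))
        for dm, dn in offsets:
            mm, nn = m + dm, n + dn
            if 0 <= mm < M and 0 <= nn < N and not seen[mm, nn] and matched[mm, nn]:
                seen[mm, nn] = True
                queue.append((mm, nn))
    return Subregion(frozenset(coords))


def extract_subregions(
    image: np.ndarray, seed, params: FuzzyParams, cfg: GrowthConfig | None = None
) -> list[Subregion]:
    """Grow subregions in minimal-angle order until the stop conditions hit.

    Each round selects the unassigned pixel with the minimal angle to the
    seed; if it fails the fuzzy match or the distance gate ``< r`` the
    process stops, otherwise its connected matched component is extracted.
    May return an empty list.
    """
    cfg = cfg or GrowthConfig(r=params.r, gap_threshold=params.gap_threshold)
    image = validate_image(image)
    angles = angle_map(image, seed)
    matched = _matched_mask(image, seed, params, cfg)
    dist_sq = _dist_sq_map(image, seed) if np.isfinite(cfg.r) else None
    remaining = np.ones(image.shape[:2], dtype=bool)

    subregions: list[Subregion] = []
    while len(subregions) < cfg.max_subregions and remaining.any():
        masked = np.where(remaining, angles, np.inf)
        flat = int(np.argmin(masked))  # first minimum in row-major order
        start = (flat // image.shape[1], flat % image.shape[1])
        if not np.isfinite(masked[start]):
            break  # only degenerate pixels remain
        if not matched[start]:
            break
        if dist_sq is not None and not dist_sq[start] < cfg.r:
            break
        sub = grow_subregion(
            image, start, seed, params, cfg, _matched=matched, _available=remaining
        )
        subregions.append(sub)
        rows, cols = zip(*sub.coordinates)
        remaining[rows, cols] = False
    return subregions


def select_object(subregions: list[Subregion]) -> Subregion:
    """The subregion with the most pixels; earliest extraction wins ties."""
    if not subregions:
        raise NoObjectError("no subregions to select from")
    best = subregions[0]
    for sub in subregions[1:]:
        if sub.size > best.size:
            best = sub
    return best


def rasterize(subregion: Subregion, shape: tuple[int, int]) -> np.ndarray:
    """Binary 0/1 mask of a subregion on an ``(M, N)`` raster."""
    mask = np.zeros(shape, dtype=np.uint8)
    if subregion.coordinates:
        rows, cols = zip(*subregion.coordinates)
        mask[list(rows), list(cols)] = 1
    return mask


def _fill_runs_1d(line: np.ndarray, gap_threshold: int) -> None:
    """Set runs of 0s strictly shorter than the threshold when bounded by 1s."""
    ones = np.flatnonzero(line)
    for a, b in zip(ones[:-1], ones[1:]):
        if 0 < b - a - 1 < gap_threshold:
            line[a + 1 : b] = 1


def fill_gaps(mask: np.ndarray, gap_threshold: int) -> np.ndarray:
    """Fill short unextracted runs along every row, then every column.

    A maximal run of 0s bounded by 1s on both sides is set to 1 when its
    length is strictly below ``gap_threshold``.  Monotone (never clears a
    pixel) and idempotent at a fixed threshold.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be >= 0")
    out = (np.asarray(mask) != 0).astype(np.uint8)
    for row in out:
        _fill_runs_1d(row, gap_threshold)
    for col in out.T:
        _fill_runs_1d(col, gap_threshold)
    return out


def extract_object(image: np.ndarray, entry, cfg: GrowthConfig | None = None) -> np.ndarray:
    """End-to-end extraction for one dataset entry: 0/1 object mask.

    ``entry`` carries the seed pixel and fuzzy parameters (a
    :class:`p300ifce.p300_speller.SeedDatasetEntry`).  Raises
    :class:`NoObjectError` when nothing in the image matches the seed.
    """
    params = entry.params
    cfg = cfg or GrowthConfig(r=params.r, gap_threshold=params.gap_threshold)
    subregions = extract_subregions(image, entry.seed, params, cfg)
    if not subregions:
        raise NoObjectError(f"no subregion matches object {getattr(entry, 'object_id', '?')}")
    obj = select_object(subregions)
    mask = rasterize(obj, validate_image(image).shape[:2])
    return fill_gaps(mask, cfg.gap_threshold)


# ---------------------------------------------------------------------------
# image / mask I/O (8-bit RGB PNG or PPM in; single-channel 0/255 PNG out)

def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return validate_image(img)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, ((np.asarray(mask) != 0) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return (iio.imread(path) != 0).astype(np.uint8)
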