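"""Step 2 — fiducial registration and temporal plant localization.

Four white marbles at the plot corners are detected in each selected frame
(classical detector: brightness percentile threshold → connected components
→ circularity gate → best blob per frame quadrant). A reference marker set
is the per-quadrant mean over frames; each frame is registered to it by the
exact 4-point homography and warped. A coarse segmenter applied patchwise
(384×384 tiles of the 4×-downsized frame, AND-merged on overlaps) gives a
per-frame binary plant mask; summing registered masks over time yields an
accumulation map whose local maxima are the plant positions. Positions are
snapped to the expected block × genotype grid for labeling and can be
manually edited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.feature import peak_local_max
from skimage.transform import ProjectiveTransform, resize, warp

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSet",
    "PlantPosition",
    "MarkerDetectionError",
    "DegenerateGeometryError",
    "detect_markers",
    "reference_markers",
    "estimate_homography",
    "warp_to_reference",
    "tile_and_merge",
    "accumulate_masks",
    "locate_plants",
    "edit_positions",
    "positions_to_frame",
]


class MarkerDetectionError(RuntimeError):
    """Fewer than four marbles found; carries the partial set."""

    def __init__(self, msg: str, partial: Optional["MarkerSet"] = None):
        super().__init__(msg)
        self.partial = partial


class DegenerateGeometryError(RuntimeError):
    """Marker geometry (e.g. collinear points) admits no homography."""


@dataclass(frozen=True)
class MarkerSet:
    """Four marker centers in (x, y) pixel coordinates, quadrant-ordered.

    Order is (top-left, top-right, bottom-right, bottom-left) by frame
    quadrant; x = column, y = row, origin top-left, 0-based.
    """

    centers: tuple  # 4 × (x, y)
    confidence: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.centers) != 4:
            raise ValueError("exactly four markers required")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.centers, dtype=float)


@dataclass(frozen=True)
class PlantPosition:
    plant_id: int
    x: float
    y: float
    block: int = -1
    genotype: int = -1
    source: str = "auto"  # auto | manual_add
    removed: bool = False


def _circularity(region) -> float:
    p = region.perimeter
    return 4 * np.pi * region.area / (p * p) if p > 0 else 0.0


def detect_markers(frame: np.ndarray, brightness_percentile: float = 99.5,
                   min_area: int = 30, min_circularity: float = 0.7) -> MarkerSet:
    """Detect the four corner marbles in an RGB frame.

    Whiteness (the per-pixel minimum over R, G, B — high only for near-white
    pixels) is thresholded at its ``brightness_percentile``; compact
    connected components pass area and circularity gates and the best blob
    (circularity × mean brightness) is kept per frame quadrant. Confidence
    is circularity × relative brightness.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be RGB")
    whiteness = frame.min(axis=2).astype(float)
    # floor at 75% of the brightest whiteness: the percentile alone dips far
    # below the marbles on large frames and merges them with bright soil
    thr = max(np.percentile(whiteness, brightness_percentile),
              0.75 * whiteness.max(), 1.0)
    binary = whiteness >= thr
    labels = measure.label(binary)
    h, w = whiteness.shape
    cy, cx = h / 2.0, w / 2.0
    best: dict[int, tuple] = {}
    for region in measure.regionprops(labels, intensity_image=whiteness):
        if region.area < min_area:
            continue
        circ = _circularity(region)
        if circ < min_circularity:
            continue
        ry, rx = region.centroid
        quad = (1 if rx >= cx else 0) + (2 if ry >= cy else 0)  # 0 TL,1 TR,2 BL,3 BR
        score = circ * region.intensity_mean
        if quad not in best or score > best[quad][0]:
            conf = min(1.0, circ) * min(1.0, region.intensity_mean / 255.0)
            best[quad] = (score, (rx, ry), conf)
    order = (0, 1, 3, 2)  # TL, TR, BR, BL
    if len(best) < 4:
        partial_pts = [best[q][1] for q in order if q in best]
        partial = None
        raise MarkerDetectionError(
            f"found {len(best)} of 4 marbles (quadrants {sorted(best)}); "
            f"partial centers: {partial_pts}")
    centers = tuple(best[q][1] for q in order)
    conf = tuple(best[q][2] for q in order)
    return MarkerSet(centers, conf)


def reference_markers(marker_sets: Sequence[MarkerSet]) -> MarkerSet:
    """Per-quadrant arithmetic mean of marker positions over frames."""
    if not marker_sets:
        raise ValueError("need at least one marker set")
    arr = np.stack([ms.as_array() for ms in marker_sets])
    mean = arr.mean(axis=0)
    # consistency: each frame's marker must stay nearest its own quadrant mean
    d = np.linalg.norm(arr - mean[None], axis=2)
    cross = np.linalg.norm(arr[:, :, None] - mean[None, None], axis=3)
    if np.any(d > cross.min(axis=2) + 1e-9):
        raise ValueError("inconsistent quadrant assignment across marker sets")
    conf = np.stack([ms.confidence for ms in marker_sets]).mean(axis=0)
    return MarkerSet(tuple(map(tuple, mean)), tuple(conf))


def estimate_homography(src: MarkerSet, dst: MarkerSet) -> np.ndarray:
    """Exact 4-point homography mapping src marker coords to dst coords.

    Returns the 3×3 matrix normalized to H[2,2] = 1. Collinear markers
    raise DegenerateGeometryError.
    """
    s, d = src.as_array(), dst.as_array()
    try:
        tf = ProjectiveTransform.from_estimate(s, d)
    except AttributeError:  # older scikit-image
        tf = ProjectiveTransform()
        if not tf.estimate(s, d):
            raise DegenerateGeometryError("homography estimation failed")
    if not tf or not np.all(np.isfinite(tf.params)):
        raise DegenerateGeometryError("homography estimation failed")
    H = tf.params
    if abs(np.linalg.det(H)) < 1e-12 or abs(H[2, 2]) < 1e-12:
        raise DegenerateGeometryError("degenerate (non-invertible) homography")
    H = H / H[2, 2]
    resid = np.linalg.norm(ProjectiveTransform(H)(s) - d, axis=1)
    if resid.max() > 1.0:
        logger.warning("homography residual %.3f px exceeds 1 px", resid.max())
    return H


def homography_residual(H: np.ndarray, src: MarkerSet, dst: MarkerSet) -> float:
    return float(np.linalg.norm(
        ProjectiveTransform(H)(src.as_array()) - dst.as_array(), axis=1).mean())


def warp_to_reference(frame: np.ndarray, H: np.ndarray,
                      output_shape: Optional[tuple] = None) -> np.ndarray:
    """Warp ``frame`` into the reference geometry given H: frame → reference.

    Bilinear inverse mapping; pixels without a source are 0. Output size
    defaults to the frame size.
    """
    H = np.asarray(H, dtype=float)
    if abs(np.linalg.det(H)) < 1e-12:
        raise DegenerateGeometryError("non-invertible homography")
    tf = ProjectiveTransform(H)
    out_shape = output_shape or frame.shape[:2]
    warped = warp(frame, tf.inverse, output_shape=out_shape, order=1,
                  mode="constant", cval=0.0, preserve_range=True)
    return warped.astype(frame.dtype) if np.issubdtype(frame.dtype, np.integer) \
        else warped


def _tile_origins(size: int, patch: int) -> list[int]:
    """Patch origins along one axis: ceiling division, last patch flush."""
    if size < patch:
        raise ValueError(f"axis of {size} px smaller than patch {patch}")
    n = -(-size // patch)
    origins = [i * patch for i in range(n)]
    origins[-1] = size - patch
    return origins


def tile_and_merge(registered_frame: np.ndarray,
                   coarse_segmenter: Callable[[np.ndarray], np.ndarray],
                   downscale: int = 4, patch_size: int = 384,
                   overlap_merge: str = "and",
                   prob_threshold: float = 0.5) -> np.ndarray:
    """Coarse full-frame plant mask via downscale → tile → segment → merge.

    The frame is downsized by ``downscale`` (a 4608×3456 capture becomes
    1152×864), tiled into ``patch_size``² patches by ceiling division with
    the last patch of each axis flush to the border (1152×864 → 9 patches),
    each patch segmented (``coarse_segmenter`` maps an RGB patch to per-pixel
    plant probability), overlapping regions merged by logical AND (or OR),
    and the mask upscaled back by nearest neighbor.
    """
    if overlap_merge not in ("and", "or"):
        raise ValueError("overlap_merge must be 'and' or 'or'")
    frame = np.asarray(registered_frame)
    h, w = frame.shape[:2]
    if downscale > 1:
        small = resize(frame, (h // downscale, w // downscale, frame.shape[2]),
                       order=1, anti_aliasing=True, preserve_range=True)
    else:
        small = frame.astype(float)
    sh, sw = small.shape[:2]
    votes = np.zeros((sh, sw), dtype=np.int32)
    cover = np.zeros((sh, sw), dtype=np.int32)
    for oy in _tile_origins(sh, patch_size):
        for ox in _tile_origins(sw, patch_size):
            patch = small[oy:oy + patch_size, ox:ox + patch_size]
            prob = np.asarray(coarse_segmenter(patch.astype(np.uint8)))
            if prob.shape != (patch_size, patch_size):
                raise ValueError("segmenter output shape mismatch")
            votes[oy:oy + patch_size, ox:ox + patch_size] += prob > prob_threshold
            cover[oy:oy + patch_size, ox:ox + patch_size] += 1
    if overlap_merge == "and":
        mask_small = votes == cover
    else:
        mask_small = votes >= 1
    if downscale > 1:
        mask = np.kron(mask_small, np.ones((downscale, downscale), dtype=bool))
        mask = mask[:h, :w]
        full = np.zeros((h, w), dtype=bool)
        full[:mask.shape[0], :mask.shape[1]] = mask
        return full
    return mask_small


def count_tiles(height: int, width: int, patch_size: int = 384) -> int:
    """Number of patches the tiler produces for a (height × width) frame."""
    return len(_tile_origins(height, patch_size)) * len(_tile_origins(width, patch_size))


def accumulate_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise sum of registered binary masks (the accumulation map)."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to accumulate")
    shape = np.asarray(masks[0]).shape
    acc = np.zeros(shape, dtype=np.int32)
    for m in masks:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError(f"mask shape {m.shape} != {shape}")
        acc += m.astype(bool)
    return acc


def locate_plants(acc: np.ndarray, min_distance: int,
                  rel_threshold: float = 0.3,
                  expected_grid: Optional[pd.DataFrame] = None,
                  smooth_sigma: Optional[float] = None) -> list[PlantPosition]:
    """Plant centers as local maxima of the accumulation map.

    The map is Gaussian-smoothed (default σ = min_distance/6) so the stable
    rosette core, not an individual leaf, carries the maximum; peaks must be
    ``min_distance`` apart and reach ``rel_threshold`` × the global maximum.
    When ``expected_grid`` (columns x, y, block, genotype) is given, each
    peak inherits the labels of the nearest expected cell. An all-zero map
    yields an empty list (logged).
    """
    from scipy import ndimage as ndi

    acc = np.asarray(acc)
    if acc.size == 0:
        raise ValueError("empty accumulation map")
    if acc.max() == 0:
        logger.warning("all-zero accumulation map: no plants located")
        return []
    if smooth_sigma is None:
        smooth_sigma = min_distance / 6.0
    smoothed = ndi.gaussian_filter(acc.astype(float), smooth_sigma) \
        if smooth_sigma > 0 else acc.astype(float)
    peaks = peak_local_max(smoothed, min_distance=int(min_distance),
                           threshold_rel=rel_threshold, exclude_border=False)
    # refine each peak to the centroid of its stable high-count plateau:
    # the rosette core keeps the full frame count, individual leaves do not
    refined = []
    r = max(1, int(min_distance) // 2)
    for (py, px) in peaks:
        y0, y1 = max(0, py - r), min(acc.shape[0], py + r + 1)
        x0, x1 = max(0, px - r), min(acc.shape[1], px + r + 1)
        win = acc[y0:y1, x0:x1].astype(float)
        plateau = win >= 0.95 * win.max()
        lab, _ = ndi.label(plateau)
        comp = lab == lab[py - y0, px - x0]
        if not comp.any():
            refined.append((float(py), float(px)))
            continue
        cy, cx = ndi.center_of_mass(win * comp)
        refined.append((y0 + cy, x0 + cx))
    positions = []
    for i, (py, px) in enumerate(refined):
        block = genotype = -1
        if expected_grid is not None and len(expected_grid):
            d = np.hypot(expected_grid["x"] - px, expected_grid["y"] - py)
            nearest = expected_grid.iloc[int(np.argmin(d))]
            block, genotype = int(nearest["block"]), int(nearest["genotype"])
        positions.append(PlantPosition(i, float(px), float(py), block, genotype))
    return positions


def _check_separation(positions: Sequence[PlantPosition], min_separation: float):
    act = [p for p in positions if not p.removed]
    for i, a in enumerate(act):
        for b in act[i + 1:]:
            if np.hypot(a.x - b.x, a.y - b.y) < min_separation:
                raise ValueError(
                    f"plants {a.plant_id} and {b.plant_id} closer than "
                    f"{min_separation} px")


def edit_positions(positions: Sequence[PlantPosition], manual_edits,
                   min_separation: float = 0.0) -> list[PlantPosition]:
    """Apply manual add/remove edits to a position map.

    ``manual_edits`` rows: action ∈ {add, remove}; 'remove' needs plant_id,
    'add' needs x, y (and optionally block/genotype). Additions carry
    source='manual_add'; removals only set the removed flag. The minimum
    separation invariant is re-checked afterwards.
    """
    out = {p.plant_id: p for p in positions}
    next_id = max(out, default=-1) + 1
    edits = manual_edits.to_dict("records") if isinstance(manual_edits, pd.DataFrame) \
        else list(manual_edits)
    for e in edits:
        action = str(e["action"]).lower()
        if action == "remove":
            pid = int(e["plant_id"])
            if pid not in out:
                raise KeyError(f"no plant with id {pid}")
            out[pid] = replace(out[pid], removed=True)
        elif action == "add":
            out[next_id] = PlantPosition(
                next_id, float(e["x"]), float(e["y"]),
                int(e.get("block", -1)), int(e.get("genotype", -1)),
                source="manual_add")
            next_id += 1
        else:
            raise ValueError(f"unknown edit action {action!r}")
    result = sorted(out.values(), key=lambda p: p.plant_id)
    if min_separation > 0:
        _check_separation(result, min_separation)
    return result


def positions_to_frame(positions: Sequence[PlantPosition]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in positions])
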