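"""Per-plant color extraction and color-space conversions.

The downstream pigment model works on CIELAB coordinates of the segmented
rosette; this module converts 8-bit sRGB values to L*a*b* (D65, 2° observer),
HSV and BT.601 YUV, computes the red/green vegetation indices used as
alternative feature sets, and summarizes the color of a plant over its
segmentation mask (mean and median per channel, background excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage import color as skcolor

__all__ = [
    "ColorSummary",
    "ColorIndexSet",
    "srgb_to_lab",
    "lab_to_srgb",
    "convert_color_space",
    "compute_indices",
    "summarize_plant_color",
]


@dataclass
class ColorSummary:
    """Mean/median color of one plant at one time point, mask pixels only.

    ``n_pixels == 0`` means the mask was empty; every color field is then NaN.
    """

    plant_id: object
    timestamp: object
    n_pixels: int
    mean_rgb: tuple = (np.nan, np.nan, np.nan)
    median_rgb: tuple = (np.nan, np.nan, np.nan)
    mean_lab: tuple = (np.nan, np.nan, np.nan)
    median_lab: tuple = (np.nan, np.nan, np.nan)

    @property
    def plant_area(self) -> int:
        return self.n_pixels

    def to_row(self) -> dict:
        r = {"plant_id": self.plant_id, "timestamp": self.timestamp,
             "n_pixels": self.n_pixels}
        for stat, rgb, lab in (("mean", self.mean_rgb, self.mean_lab),
                               ("median", self.median_rgb, self.median_lab)):
            for name, v in zip(("R", "G", "B"), rgb):
                r[f"{stat}_{name}"] = v
            for name, v in zip(("Lstar", "astar", "bstar"), lab):
                r[f"{stat}_{name}"] = v
        return r


@dataclass
class ColorIndexSet:
    """Scalar vegetation indices plus HSV/YUV triples for one RGB color."""

    ExR: float
    GRVI: float
    RGR: float
    hsv: tuple
    yuv: tuple


def _check_range(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    finite = rgb[np.isfinite(rgb)]
    if finite.size and (finite.min() < 0 or finite.max() > 255):
        raise ValueError("RGB channels must lie in 0–255")
    return rgb


#: IEC 61966-2-1 sRGB (linear) → XYZ, D65, 2° observer
_M_RGB2XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
#: reference white = the matrix's own white, so (1,1,1) → L*=100, a*=b*=0 exactly
_WHITE = _M_RGB2XYZ.sum(axis=1)
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)


def _srgb_eotf_inv(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_eotf(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def _lab_f(t: np.ndarray) -> np.ndarray:
    d = 6.0 / 29.0
    return np.where(t > d ** 3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)


def _lab_f_inv(f: np.ndarray) -> np.ndarray:
    d = 6.0 / 29.0
    return np.where(f > d, f ** 3, 3 * d * d * (f - 4.0 / 29.0))


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to CIE L*a*b* (D65, 2° observer).

    Accepts a single (R, G, B) triple or an (..., 3) image array in 0–255.
    The sRGB electro-optical transfer function is inverted, the linear
    values are mapped to XYZ and then to L*a*b*; (255,255,255) maps to
    exactly (100, 0, 0).
    """
    rgb = _check_range(rgb)
    xyz = _srgb_eotf_inv(rgb / 255.0) @ _M_RGB2XYZ.T
    f = _lab_f(xyz / _WHITE)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_srgb(lab) -> np.ndarray:
    """Inverse of :func:`srgb_to_lab`; returns float values in 0–255 (clipped)."""
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * _WHITE
    rgb = _srgb_eotf(xyz @ _M_XYZ2RGB.T)
    return np.clip(rgb, 0.0, 1.0) * 255.0


def convert_color_space(rgb, target: str) -> np.ndarray:
    """Convert 8-bit sRGB to ``target`` in {"HSV", "YUV"}.

    HSV hue is in degrees [0, 360); S, V in [0, 1]. YUV uses the BT.601
    luma coefficients with Y in [0, 1] and U, V centered on 0.
    """
    rgb = _check_range(rgb) / 255.0
    target = target.upper()
    if target == "HSV":
        hsv = skcolor.rgb2hsv(rgb)
        hsv = np.array(hsv, dtype=float)
        hsv[..., 0] = hsv[..., 0] * 360.0
        return hsv
    if target == "YUV":
        return skcolor.rgb2yuv(rgb)
    raise ValueError(f"unsupported target color space: {target!r}")


def compute_indices(rgb) -> ColorIndexSet:
    """Vegetation indices of an (R, G, B) triple in 0–255.

    ExR = (1.4 R − G)/(R + G + B); GRVI = (R − G)/(R + G); RGR = R/G.
    A zero denominator yields NaN for that index (missing, not an error).
    """
    r, g, b = (float(v) for v in _check_range(rgb))
    s = r + g + b
    exr = (1.4 * r - g) / s if s > 0 else np.nan
    grvi = (r - g) / (r + g) if (r + g) > 0 else np.nan
    rgr = r / g if g > 0 else np.nan
    hsv = tuple(convert_color_space((r, g, b), "HSV"))
    yuv = tuple(convert_color_space((r, g, b), "YUV"))
    return ColorIndexSet(ExR=exr, GRVI=grvi, RGR=rgr, hsv=hsv, yuv=yuv)


def summarize_plant_color(frame: np.ndarray, mask: np.ndarray,
                          plant_id=None, timestamp=None) -> ColorSummary:
    """Mean and median RGB and L*a*b* of ``frame`` over ``mask`` pixels.

    ``frame`` is an (H, W, 3) 8-bit RGB array; ``mask`` a boolean/0-1 array of
    the same spatial shape. Pixels outside the mask never influence the
    summary. An empty mask gives ``n_pixels == 0`` and NaN color fields.
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask).astype(bool)
    if frame.shape[:2] != mask.shape:
        raise ValueError(f"frame {frame.shape[:2]} and mask {mask.shape} misaligned")
    pix = frame[mask].astype(float)
    if pix.size == 0:
        return ColorSummary(plant_id, timestamp, 0)
    lab = srgb_to_lab(pix)
    return ColorSummary(
        plant_id, timestamp, int(pix.shape[0]),
        mean_rgb=tuple(pix.mean(axis=0)),
        median_rgb=tuple(np.median(pix, axis=0)),
        mean_lab=tuple(lab.mean(axis=0)),
        median_lab=tuple(np.median(lab, axis=0)),
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack ColorSummary objects into the canonical CSV-ready table."""
    return pd.DataFrame([s.to_row() for s in summaries])
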