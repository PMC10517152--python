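"""Deterministic synthetic field scenes with full ground truth.

Every downstream stage is testable without the ~250 GB of real field
imagery: this module renders top-view plots of 48 rosette plants (4 blocks ×
12 genotypes) with four white corner marbles, per-frame camera jitter
(rotation + translation homographies), day/night brightness, variable
backgrounds (soil, sand, humus), optional snow speckle recorded in a
manual-record file, genotype-specific leaf-color trajectories driven by
lagged environmental signals through a known (threshold, window, lag)
specification, and a spectrophotometry leaf dataset with a known
color→anthocyanin mapping. Plants are drawn in L*a*b* and converted to sRGB,
so the color ground truth is exact by construction; truth masks are exactly
the rendered plant pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw
from skimage.transform import AffineTransform, ProjectiveTransform, warp

from . import colorimetry, env_model

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateParams",
    "SceneConfig",
    "GroundTruth",
    "FrameInfo",
    "SceneData",
    "generate_env_series",
    "generate_pigment_truth",
    "derive_polyploid_min",
    "render_scene_series",
    "generate_leaf_dataset",
    "default_genotype_params",
    "anthocyanin_to_lab",
    "lab_to_anthocyanin",
]

BACKGROUND_LAB = {
    # nominal CIELAB of the three background textures
    "soil": (42.0, 12.0, 22.0),
    "sand": (72.0, 8.0, 18.0),
    "humus": (26.0, 6.0, 10.0),
}

#: affine anthocyanin→Lab map (invertible, monotone in each coordinate)
ANTH_MAP = {"lo": 0.0, "hi": 0.06,
            "L": (48.0, -18.0), "a": (-38.0, 64.0), "b": (32.0, -26.0)}


def anthocyanin_to_lab(anth) -> np.ndarray:
    """Map relative anthocyanin to leaf L*a*b*: green → red/purple, darker."""
    t = (np.asarray(anth, dtype=float) - ANTH_MAP["lo"]) / (ANTH_MAP["hi"] - ANTH_MAP["lo"])
    L = ANTH_MAP["L"][0] + ANTH_MAP["L"][1] * t
    a = ANTH_MAP["a"][0] + ANTH_MAP["a"][1] * t
    b = ANTH_MAP["b"][0] + ANTH_MAP["b"][1] * t
    return np.stack([L, a, b], axis=-1)


def lab_to_anthocyanin(astar) -> np.ndarray:
    """Invert the a* coordinate of the anthocyanin→Lab map."""
    t = (np.asarray(astar, dtype=float) - ANTH_MAP["a"][0]) / ANTH_MAP["a"][1]
    return ANTH_MAP["lo"] + t * (ANTH_MAP["hi"] - ANTH_MAP["lo"])


# ---------------------------------------------------------------------------
# weather


@dataclass
class ClimateParams:
    """Seasonal climate model: sinusoidal temperature with a winter trough,
    AR(1) day-to-day weather, intermittent gamma-distributed precipitation."""

    t_mean: float = 8.0         # °C annual mean
    t_amp: float = 10.0         # °C seasonal amplitude
    t_trough_day: int = 110     # series day of the temperature minimum
    t_ar: float = 0.7           # AR(1) coefficient of temperature anomalies
    t_sd: float = 2.5           # °C anomaly innovation scale
    r_mean: float = 12.0        # radiation units (daily total)
    r_amp: float = 8.0
    r_sd: float = 2.0
    p_wet: float = 0.35         # probability of a wet day
    p_shape: float = 1.2        # gamma shape of wet-day amounts
    p_scale: float = 6.0        # gamma scale (mm)


def generate_env_series(seed: int, n_days: int,
                        climate_params: Optional[ClimateParams] = None,
                        start_date: str = "2017-10-01") -> pd.DataFrame:
    """Daily weather table: (date, temp_C, radiation, precip).

    Temperature is a seasonal sinusoid (trough at ``t_trough_day``) plus an
    autocorrelated anomaly; radiation follows the inverse season (low in
    winter) and is nonnegative, as is precipitation. Identical seeds give
    byte-identical tables.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    cp = climate_params or ClimateParams()
    rng = np.random.default_rng(seed)
    d = np.arange(n_days)
    season = np.cos(2 * np.pi * (d - cp.t_trough_day) / 365.0)
    temp = cp.t_mean - cp.t_amp * season
    anom = np.zeros(n_days)
    eps = rng.normal(0, 1, n_days)
    for i in range(1, n_days):
        anom[i] = cp.t_ar * anom[i - 1] + cp.t_sd * np.sqrt(max(0.0, 1 - cp.t_ar ** 2)) * eps[i]
    temp = temp + anom
    rad = np.maximum(0.0, cp.r_mean + cp.r_amp * season + rng.normal(0, cp.r_sd, n_days))
    wet = rng.random(n_days) < cp.p_wet
    amounts = rng.gamma(cp.p_shape, cp.p_scale, n_days) if cp.p_scale > 0 else np.zeros(n_days)
    precip = np.where(wet, amounts, 0.0)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "temp_C": temp,
                         "radiation": rad, "precip": precip})


# ---------------------------------------------------------------------------
# genotype trajectories


def default_genotype_params(n_genotypes: int = 12, seed: int = 7) -> pd.DataFrame:
    """Per-genotype response coefficients on standardized env features.

    Columns beta0 (baseline), beta_p, beta_c, beta_r (precip, coldness,
    radiation effects in response units per feature sd). Cold response
    dominates and varies across genotypes, emulating genotype-specific
    winter reddening.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "genotype": np.arange(n_genotypes),
        "beta0": 0.020 + 0.006 * rng.random(n_genotypes),
        "beta_p": rng.uniform(-0.0025, 0.0005, n_genotypes),
        "beta_c": np.linspace(0.004, 0.011, n_genotypes),
        "beta_r": rng.uniform(0.0005, 0.0030, n_genotypes),
    })


def generate_pigment_truth(env_series: pd.DataFrame,
                           genotype_params: pd.DataFrame,
                           spec: env_model.EnvFeatureSpec,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Per-genotype daily anthocyanin and L*a*b* truth trajectories.

    anthocyanin(d) = β₀ + β_p·f_p(d) + β_c·f_c(d) + β_r·f_r(d) + ε with the
    moving-total features of ``spec`` z-standardized over their valid days
    (so the β are effect sizes per feature sd). Days inside the spec's
    burn-in take the first valid value (they are excluded from model fits
    anyway). L*a*b* follows the invertible affine anthocyanin→color map.
    """
    n_days = len(env_series)
    if spec.burn_in >= n_days:
        raise ValueError(f"spec burn-in {spec.burn_in} exceeds n_days {n_days}")
    temp = env_series["temp_C"].to_numpy()
    rad = env_series["radiation"].to_numpy()
    prec = env_series["precip"].to_numpy()
    cold = env_model.daily_coldness(temp, spec.t_thr)
    feats = np.column_stack([
        env_model.moving_total(prec, spec.windows[0], spec.lags[0]),
        env_model.moving_total(cold, spec.windows[1], spec.lags[1]),
        env_model.moving_total(rad, spec.windows[2], spec.lags[2]),
    ])
    valid = np.all(np.isfinite(feats), axis=1)
    mu = feats[valid].mean(axis=0)
    sd = feats[valid].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (feats - mu) / sd
    first = int(np.argmax(valid))
    z[~valid] = z[first]
    rng = np.random.default_rng(seed)
    rows = []
    for _, gp in genotype_params.iterrows():
        anth = (gp["beta0"] + gp["beta_p"] * z[:, 0] + gp["beta_c"] * z[:, 1]
                + gp["beta_r"] * z[:, 2])
        if noise_sd > 0:
            anth = anth + rng.normal(0, noise_sd, n_days)
        lab = anthocyanin_to_lab(anth)
        rows.append(pd.DataFrame({
            "date": env_series["date"].to_numpy(),
            "genotype": int(gp["genotype"]),
            "anthocyanin": anth,
            "Lstar": lab[:, 0], "astar": lab[:, 1], "bstar": lab[:, 2],
        }))
    return pd.concat(rows, ignore_index=True)


def derive_polyploid_min(truth: pd.DataFrame, parent_a: int, parent_b: int,
                         new_genotype: int) -> pd.DataFrame:
    """Append a genotype whose anthocyanin is the per-day minimum of two parents.

    A simple transgressive-combination model for an allopolyploid candidate:
    its trajectory never exceeds either progenitor. Color follows the map.
    """
    a = truth[truth.genotype == parent_a].set_index("date")["anthocyanin"]
    b = truth[truth.genotype == parent_b].set_index("date")["anthocyanin"]
    anth = np.minimum(a, b)
    lab = anthocyanin_to_lab(anth.to_numpy())
    new = pd.DataFrame({"date": anth.index, "genotype": new_genotype,
                        "anthocyanin": anth.to_numpy(),
                        "Lstar": lab[:, 0], "astar": lab[:, 1], "bstar": lab[:, 2]})
    return pd.concat([truth, new], ignore_index=True)


# ---------------------------------------------------------------------------
# scene geometry and rendering


@dataclass
class SceneConfig:
    """Geometry, optics and noise of one synthetic plot camera."""

    seed: int = 0
    n_days: int = 20
    frames_per_day: int = 16
    image_size: tuple = (1152, 864)      # (width, height)
    n_blocks: int = 4
    n_genotypes: int = 12
    camera_id: str = "1"
    background_kind: str = "soil"
    marble_margin: float = 0.045         # fraction of min(image size)
    marble_radius: float = 9.0           # px
    max_translation_px: float = 8.0      # per-frame jitter
    max_rotation_deg: float = 1.5
    snow_day_prob: float = 0.0           # fraction of days with snow speckle
    snow_cover: float = 0.04             # fraction of frame under speckle
    brightness_range: tuple = (0.88, 1.12)
    diurnal_brightness: bool = True  # scale frames by solar elevation
    color_noise_sd: float = 1.5          # Lab units per plant pixel
    growth: tuple = (0.65, 1.0)          # rosette scale from first to last day
    start_date: str = "2017-10-01"
    marble_positions: Optional[tuple] = None  # four (x, y); default from margin
    frame_hours: Optional[tuple] = None       # capture hours; default from count

    def __post_init__(self):
        w, h = self.image_size
        if self.marble_positions is None:
            m = self.marble_margin * min(w, h)
            self.marble_positions = ((m, m), (w - m, m), (w - m, h - m), (m, h - m))
        pts = np.asarray(self.marble_positions, dtype=float)
        if pts.shape != (4, 2):
            raise ValueError("need exactly four marble positions")
        if np.any(pts[:, 0] <= 0) or np.any(pts[:, 0] >= w) \
                or np.any(pts[:, 1] <= 0) or np.any(pts[:, 1] >= h):
            raise ValueError("marble positions must be strictly inside the frame")
        if not _is_convex(pts):
            raise ValueError("marble positions must form a convex quadrilateral")
        if self.background_kind not in BACKGROUND_LAB:
            raise ValueError(f"unknown background {self.background_kind!r}")

    @property
    def n_plants(self) -> int:
        return self.n_blocks * self.n_genotypes

    def layout(self) -> pd.DataFrame:
        """True plant centers: blocks as rows, genotypes as columns."""
        w, h = self.image_size
        m = np.asarray(self.marble_positions, dtype=float)
        x0, x1 = m[:, 0].min(), m[:, 0].max()
        y0, y1 = m[:, 1].min(), m[:, 1].max()
        pad = 2.5 * self.marble_radius
        xs = np.linspace(x0 + pad, x1 - pad, self.n_genotypes + 1)
        ys = np.linspace(y0 + pad, y1 - pad, self.n_blocks + 1)
        cx = (xs[:-1] + xs[1:]) / 2
        cy = (ys[:-1] + ys[1:]) / 2
        rows = []
        pid = 0
        for bi, yy in enumerate(cy):
            for gi, xx in enumerate(cx):
                rows.append({"plant_id": pid, "x": xx, "y": yy,
                             "block": bi, "genotype": gi})
                pid += 1
        return pd.DataFrame(rows)

    @property
    def plant_spacing(self) -> float:
        lay = self.layout()
        dx = np.diff(np.unique(lay.x)).min() if self.n_genotypes > 1 else np.inf
        dy = np.diff(np.unique(lay.y)).min() if self.n_blocks > 1 else np.inf
        return float(min(dx, dy))

    @property
    def max_plant_radius(self) -> float:
        return 0.42 * self.plant_spacing


def _is_convex(pts: np.ndarray) -> bool:
    # order by angle about the centroid, then check consistent cross products
    c = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    p = pts[order]
    cross = []
    for i in range(4):
        a, b, cc = p[i], p[(i + 1) % 4], p[(i + 2) % 4]
        u, v = b - a, cc - b
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.asarray(cross)
    return bool(np.all(cross > 0) or np.all(cross < 0))


@dataclass
class FrameInfo:
    name: str
    camera_id: str
    timestamp: datetime
    day_index: int
    image: np.ndarray = field(repr=False)
    homography: np.ndarray = field(repr=False)  # reference → frame coords


@dataclass
class GroundTruth:
    centers: pd.DataFrame                 # plant_id, x, y, block, genotype
    pigment: pd.DataFrame                 # date, genotype, anthocyanin, L*a*b*
    env: pd.DataFrame
    truth_spec: env_model.EnvFeatureSpec
    genotype_params: pd.DataFrame
    label_masks: Optional[np.ndarray] = None   # (n_days, H, W) uint8, 0 = background
    homographies: Optional[dict] = None        # frame name → 3×3 (reference → frame)
    snow_days: Optional[list] = None
    plant_lab: Optional[pd.DataFrame] = None   # per plant per day nominal Lab


@dataclass
class SceneData:
    config: SceneConfig
    truth: GroundTruth
    frames: list  # of FrameInfo
    manual_records: pd.DataFrame


def _background_lab(cfg: SceneConfig, rng) -> np.ndarray:
    """Static Lab base texture of the plot background."""
    w, h = cfg.image_size
    lab0 = np.array(BACKGROUND_LAB[cfg.background_kind])
    blotch = np.stack([ndi.gaussian_filter(rng.normal(0, 1, (h, w)), 12) for _ in range(3)],
                      axis=-1)
    blotch *= np.array([12.0, 1.5, 2.2]) / (blotch.std(axis=(0, 1)) + 1e-9)
    return lab0[None, None, :] + blotch


def _day_background(base_lab: np.ndarray, rng) -> np.ndarray:
    """Daily background realization: the static texture plus a fresh
    moisture/lighting blotch layer and pixel grain (soil appearance is not
    identical from day to day)."""
    h, w, _ = base_lab.shape
    day_blotch = np.stack(
        [ndi.gaussian_filter(rng.normal(0, 1, (h, w)), 8) for _ in range(3)], axis=-1)
    day_blotch *= np.array([6.0, 1.8, 2.5]) / (day_blotch.std(axis=(0, 1)) + 1e-9)
    grain = rng.normal(0, 1.0, (h, w, 3))
    rgb = colorimetry.lab_to_srgb(base_lab + day_blotch + grain)
    return rgb.astype(np.uint8)


def _plant_shapes(cfg: SceneConfig, rng) -> list:
    """Per plant: list of leaf ellipses (dx, dy, r_len, r_wid, angle)."""
    shapes = []
    rmax = cfg.max_plant_radius
    for _ in range(cfg.n_plants):
        n_leaves = rng.integers(5, 13)
        # dense rosette core where the leaf bases overlap
        leaves = [(0.0, 0.0, 0.40 * rmax, 0.40 * rmax, 0.0)]
        # near-regular phyllotactic spread with angular jitter
        phase = rng.uniform(0, 2 * np.pi)
        angles = (phase + 2 * np.pi * (np.arange(n_leaves)
                                       + rng.uniform(-0.25, 0.25, n_leaves))
                  / n_leaves) % (2 * np.pi)
        for ang in angles:
            length = rng.uniform(0.45, 1.0) * rmax
            width = rng.uniform(0.22, 0.42) * length
            # leaf ellipse centered halfway along its petiole direction
            leaves.append((0.5 * length * np.cos(ang), 0.5 * length * np.sin(ang),
                           0.5 * length, width, ang))
        shapes.append(leaves)
    return shapes


def _day_label_mask(cfg: SceneConfig, layout: pd.DataFrame, shapes, scale: float
                    ) -> np.ndarray:
    w, h = cfg.image_size
    labels = np.zeros((h, w), dtype=np.uint8)
    for _, row in layout.iterrows():
        pid = int(row.plant_id)
        for (dx, dy, rl, rw, ang) in shapes[pid]:
            rr, cc = draw.ellipse(row.y + scale * dy, row.x + scale * dx,
                                  max(1.0, scale * rl), max(1.0, scale * rw),
                                  shape=(h, w), rotation=-ang)
            labels[rr, cc] = pid + 1
    return labels


def _jitter_homography(cfg: SceneConfig, rng) -> np.ndarray:
    w, h = cfg.image_size
    ang = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    tx, ty = rng.uniform(-cfg.max_translation_px, cfg.max_translation_px, 2)
    center = np.array([w / 2, h / 2])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(rotation=ang)
          + AffineTransform(translation=center + (tx, ty)))
    H = tf.params.copy()
    return H / H[2, 2]


def render_scene_series(cfg: SceneConfig,
                        env: Optional[pd.DataFrame] = None,
                        pigment_truth: Optional[pd.DataFrame] = None,
                        truth_spec: Optional[env_model.EnvFeatureSpec] = None,
                        genotype_params: Optional[pd.DataFrame] = None,
                        out_dir=None, jitter: bool = True) -> SceneData:
    """Render the frame series of one camera plus full ground truth.

    Builds (or reuses) the daily environment and per-genotype pigment truth,
    renders one reference scene per day (background + rosettes colored by
    the day's L*a*b* + marbles), and produces ``frames_per_day`` frames per
    day by applying a per-frame jitter homography, a diurnal × random
    brightness factor, and snow speckle on flagged days. With ``out_dir``
    set, frames, truth masks, homographies, truth tables and the
    manual-record file are written to disk.
    """
    rng = np.random.default_rng(cfg.seed)
    r_bg, r_shape, r_frame, r_truth, r_snow = rng.spawn(5)
    if env is None:
        env = generate_env_series(cfg.seed, cfg.n_days, start_date=cfg.start_date)
    if truth_spec is None:
        truth_spec = env_model.EnvFeatureSpec(4.0, (3, 5, 2), (1, 0, 4))
        if truth_spec.burn_in >= cfg.n_days:  # very short scenes
            truth_spec = env_model.EnvFeatureSpec(4.0, (1, 1, 1), (0, 0, 0))
    if genotype_params is None:
        genotype_params = default_genotype_params(cfg.n_genotypes)
    if pigment_truth is None:
        pigment_truth = generate_pigment_truth(env, genotype_params, truth_spec,
                                               seed=cfg.seed)
    layout = cfg.layout()
    base_lab = _background_lab(cfg, r_bg)
    shapes = _plant_shapes(cfg, r_shape)
    snow_days = sorted(
        int(d) for d in np.flatnonzero(r_snow.random(cfg.n_days) < cfg.snow_day_prob))

    dates = pd.to_datetime(env["date"]).dt.date.to_numpy()[:cfg.n_days]
    pig = pigment_truth.copy()
    pig["date"] = pd.to_datetime(pig["date"]).dt.date

    frames: list[FrameInfo] = []
    label_masks = np.zeros((cfg.n_days, cfg.image_size[1], cfg.image_size[0]),
                           dtype=np.uint8)
    homographies: dict[str, np.ndarray] = {}
    plant_lab_rows = []
    g0, g1 = cfg.growth
    if cfg.frame_hours is not None:
        hours = list(cfg.frame_hours)
    elif cfg.frames_per_day >= 8:
        hours = np.linspace(6, 20, cfg.frames_per_day)   # full diurnal sweep
    elif cfg.frames_per_day > 1:
        hours = np.linspace(10, 14, cfg.frames_per_day)  # midday-only short mode
    else:
        hours = [12.0]

    for di, day in enumerate(dates):
        scale = g0 + (g1 - g0) * (di / max(1, cfg.n_days - 1))
        labels = _day_label_mask(cfg, layout, shapes, scale)
        label_masks[di] = labels
        ref = _day_background(base_lab, r_bg).astype(float)
        day_pig = pig[pig.date == day].set_index("genotype")
        for _, row in layout.iterrows():
            pid = int(row.plant_id)
            lab_nom = day_pig.loc[int(row.genotype), ["Lstar", "astar", "bstar"]]
            lab_nom = lab_nom.to_numpy(dtype=float)
            sel = labels == pid + 1
            npix = int(sel.sum())
            if npix == 0:
                continue
            lab_pix = lab_nom[None, :] + r_truth.normal(0, cfg.color_noise_sd, (npix, 3))
            ref[sel] = colorimetry.lab_to_srgb(lab_pix)
            plant_lab_rows.append({"date": pd.Timestamp(day), "plant_id": pid,
                                   "genotype": int(row.genotype),
                                   "Lstar": lab_nom[0], "astar": lab_nom[1],
                                   "bstar": lab_nom[2],
                                   "anthocyanin": float(day_pig.loc[int(row.genotype),
                                                                    "anthocyanin"]),
                                   "area_px": npix})
        for (mx, my) in cfg.marble_positions:
            rr, cc = draw.disk((my, mx), cfg.marble_radius,
                               shape=ref.shape[:2])
            ref[rr, cc] = 252.0

        for hour in hours:
            hh = int(hour)
            mm = int(round((hour - hh) * 60))
            ts = datetime.combine(day, datetime.min.time()) + timedelta(hours=hh, minutes=mm)
            name = f"CAM{cfg.camera_id}_{ts:%Y%m%d_%H%M}.png"
            if jitter:
                H = _jitter_homography(cfg, r_frame)
                tf = ProjectiveTransform(H)
                img = warp(ref, tf.inverse, order=1, mode="constant", cval=0.0,
                           preserve_range=True)
            else:
                H = np.eye(3)
                img = ref.copy()
            solar = max(0.02, np.sin(np.pi * (hour - 6) / 14.0)) \
                if cfg.diurnal_brightness else 1.0
            bf = solar * r_frame.uniform(*cfg.brightness_range)
            img = img * min(1.0, bf)
            if di in snow_days:
                n_specks = int(cfg.snow_cover * img.shape[0] * img.shape[1] / 4)
                ys = r_snow.integers(0, img.shape[0], n_specks)
                xs = r_snow.integers(0, img.shape[1], n_specks)
                for yy, xx in zip(ys, xs):
                    rr, cc = draw.disk((yy, xx), 1.3, shape=img.shape[:2])
                    img[rr, cc] = 250.0
            frames.append(FrameInfo(name, cfg.camera_id, ts, di,
                                    np.clip(img, 0, 255).astype(np.uint8), H))
            homographies[name] = H

    records = pd.DataFrame(
        [{"date": pd.Timestamp(dates[d]), "camera": cfg.camera_id,
          "flag": "snow", "note": "synthetic snow speckle"} for d in snow_days],
        columns=["date", "camera", "flag", "note"])
    truth = GroundTruth(centers=layout, pigment=pigment_truth, env=env,
                        truth_spec=truth_spec, genotype_params=genotype_params,
                        label_masks=label_masks, homographies=homographies,
                        snow_days=snow_days,
                        plant_lab=pd.DataFrame(plant_lab_rows))
    data = SceneData(cfg, truth, frames, records)
    if out_dir is not None:
        _write_scene(data, Path(out_dir))
    return data


def _write_scene(data: SceneData, out_dir: Path) -> None:
    from PIL import Image

    frames_dir = out_dir / "frames"
    truth_dir = out_dir / "truth"
    frames_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    for fr in data.frames:
        Image.fromarray(fr.image).save(frames_dir / fr.name)
    for di in range(data.config.n_days):
        m = (data.truth.label_masks[di] > 0).astype(np.uint8) * 255
        Image.fromarray(m).save(truth_dir / f"mask_day{di:03d}.png")
    hom = pd.DataFrame(
        [{"frame": k, **{f"h{i}{j}": H[i, j] for i in range(3) for j in range(3)}}
         for k, H in data.truth.homographies.items()])
    hom.to_csv(truth_dir / "homographies.csv", index=False)
    data.truth.centers.to_csv(truth_dir / "centers.csv", index=False)
    data.truth.env.to_csv(truth_dir / "env.csv", index=False)
    data.truth.pigment.to_csv(truth_dir / "pigment_truth.csv", index=False)
    data.manual_records.to_csv(out_dir / "manual_records.csv", index=False)


# ---------------------------------------------------------------------------
# spectrophotometry leaf dataset


@dataclass
class LeafMapping:
    """Known color→anthocyanin-per-weight mapping g(L*, a*, b*) + noise."""

    c0: float = 0.004
    c_a: float = 0.030          # weight of the sigmoidal a* term
    a_mid: float = -8.0         # sigmoid midpoint on the a* axis
    a_scale: float = 9.0
    c_L: float = 0.010          # weight of the darkness term
    c_b: float = 0.004
    noise_sd: float = 0.002
    nonlinear: bool = True

    def g(self, L, a, b) -> np.ndarray:
        L, a, b = (np.asarray(v, dtype=float) for v in (L, a, b))
        if self.nonlinear:
            a_term = 1.0 / (1.0 + np.exp(-(a - self.a_mid) / self.a_scale))
        else:
            a_term = (a - self.a_mid) / (4.0 * self.a_scale) + 0.5
        return (self.c0 + self.c_a * a_term + self.c_L * (55.0 - L) / 55.0
                + self.c_b * (30.0 - b) / 30.0)


def generate_leaf_dataset(seed: int, n_samples: int = 451,
                          mapping: Optional[LeafMapping] = None) -> pd.DataFrame:
    """Leaf spectrophotometry table with a known color→pigment mapping.

    Each row carries leaf color (mean RGB and L*a*b*), absorbances, leaf
    area/weight, and the derived relative pigment contents; the absorbances
    are constructed so the spectrophotometry formula reproduces the mapped
    anthocyanin value exactly (plus configured noise).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    mp = mapping or LeafMapping()
    if mp.c_a == 0 and mp.c_L == 0 and mp.c_b == 0:
        raise ValueError("degenerate mapping: g is constant in color")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-38, 28, n_samples)
    L = 48.0 - 0.28 * (a + 38.0) + rng.normal(0, 3.0, n_samples)
    b = 32.0 - 0.40 * (a + 38.0) + rng.normal(0, 2.5, n_samples)
    anth = mp.g(L, a, b)
    if mp.noise_sd > 0:
        anth = anth + rng.normal(0, mp.noise_sd, n_samples)
    anth = np.maximum(anth, 1e-5)
    weight = rng.uniform(5.0, 15.0, n_samples)          # mg
    area = rng.uniform(30.0, 150.0, n_samples)          # mm²
    a650 = rng.uniform(0.02, 0.10, n_samples)
    a_main = anth * weight + a650                       # inverts the formula
    chl_pw = np.maximum(0.05, 1.5 - 15.0 * anth + rng.normal(0, 0.05, n_samples))
    a647 = chl_pw * weight / 32.36                      # with A664 = 2·A647
    a664 = 2.0 * a647
    rgb = colorimetry.lab_to_srgb(np.stack([L, a, b], axis=-1))
    dates = pd.to_datetime("2018-11-01") + pd.to_timedelta(
        rng.integers(0, 150, n_samples), unit="D")
    return pd.DataFrame({
        "genotype": rng.integers(0, 12, n_samples),
        "date": dates,
        "A_main": a_main, "A650": a650, "A664": a664, "A647": a647,
        "leaf_area_mm2": area, "leaf_weight_mg": weight,
        "anth_per_weight": (a_main - a650) / weight,
        "anth_per_area": (a_main - a650) / area,
        "chl_per_weight": (11.65 * a664 - 2.69 * a647
                           + 20.81 * a647 - 4.53 * a664) / weight,
        "mean_R": rgb[:, 0], "mean_G": rgb[:, 1], "mean_B": rgb[:, 2],
        "mean_Lstar": L, "mean_astar": a, "mean_bstar": b,
    })
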