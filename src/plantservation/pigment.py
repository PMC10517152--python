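"""Spectrophotometric pigment formulas and color→anthocyanin models.

Relative anthocyanin content of a leaf extract is (A535 or A530 − A650)
divided by leaf area (mm²) or fresh weight (mg); relative chlorophyll is
(chl a + chl b)/weight with chl a = 11.65·A664 − 2.69·A647 and
chl b = 20.81·A647 − 4.53·A664. The estimation models map leaf color
(one color space or index: L*a*b*, YUV, HSV, RGB, ExR, GRVI or RGR) to the
relative pigment content; linear, generalized-linear and random-forest
regressors are compared by leave-one-out cross-validation, and the winning
model (in practice a random forest on L*a*b* against anthocyanin per
weight) is applied to image-derived color time series. Genotype and date
are deliberately excluded from the design so estimation transfers across
genotypes and seasons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LinearRegression

logger = logging.getLogger(__name__)

__all__ = [
    "PigmentModel",
    "DegenerateFitError",
    "relative_anthocyanin",
    "relative_chlorophyll",
    "design_matrix",
    "fit_pigment_model",
    "loocv_compare_models",
    "estimate_anthocyanin",
    "FEATURE_SETS",
    "RESPONSES",
]

#: explanatory-variable sets; derived columns are computed from mean RGB
FEATURE_SETS = {
    "Lab": ["mean_Lstar", "mean_astar", "mean_bstar"],
    "YUV": ["mean_Y", "mean_U", "mean_V"],
    "HSV": ["mean_H", "mean_S", "mean_Vv"],
    "RGB": ["mean_R", "mean_G", "mean_B"],
    "ExR": ["ExR"],
    "GRVI": ["GRVI"],
    "RGR": ["RGR"],
}
RESPONSES = {"per_weight": "anth_per_weight", "per_area": "anth_per_area"}
_FORBIDDEN = {"genotype", "date", "sampling_date"}


class DegenerateFitError(RuntimeError):
    """Response is constant; no model can be fitted."""


def relative_anthocyanin(a_main, a650, denom, basis: str = "weight"):
    """(A_main − A650)/denom; denom is leaf weight (mg) or area (mm²).

    ``basis`` is documentation of the normalization used; values may be
    negative (measurement noise) and are retained.
    """
    if basis not in ("weight", "area"):
        raise ValueError("basis must be 'weight' or 'area'")
    denom = np.asarray(denom, dtype=float)
    if np.any(denom <= 0):
        raise ValueError(f"leaf {basis} must be positive")
    out = (np.asarray(a_main, dtype=float) - np.asarray(a650, dtype=float)) / denom
    if np.any(np.asarray(out) < 0):
        logger.info("negative relative anthocyanin values retained")
    return out


def relative_chlorophyll(a664, a647, weight_mg):
    """(chl a + chl b)/weight with the dimethylformamide-extract coefficients."""
    weight = np.asarray(weight_mg, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("leaf weight must be positive")
    a664 = np.asarray(a664, dtype=float)
    a647 = np.asarray(a647, dtype=float)
    chl_a = 11.65 * a664 - 2.69 * a647
    chl_b = 20.81 * a647 - 4.53 * a664
    return (chl_a + chl_b) / weight


# ---------------------------------------------------------------------------
# design construction


def design_matrix(samples: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Feature columns for ``feature_set``, derived from mean colors as needed.

    Lab features come straight from the color summary; YUV/HSV and the
    indices are computed from the mean R, G, B. Genotype/date columns are
    never part of any design.
    """
    from . import colorimetry

    if feature_set not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {feature_set!r}")
    cols = FEATURE_SETS[feature_set]
    if any(c.lower() in _FORBIDDEN for c in cols):  # defensive; never true
        raise ValueError("genotype/date may not enter the design")
    df = samples.copy()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        rgb = df[["mean_R", "mean_G", "mean_B"]].to_numpy(dtype=float)
        safe = np.nan_to_num(rgb)
        if feature_set == "YUV":
            yuv = colorimetry.convert_color_space(safe, "YUV")
            df["mean_Y"], df["mean_U"], df["mean_V"] = yuv.T
        elif feature_set == "HSV":
            hsv = colorimetry.convert_color_space(safe, "HSV")
            df["mean_H"], df["mean_S"], df["mean_Vv"] = hsv.T
        else:
            r, g, b = rgb.T
            s = r + g + b
            with np.errstate(divide="ignore", invalid="ignore"):
                df["ExR"] = np.where(s > 0, (1.4 * r - g) / s, np.nan)
                df["GRVI"] = np.where(r + g > 0, (r - g) / (r + g), np.nan)
                df["RGR"] = np.where(g > 0, r / g, np.nan)
        bad = ~np.all(np.isfinite(rgb), axis=1)
        if bad.any():
            for c in cols:
                df.loc[bad, c] = np.nan
    return df[cols]


@dataclass
class PigmentModel:
    """One fitted color→pigment regressor plus its metadata."""

    model_type: str            # linear | glm | rf
    feature_set: str
    response: str              # per_weight | per_area
    estimator: object = field(repr=False)
    feature_names: list = field(default_factory=list)
    importance: Optional[dict] = None  # percent shares (rf only)
    seed: int = 0
    calibrator: object = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred = _predict_estimator(self.model_type, self.estimator, X)
        if self.calibrator is not None:
            pred = self.calibrator.predict(pred)
        return pred


def _fit_estimator(model_type: str, X: np.ndarray, y: np.ndarray, seed: int,
                   n_estimators: int = 500):
    if model_type == "linear":
        return LinearRegression().fit(X, y)
    if model_type == "glm":
        import statsmodels.api as sm

        # Gaussian family with log link: positive, right-skewed pigment scale
        offset = max(0.0, -float(y.min())) + 1e-6  # keep initial mu positive
        exog = sm.add_constant(X, has_constant="add")
        model = sm.GLM(y + offset, exog,
                       family=sm.families.Gaussian(sm.families.links.Log()))
        res = model.fit(maxiter=200)
        return ("glm", res, offset)
    if model_type == "rf":
        p = X.shape[1]
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max(1, p // 3),
            random_state=seed,
        )
        return rf.fit(X, y)
    raise ValueError(f"unknown model type {model_type!r}")


def _predict_estimator(model_type: str, est, X: np.ndarray) -> np.ndarray:
    if model_type == "glm":
        import statsmodels.api as sm

        _, res, offset = est
        exog = sm.add_constant(np.asarray(X), has_constant="add")
        return np.asarray(res.predict(exog)) - offset
    return est.predict(X)


def fit_pigment_model(samples: pd.DataFrame, model_type: str = "rf",
                      feature_set: str = "Lab", response: str = "per_weight",
                      seed: int = 0, n_estimators: int = 500,
                      calibrate: bool = False) -> PigmentModel:
    """Fit one color→anthocyanin model on the spectrophotometry samples.

    ``samples`` needs the response column and the color summary columns.
    Random-forest importance shares (impurity-based) are normalized to
    percent. ``calibrate`` adds a monotone (isotonic) recalibration of the
    predictions against the observed response — useful for the per-area
    response whose relation to the raw prediction is nonlinear.
    """
    if len(samples) < 20:
        raise ValueError("need at least 20 samples")
    ycol = RESPONSES[response]
    X_df = design_matrix(samples, feature_set)
    keep = X_df.notna().all(axis=1) & samples[ycol].notna()
    X = X_df[keep].to_numpy(dtype=float)
    y = samples.loc[keep, ycol].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant response")
    est = _fit_estimator(model_type, X, y, seed, n_estimators)
    importance = None
    if model_type == "rf":
        imp = est.feature_importances_
        shares = 100.0 * imp / imp.sum()
        importance = dict(zip(X_df.columns, shares))
    model = PigmentModel(model_type, feature_set, response, est,
                         list(X_df.columns), importance, seed)
    if calibrate:
        model.calibrator = IsotonicRegression(out_of_bounds="clip").fit(
            _predict_estimator(model_type, est, X), y)
    return model


def loocv_compare_models(samples: pd.DataFrame,
                         model_types: Sequence[str] = ("linear", "glm", "rf"),
                         feature_sets: Sequence[str] = tuple(FEATURE_SETS),
                         responses: Sequence[str] = tuple(RESPONSES),
                         seed: int = 0, n_estimators: int = 500,
                         aggregate: str = "pooled") -> pd.DataFrame:
    """Leave-one-out comparison over the model × feature × response grid.

    Each configuration runs n single-holdout fits (one per sample).
    ``aggregate='pooled'`` reports RMSE over the pooled holdout errors
    (default); ``'per_trial'`` averages the per-trial root squared errors,
    i.e. the mean absolute error — for single holdouts the two readings of
    "average RMSE over trials" differ only in this way. Also reports LOOCV
    R² and the Pearson r between held-out predictions and observations, and
    flags the best (lowest-RMSE) configuration per response. Configurations
    that fail to fit are recorded with NaN metrics, not raised.
    """
    rows = []
    for response in responses:
        ycol = RESPONSES[response]
        for model_type, feature_set in itertools.product(model_types, feature_sets):
            try:
                rmse, mae, r2, r = _loocv_one(samples, model_type, feature_set,
                                              ycol, seed, n_estimators)
                err = rmse if aggregate == "pooled" else mae
            except Exception as exc:  # record, don't abort the grid
                logger.warning("LOOCV failed for %s/%s/%s: %s",
                               model_type, feature_set, response, exc)
                err = rmse = r2 = r = np.nan
            rows.append({"model": model_type, "features": feature_set,
                         "response": response, "loocv_rmse": err,
                         "loocv_r2": r2, "pearson_r": r})
    out = pd.DataFrame(rows)
    out["best"] = False
    for response in responses:
        sub = out[out.response == response]
        if sub.loocv_rmse.notna().any():
            out.loc[sub.loocv_rmse.idxmin(), "best"] = True
    return out


def _loocv_one(samples, model_type, feature_set, ycol, seed, n_estimators):
    X_df = design_matrix(samples, feature_set)
    keep = X_df.notna().all(axis=1) & samples[ycol].notna()
    X = X_df[keep].to_numpy(dtype=float)
    y = samples.loc[keep, ycol].to_numpy(dtype=float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        m = np.ones(n, dtype=bool)
        m[i] = False
        est = _fit_estimator(model_type, X[m], y[m], seed, n_estimators)
        preds[i] = _predict_estimator(model_type, est, X[i:i + 1])[0]
    err = preds - y
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(err @ err) / tss if tss > 0 else np.nan
    r = float(np.corrcoef(preds, y)[0, 1]) if np.ptp(preds) > 0 else np.nan
    return rmse, mae, r2, r


def estimate_anthocyanin(model: PigmentModel, color_series: pd.DataFrame) -> pd.Series:
    """Apply a fitted model to a color table; missing features give NaN rows."""
    X_df = color_series.copy()
    missing_cols = [c for c in model.feature_names if c not in X_df.columns]
    if missing_cols:
        X_df = pd.concat([X_df, design_matrix(color_series, model.feature_set)],
                         axis=1)
        still = [c for c in model.feature_names if c not in X_df.columns]
        if still:
            raise KeyError(f"color series lacks features {still}")
    X_df = X_df.loc[:, ~X_df.columns.duplicated()]
    X = X_df[model.feature_names].to_numpy(dtype=float)
    out = np.full(len(X), np.nan)
    ok = np.all(np.isfinite(X), axis=1)
    if ok.any():
        out[ok] = model.predict(X[ok])
    return pd.Series(out, index=color_series.index, name="anthocyanin_est")
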