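"""Environmental lag/window regression for leaf anthocyanin.

Anthocyanin accumulation integrates environmental signals over a *reference
window* of w days that precedes the observation day by a *lag* of l days.
Three daily drivers are used: coldness (degree-days below a threshold
temperature), radiation, and precipitation. For each candidate specification
(T_thr ∈ {1, 4, 7, 10, 13} °C, windows 1–14 d, lags 0–14 d per factor —
5 × 14³ × 15³ = 46,305,000 combinations on the full grid) an ordinary
least-squares model of standardized features is fitted and the specification
with the smallest AIC wins. Coefficient significance comes from a
case-resampling BCa bootstrap, and each factor's relative importance from the
LMG decomposition of R² (average sequential contribution over all predictor
orderings).

The exhaustive grid search is implemented with per-(factor, window, lag)
feature precomputation and batched normal-equation solves assembled from
Gram tables, so restricted grids fit interactively and the full grid streams
in chunks without materializing 46 M design matrices.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnvFeatureSpec",
    "EnvModelFit",
    "GridSpec",
    "DegenerateBootstrapError",
    "fill_gaps",
    "daily_coldness",
    "moving_total",
    "enumerate_grid",
    "fit_one",
    "grid_select",
    "bca_significance",
    "lmg_importance",
]

FACTORS = ("precip", "coldness", "radiation")  # canonical factor order

#: the grid dimensions used in the published analysis
FULL_THRESHOLDS = (1, 4, 7, 10, 13)
FULL_WINDOWS = tuple(range(1, 15))
FULL_LAGS = tuple(range(0, 15))


class DegenerateBootstrapError(RuntimeError):
    """All bootstrap replicates identical; no interval can be formed."""


@dataclass(frozen=True, order=True)
class EnvFeatureSpec:
    """One (threshold, windows, lags) feature specification.

    ``windows`` and ``lags`` are (precip, coldness, radiation) triples in
    days; ``t_thr`` applies to the coldness feature only.
    """

    t_thr: float
    windows: tuple
    lags: tuple

    def __post_init__(self):
        if len(self.windows) != 3 or len(self.lags) != 3:
            raise ValueError("windows and lags must be (precip, coldness, radiation) triples")
        if min(self.windows) < 1 or min(self.lags) < 0:
            raise ValueError("require window >= 1 and lag >= 0")

    @property
    def burn_in(self) -> int:
        return max(self.windows) + max(self.lags)


@dataclass
class EnvModelFit:
    """Fitted OLS on standardized lag/window features.

    ``coef`` follows the canonical factor order (precip, coldness,
    radiation); ``ci`` / ``significant`` / ``importance`` are filled by
    :func:`bca_significance` and :func:`lmg_importance`.
    """

    spec: EnvFeatureSpec
    coef: np.ndarray          # standardized slopes, shape (3,)
    intercept: float
    aic: float
    r2: float
    n: int
    X: np.ndarray = field(repr=False, default=None)  # standardized design rows
    y: np.ndarray = field(repr=False, default=None)
    X_raw: np.ndarray = field(repr=False, default=None)
    ci: Optional[np.ndarray] = None           # (3, 2) BCa bounds
    significant: Optional[np.ndarray] = None  # (3,) bool
    importance: Optional[np.ndarray] = None   # (3,) shares of R²

    def summary_row(self) -> dict:
        row = {
            "t_thr": self.spec.t_thr,
            **{f"w_{f[0]}": w for f, w in zip(FACTORS, self.spec.windows)},
            **{f"l_{f[0]}": l for f, l in zip(FACTORS, self.spec.lags)},
            "aic": self.aic, "r2": self.r2, "n": self.n,
            "intercept": self.intercept,
            **{f"beta_{f[0]}": c for f, c in zip(FACTORS, self.coef)},
        }
        if self.ci is not None:
            for f, (lo, hi), sig in zip(FACTORS, self.ci, self.significant):
                row[f"ci_lo_{f[0]}"], row[f"ci_hi_{f[0]}"] = lo, hi
                row[f"sig_{f[0]}"] = bool(sig)
        if self.importance is not None:
            for f, s in zip(FACTORS, self.importance):
                row[f"lmg_{f[0]}"] = s
        return row


# ---------------------------------------------------------------------------
# daily features


def fill_gaps(env_raw: pd.DataFrame) -> pd.DataFrame:
    """Fill missing days/values in a daily weather table.

    ``env_raw`` must have a ``date`` column (or DatetimeIndex) and numeric
    columns. The date index is made contiguous; interior gaps are linearly
    interpolated over the date index, leading/trailing gaps take the nearest
    value. Boolean ``<col>_filled`` flag columns record what was imputed.
    """
    df = env_raw.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
        df = df.set_index("date")
    df = df.sort_index()
    full_idx = pd.date_range(df.index.min(), df.index.max(), freq="D")
    df = df.reindex(full_idx)
    df.index.name = "date"
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.notna().sum() < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        filled = vals.interpolate(method="time", limit_direction="both")
        out[col] = filled
        out[f"{col}_filled"] = vals.isna()
    return out


def daily_coldness(temp_series, t_thr: float):
    """Degree-days below threshold: max(0, T_thr − T_mean(d)) per day."""
    t = np.asarray(temp_series, dtype=float) if not isinstance(temp_series, pd.Series) else temp_series
    cold = np.maximum(0.0, t_thr - t)
    return cold


def moving_total(series, window: int, lag: int) -> np.ndarray:
    """Lagged moving total: feature(d) = Σ_{i=d−l−w+1}^{d−l} series(i).

    Days whose window would reach before the start of the series are NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    x = np.asarray(series, dtype=float)
    n = x.size
    out = np.full(n, np.nan)
    c = np.concatenate([[0.0], np.cumsum(x)])
    d = np.arange(n)
    hi = d - lag          # inclusive upper summand index
    lo = hi - window + 1  # inclusive lower summand index
    valid = lo >= 0
    out[valid] = c[hi[valid] + 1] - c[lo[valid]]
    return out


# ---------------------------------------------------------------------------
# grid enumeration


@dataclass(frozen=True)
class GridSpec:
    """A Cartesian grid of EnvFeatureSpec; iterable in canonical order.

    Canonical order is threshold-major, then w_p, w_c, w_r, l_p, l_c, l_r
    (precip/coldness/radiation windows, then lags), each ascending as given.
    """

    thresholds: tuple
    windows: tuple
    lags: tuple

    def __post_init__(self):
        if not (self.thresholds and self.windows and self.lags):
            raise ValueError("grid ranges must be nonempty")

    @property
    def count(self) -> int:
        return len(self.thresholds) * len(self.windows) ** 3 * len(self.lags) ** 3

    @property
    def burn_in(self) -> int:
        return max(self.windows) + max(self.lags)

    def __iter__(self) -> Iterator[EnvFeatureSpec]:
        for thr, wp, wc, wr, lp, lc, lr in itertools.product(
            self.thresholds, self.windows, self.windows, self.windows,
            self.lags, self.lags, self.lags,
        ):
            yield EnvFeatureSpec(thr, (wp, wc, wr), (lp, lc, lr))

    def spec_at(self, flat_index: int) -> EnvFeatureSpec:
        dims = (len(self.thresholds),) + (len(self.windows),) * 3 + (len(self.lags),) * 3
        it, iwp, iwc, iwr, ilp, ilc, ilr = np.unravel_index(flat_index, dims)
        w, l = self.windows, self.lags
        return EnvFeatureSpec(self.thresholds[it], (w[iwp], w[iwc], w[iwr]),
                              (l[ilp], l[ilc], l[ilr]))


def enumerate_grid(thresholds=FULL_THRESHOLDS, window_range=FULL_WINDOWS,
                   lag_range=FULL_LAGS) -> GridSpec:
    """Grid of all (threshold, windows, lags) specs; ``.count`` gives |thr|·|w|³·|l|³."""
    return GridSpec(tuple(thresholds), tuple(window_range), tuple(lag_range))


# ---------------------------------------------------------------------------
# single-spec fit


def _env_arrays(env: pd.DataFrame):
    cols = {c.lower(): c for c in env.columns}
    def pick(*names):
        for nm in names:
            if nm in cols:
                return env[cols[nm]].to_numpy(dtype=float)
        raise KeyError(f"env table lacks any of {names}")
    temp = pick("temp_c", "temperature", "temp")
    rad = pick("radiation", "rad")
    prec = pick("precip", "precipitation", "prec")
    return temp, rad, prec


def _spec_features(env: pd.DataFrame, spec: EnvFeatureSpec) -> np.ndarray:
    temp, rad, prec = _env_arrays(env)
    cold = daily_coldness(temp, spec.t_thr)
    cols = [
        moving_total(prec, spec.windows[0], spec.lags[0]),
        moving_total(cold, spec.windows[1], spec.lags[1]),
        moving_total(rad, spec.windows[2], spec.lags[2]),
    ]
    return np.column_stack(cols)


def fit_one(response, env: pd.DataFrame, spec: EnvFeatureSpec,
            burn_in: Optional[int] = None) -> EnvModelFit:
    """OLS of the response on z-standardized lag/window features.

    ``response`` is aligned positionally with the env table's days (a pandas
    Series with the same date index, or an array of the same length).
    Rows inside the burn-in (default the spec's own max window + max lag),
    rows with missing response, and rows with missing features are dropped.
    AIC = n·ln(RSS/n) + 2(k+1) with k = 4 (three slopes + intercept).
    """
    y_all = np.asarray(response, dtype=float)
    X_all = _spec_features(env, spec)
    if y_all.shape[0] != X_all.shape[0]:
        raise ValueError("response and env series length mismatch")
    bi = spec.burn_in if burn_in is None else burn_in
    keep = np.isfinite(y_all) & np.all(np.isfinite(X_all), axis=1)
    keep[:bi] = False
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"too few usable rows after burn-in: {n}")
    y = y_all[keep]
    X_raw = X_all[keep]
    sd = X_raw.std(axis=0)
    if np.any(sd == 0):
        dead = [FACTORS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance feature(s): {dead}")
    X = (X_raw - X_raw.mean(axis=0)) / sd
    beta, rss, r2 = _ols_centered(X, y)
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * (4 + 1)
    return EnvModelFit(spec=spec, coef=beta, intercept=float(y.mean()),
                       aic=aic, r2=r2, n=n, X=X, y=y, X_raw=X_raw)


def _ols_centered(X: np.ndarray, y: np.ndarray):
    """Slopes of y on mean-centered X plus implicit intercept; (beta, RSS, R²)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    rss = float(resid @ resid)
    tss = float(yc @ yc)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, rss, r2


# ---------------------------------------------------------------------------
# exhaustive grid selection (Gram-table batched engine)


def grid_select(response, env: pd.DataFrame, grid: GridSpec,
                chunk_size: int = 200_000) -> EnvModelFit:
    """Exhaustive AIC model selection over ``grid``; returns the winning fit.

    All fits share the same rows: the grid-wide burn-in (max window + max
    lag over the grid) plus missing-response days are dropped once, so AIC
    values are comparable. Features are precomputed per (factor, window,
    lag[, threshold]) and every spec's normal equations are assembled from
    Gram tables and solved in batches. Ties go to the first spec in
    canonical order. Specs with a zero-variance feature are skipped.
    """
    y_all = np.asarray(response, dtype=float)
    temp, rad, prec = _env_arrays(env)
    if y_all.shape[0] != temp.shape[0]:
        raise ValueError("response and env series length mismatch")
    bi = grid.burn_in
    keep = np.isfinite(y_all)
    keep[:bi] = False
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"too few usable rows after burn-in: {n}")
    y = y_all[keep]

    wins, lags, thrs = grid.windows, grid.lags, grid.thresholds
    nw, nl, nt = len(wins), len(lags), len(thrs)

    def bank(series) -> np.ndarray:
        """columns over (w, l) pairs in (w-major, l-minor) order, fit rows only"""
        cols = np.empty((n, nw * nl))
        for iw, w in enumerate(wins):
            for il, l in enumerate(lags):
                cols[:, iw * nl + il] = moving_total(series, w, l)[keep]
        if not np.all(np.isfinite(cols)):
            raise AssertionError("burn-in must make every feature finite")
        return cols

    P = bank(prec)
    R = bank(rad)
    C = np.concatenate([bank(daily_coldness(temp, t)) for t in thrs], axis=1)
    # column index of spec (it, iw, il) in C is (it*nw + iw)*nl + il

    tabs = _gram_tables(P, C, R, y)
    my, syy = y.mean(), float(((y - y.mean()) ** 2).sum())

    dims = (nt, nw, nw, nw, nl, nl, nl)  # thr, w_p, w_c, w_r, l_p, l_c, l_r
    total = int(np.prod(dims))
    assert total == grid.count
    best_aic, best_flat = np.inf, -1
    n_skipped = 0
    for start in range(0, total, chunk_size):
        flat = np.arange(start, min(start + chunk_size, total))
        it, iwp, iwc, iwr, ilp, ilc, ilr = np.unravel_index(flat, dims)
        ip = iwp * nl + ilp
        ic = (it * nw + iwc) * nl + ilc
        ir = iwr * nl + ilr
        rss, ok = _batched_rss(tabs, ip, ic, ir, n, my, syy)
        n_skipped += int((~ok).sum())
        aic = np.where(ok, n * np.log(np.maximum(rss, 1e-300) / n) + 2 * 5, np.inf)
        j = int(np.argmin(aic))
        if aic[j] < best_aic:
            best_aic, best_flat = float(aic[j]), int(flat[j])
    if best_flat < 0:
        raise ValueError("every spec in the grid was skipped")
    if n_skipped:
        logger.info("grid_select: skipped %d degenerate specs", n_skipped)
    best_spec = grid.spec_at(best_flat)
    fit = fit_one(response, env, best_spec, burn_in=bi)
    # engine RSS and the refit RSS agree up to cancellation noise (the
    # engine assembles RSS from Gram tables, which loses precision only
    # when the fit is essentially exact)
    rss_fit = (1.0 - fit.r2) * syy
    rss_engine = np.exp((best_aic - 2 * 5) / n) * n
    if abs(rss_fit - rss_engine) > 1e-6 * syy + 1e-12:
        logger.debug("grid_select RSS cross-check: engine %.3e vs refit %.3e",
                     rss_engine, rss_fit)
    return fit


def _gram_tables(P, C, R, y):
    """Sums, sums of squares, x·y and cross-bank dot products for the engine."""
    t = {}
    for name, M in (("p", P), ("c", C), ("r", R)):
        t[f"sum_{name}"] = M.sum(axis=0)
        t[f"ss_{name}"] = (M * M).sum(axis=0)
        t[f"xy_{name}"] = M.T @ y
    t["pc"] = P.T @ C
    t["pr"] = P.T @ R
    t["cr"] = C.T @ R
    return t


def _batched_rss(t, ip, ic, ir, n, my, syy):
    """RSS of standardized-feature OLS for each (ip, ic, ir) column triple."""
    m = len(ip)
    sums = np.stack([t["sum_p"][ip], t["sum_c"][ic], t["sum_r"][ir]], axis=1) / n
    ss = np.stack([t["ss_p"][ip], t["ss_c"][ic], t["ss_r"][ir]], axis=1)
    var = ss / n - sums ** 2
    ok = np.all(var > 1e-12, axis=1)
    var = np.where(var > 1e-12, var, 1.0)
    # centered covariance matrix entries (times n), then correlation scaling
    S = np.empty((m, 3, 3))
    S[:, 0, 0], S[:, 1, 1], S[:, 2, 2] = (ss - n * sums ** 2).T
    S[:, 0, 1] = S[:, 1, 0] = t["pc"][ip, ic] - n * sums[:, 0] * sums[:, 1]
    S[:, 0, 2] = S[:, 2, 0] = t["pr"][ip, ir] - n * sums[:, 0] * sums[:, 2]
    S[:, 1, 2] = S[:, 2, 1] = t["cr"][ic, ir] - n * sums[:, 1] * sums[:, 2]
    sxy = np.stack([t["xy_p"][ip], t["xy_c"][ic], t["xy_r"][ir]], axis=1)
    sxy = sxy - n * sums * my
    sd = np.sqrt(var)
    S = S / (sd[:, :, None] * sd[:, None, :])
    sxy = sxy / sd
    # guard singular systems
    try:
        beta = np.linalg.solve(S, sxy[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.empty_like(sxy)
        for i in range(m):
            try:
                beta[i] = np.linalg.solve(S[i], sxy[i])
            except np.linalg.LinAlgError:
                ok[i] = False
                beta[i] = 0.0
    rss = syy - np.einsum("ij,ij->i", beta, sxy)
    rss = np.maximum(rss, 0.0)
    return rss, ok


# ---------------------------------------------------------------------------
# inference on the selected model


def _batched_std_ols(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Standardize-within-sample OLS slopes for stacked samples.

    Xb: (B, n, 3) raw features, yb: (B, n). Returns (B, 3) slopes on
    z-standardized features (the full estimator re-applied per sample).
    """
    mean = Xb.mean(axis=1, keepdims=True)
    sd = Xb.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xb - mean) / sd
    Zc = Z - Z.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    S = np.einsum("bni,bnj->bij", Zc, Zc)
    sxy = np.einsum("bni,bn->bi", Zc, yc)
    S = S + 1e-12 * np.eye(3)
    return np.linalg.solve(S, sxy[..., None])[..., 0]


def bca_significance(fit: EnvModelFit, n_boot: int = 2000, seed: int = 0,
                     alpha: float = 0.05) -> EnvModelFit:
    """BCa bootstrap 95% CIs for the standardized slopes; flags significance.

    Case resampling of the fitted rows; the full estimator (standardize,
    then OLS) is re-applied to each resample. The bias correction ẑ₀ comes
    from the bootstrap CDF at the point estimate and the acceleration â from
    jackknife skewness. A coefficient is significant iff its interval
    excludes 0. Fills ``fit.ci`` and ``fit.significant`` in place (and
    returns the fit).
    """
    if fit.X_raw is None or fit.y is None:
        raise ValueError("fit does not retain row data")
    rng = np.random.default_rng(seed)
    n = fit.n
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _batched_std_ols(fit.X_raw[idx], fit.y[idx])
    if np.allclose(boot.std(axis=0), 0):
        raise DegenerateBootstrapError("all bootstrap replicates identical")
    # jackknife for acceleration
    mask = ~np.eye(n, dtype=bool)
    jk_idx = np.arange(n)[None, :].repeat(n, axis=0)[mask].reshape(n, n - 1)
    jack = _batched_std_ols(fit.X_raw[jk_idx], fit.y[jk_idx])
    ci = np.empty((3, 2))
    for k in range(3):
        ci[k] = _bca_interval(boot[:, k], fit.coef[k], jack[:, k], alpha)
    fit.ci = ci
    fit.significant = ~((ci[:, 0] <= 0) & (0 <= ci[:, 1]))
    return fit


def _bca_interval(boot: np.ndarray, theta_hat: float, jack: np.ndarray,
                  alpha: float) -> tuple:
    B = boot.size
    prop = np.clip(np.mean(boot < theta_hat), 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(prop)
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        out.append(np.quantile(boot, np.clip(stats.norm.cdf(adj), 0, 1)))
    return tuple(out)


def lmg_importance(fit: EnvModelFit) -> np.ndarray:
    """LMG shares of R² per factor (precip, coldness, radiation).

    The sequential R² increment of each predictor is averaged over all 3!
    orderings (exact enumeration). Shares sum to the model's total R².
    Fills ``fit.importance`` and returns it.
    """
    if fit.X is None or fit.y is None:
        raise ValueError("fit does not retain row data")
    X, y = fit.X, fit.y
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant response")

    r2_cache: dict = {(): 0.0}

    def r2_of(subset: tuple) -> float:
        if subset not in r2_cache:
            _, rss, r2 = _ols_centered(X[:, list(subset)], y)
            r2_cache[subset] = r2
        return r2_cache[subset]

    shares = np.zeros(3)
    perms = list(itertools.permutations(range(3)))
    for perm in perms:
        seen: list = []
        for p in perm:
            before = r2_of(tuple(sorted(seen)))
            seen.append(p)
            after = r2_of(tuple(sorted(seen)))
            shares[p] += after - before
    shares /= len(perms)
    fit.importance = shares
    return shares
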