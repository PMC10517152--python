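"""Daily aggregation, smoothing, and anomaly removal for trait time series.

Per-frame plant traits (area, L*, a*, b*, estimated anthocyanin) are averaged
within (plant, day) and then across plants of a genotype; plots use 5-day
centered moving averages. Anomalous periods are removed by three criteria:
(1) manual incident records (snow, storms, ...), (2) a reviewable report of
plants whose a* series deviates strongly from the genotype median (the
human-inspection criterion — report, not automatic removal), and (3) a
block-wise nearest-neighbor imputation screen: the season is cut into 10
blocks, each block in turn is masked and imputed from the remainder, and
days whose |imputed − original| difference has z > 5 are excluded. Every
exclusion is written to an auditable ledger.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_daily",
    "moving_average",
    "apply_manual_exclusions",
    "flag_deviating_plants",
    "block_zscore_filter",
]

LEDGER_COLUMNS = ["scope", "date_start", "date_end", "criterion", "note"]


def aggregate_daily(per_frame: pd.DataFrame, value_col: str,
                    by: str = "plant_id") -> pd.DataFrame:
    """Mean of ``value_col`` within (key, calendar day).

    ``per_frame`` needs a ``timestamp`` (or ``date``) column and the key
    column. Multiple frames of a day are averaged; genotype-level series are
    obtained by passing ``by='genotype'`` on plant-day aggregates (mean over
    plants of the genotype).
    """
    df = per_frame.copy()
    ts = df["timestamp"] if "timestamp" in df.columns else df["date"]
    df["date"] = pd.to_datetime(ts).dt.normalize()
    out = df.groupby([by, "date"], as_index=False)[value_col].mean()
    return out


def moving_average(series: pd.Series, window: int = 5) -> pd.Series:
    """Centered moving average over available (non-missing) days.

    ``window`` must be odd. Days whose whole window is missing stay missing;
    otherwise the mean of the available values in the window is used.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    return series.rolling(window, center=True, min_periods=1).mean()


def _empty_ledger() -> pd.DataFrame:
    return pd.DataFrame(columns=LEDGER_COLUMNS)


def apply_manual_exclusions(series: pd.Series, records: pd.DataFrame,
                            scope: Optional[str] = None):
    """Mask days covered by manual incident records; return (series, ledger).

    ``records`` rows carry ``date`` (or ``date_start``/``date_end``),
    optionally ``camera`` (the scope), ``flag`` and ``note``. When ``scope``
    is given, only rows whose camera matches it (or is empty/'all') apply.
    The series index must be datetime-like. Exclusion only removes values;
    surviving days are untouched.
    """
    out = series.copy()
    ledger_rows = []
    if records is None or len(records) == 0:
        return out, _empty_ledger()
    recs = records.copy()
    if "date" in recs.columns and "date_start" not in recs.columns:
        recs["date_start"] = recs["date"]
        recs["date_end"] = recs["date"]
    for _, row in recs.iterrows():
        cam = str(row.get("camera", "all") or "all")
        if scope is not None and cam not in ("all", "", str(scope)):
            continue
        d0 = pd.to_datetime(row["date_start"])
        d1 = pd.to_datetime(row.get("date_end", row["date_start"]))
        hit = (out.index >= d0) & (out.index <= d1)
        out[hit] = np.nan
        ledger_rows.append({"scope": cam, "date_start": d0, "date_end": d1,
                            "criterion": "manual_record",
                            "note": str(row.get("note", row.get("flag", "")))})
    ledger = pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS)
    return out, ledger


def flag_deviating_plants(plant_series: pd.DataFrame, value_col: str = "astar",
                          k: float = 5.0, min_days: int = 3) -> pd.DataFrame:
    """Report plants whose series deviates from the genotype median (criterion 2).

    For each (genotype, date) the median and MAD over plants are computed;
    a plant is flagged on days where |value − median| > k·MAD (MAD scaled by
    1.4826 for normal consistency), and enters the report once it collects
    at least ``min_days`` such days (per-day MAD over a handful of plants is
    noisy; isolated single-day blips are not worth a reviewer's time). This
    mirrors the manual visual-inspection step as a reviewable report:
    nothing is removed automatically.
    ``plant_series`` columns: plant_id, genotype, date, <value_col>.
    """
    df = plant_series.copy()
    df["date"] = pd.to_datetime(df["date"])
    g = df.groupby(["genotype", "date"])[value_col]
    med = g.transform("median")
    mad = g.transform(lambda v: np.median(np.abs(v - np.median(v)))) * 1.4826
    dev = (df[value_col] - med).abs()
    df["flagged"] = (mad > 0) & (dev > k * mad)
    report = (df[df.flagged]
              .groupby(["plant_id", "genotype"], as_index=False)
              .agg(n_flagged_days=("date", "count"),
                   first_day=("date", "min"), last_day=("date", "max")))
    return report[report.n_flagged_days >= min_days].reset_index(drop=True)


def _nn_impute(values: np.ndarray, masked: np.ndarray):
    """1-D nearest-available-day imputation of ``masked`` positions.

    Donors are the non-missing, non-masked values; ties between equally
    near left/right donors average the two. Returns (imputed values,
    donor distance in days per position; 0 where not imputed).
    """
    n = values.size
    donors = np.flatnonzero(~masked & np.isfinite(values))
    out = values.copy()
    dist = np.zeros(n)
    if donors.size == 0:
        return out, dist
    targets = np.flatnonzero(masked)
    pos = np.searchsorted(donors, targets)
    left = donors[np.clip(pos - 1, 0, donors.size - 1)]
    right = donors[np.clip(pos, 0, donors.size - 1)]
    dl = np.abs(targets - left)
    dr = np.abs(right - targets)
    nearest = np.where(dl < dr, values[left],
                       np.where(dr < dl, values[right],
                                0.5 * (values[left] + values[right])))
    out[targets] = nearest
    dist[targets] = np.minimum(dl, dr)
    return out, dist


def block_zscore_filter(series: pd.Series, n_blocks: int = 10,
                        z_thresh: float = 5.0, robust: bool = True):
    """Criterion 3: block-masked nearest-neighbor imputation screen.

    The series is split into ``n_blocks`` equal contiguous spans (remainder
    days joining the last block). Each block in turn is masked and imputed
    from the unmasked remainder by nearest available day, giving per-day
    |imputed − original| differences. Because the imputation error of a
    smooth series grows with the distance to the donor day, each difference
    is normalized by its donor distance — the *implied daily rate of
    change* — before pooling; the rates are then z-scored (median/MAD by
    default; mean/sd with ``robust=False``, under which a block-sized
    anomaly can never reach z ≈ 5 because its own extreme values inflate
    the scale). Days with z > ``z_thresh`` are set missing and ledgered.
    Returns (filtered series, ledger).

    Differences are compared only among days with the same donor distance:
    a day right next to its donor carries the full day-to-day noise while a
    block-interior day (donor several days away) carries smoothed noise
    plus trend error, so pooling them would make the z heteroscedastic in
    both tails. Distance groups smaller than 8 days are merged with the
    next group.
    """
    n = len(series)
    if n < n_blocks:
        raise ValueError(f"series of length {n} shorter than {n_blocks} blocks")
    values = series.to_numpy(dtype=float)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    edges[-1] = n
    diffs = np.full(n, np.nan)
    dists = np.zeros(n)
    for b in range(n_blocks):
        lo = edges[b]
        hi = n if b == n_blocks - 1 else edges[b + 1]
        masked = np.zeros(n, dtype=bool)
        masked[lo:hi] = True
        imputed, dist = _nn_impute(values, masked)
        span = slice(lo, hi)
        diffs[span] = np.abs(imputed[span] - values[span])
        dists[span] = dist[span]
    ok = np.isfinite(diffs)
    z = np.full(n, np.nan)
    # merge donor-distance groups (ascending) until each holds >= 8 days
    groups = []
    current = []
    for d in np.unique(dists[ok]):
        current.extend(np.flatnonzero(ok & (dists == d)).tolist())
        if len(current) >= 8:
            groups.append(current)
            current = []
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    for idx in groups:
        vals = diffs[idx]
        if robust:
            center = np.median(vals)
            scale = 1.4826 * np.median(np.abs(vals - center))
        else:
            center = vals.mean()
            scale = vals.std()
        if not np.isfinite(scale) or scale == 0:
            continue
        z[idx] = (vals - center) / scale
    bad = ok & (z > z_thresh)
    out = series.copy()
    out[bad] = np.nan
    ledger_rows = []
    for d in series.index[bad]:
        ledger_rows.append({"scope": series.name or "series",
                            "date_start": d, "date_end": d,
                            "criterion": "block_zscore",
                            "note": f"z={z[series.index.get_loc(d)]:.2f}"})
    return out, pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS)
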