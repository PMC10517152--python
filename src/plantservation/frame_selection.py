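"""Step 1 — daily frame selection by brightness thresholds and a midday window.

Cameras fire 16–24 times a day; dusk/dawn and occluded frames are nearly
black and low-sun frames have strong directional shading. Selection keeps,
per calendar day, up to four frames whose maximum and mean pixel values
exceed thresholds (defaults 80 and 10 on the 0–255 scale) and whose
timestamp falls in a midday window (default 10:00–14:00 inclusive).
Survivors beyond the cap are dropped preferring times closest to noon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from datetime import datetime, time as dtime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = ["FrameRecord", "scan_frames", "select_frames", "records_to_frame"]

#: canonical ingest filename dialect, e.g. CAM1_20171103_1200.png
FILENAME_RE = re.compile(
    r"^CAM(?P<cam>[A-Za-z0-9]+)_(?P<date>\d{8})_(?P<time>\d{4})\.(png|jpg|jpeg)$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class FrameRecord:
    """One captured frame with its brightness statistics and selection state."""

    path: str
    camera_id: str
    timestamp: datetime
    max_pixel: int
    mean_pixel: float
    selected: bool = False
    rejection_reason: str = "none"  # dark_max | dark_mean | out_of_window | over_cap | none

    def __post_init__(self):
        if not (0 <= self.mean_pixel <= self.max_pixel <= 255):
            raise ValueError("require 0 <= mean_pixel <= max_pixel <= 255")
        if self.selected and self.rejection_reason != "none":
            raise ValueError("selected frames must carry rejection_reason 'none'")


def frame_stats(image: np.ndarray) -> tuple[int, float]:
    """(max_pixel, mean_pixel) of an 8-bit image.

    max_pixel is the maximum over the per-pixel channel maxima and mean_pixel
    the grand mean over all channel values.
    """
    arr = np.asarray(image)
    return int(arr.max(initial=0)), float(arr.mean()) if arr.size else 0.0


def parse_frame_filename(name: str) -> Optional[tuple[str, datetime]]:
    m = FILENAME_RE.match(name)
    if not m:
        return None
    ts = datetime.strptime(m["date"] + m["time"], "%Y%m%d%H%M")
    return m["cam"], ts


def scan_frames(image_dir) -> list[FrameRecord]:
    """Build one FrameRecord per parseable image file in ``image_dir``.

    Files whose names do not match the ``CAM{id}_{YYYYMMDD}_{HHMM}`` dialect
    are logged and skipped. An empty directory yields an empty list.
    """
    image_dir = Path(image_dir)
    records = []
    for p in sorted(image_dir.iterdir()):
        if not p.is_file():
            continue
        parsed = parse_frame_filename(p.name)
        if parsed is None:
            logger.warning("skipping unparseable filename: %s", p.name)
            continue
        cam, ts = parsed
        with Image.open(p) as im:
            arr = np.asarray(im.convert("RGB"))
        mx, mn = frame_stats(arr)
        records.append(FrameRecord(str(p), cam, ts, mx, mn))
    if not records:
        logger.warning("no parseable frames found in %s", image_dir)
    return records


def select_frames(
    records: Sequence[FrameRecord],
    max_thresh: float = 80,
    mean_thresh: float = 10,
    window: tuple = (dtime(10, 0), dtime(14, 0)),
    cap: int = 4,
) -> list[FrameRecord]:
    """Flag up to ``cap`` frames per calendar day passing brightness and window.

    A frame passes when ``max_pixel > max_thresh`` and ``mean_pixel >
    mean_thresh`` (strict, matching "greater than 80 and 10") and its time of
    day lies in the inclusive window. Among the passers of a day, the ``cap``
    frames closest to 12:00 are selected (ties to the earlier frame); the rest
    are marked ``over_cap``. Selection is idempotent: flags are recomputed
    from the immutable stats, never from previous flags.
    """
    w0, w1 = (_as_time(t) for t in window)
    if w0 >= w1:
        raise ValueError(f"malformed window: start {w0} >= end {w1}")
    noon = 12 * 60

    out: list[FrameRecord] = []
    by_day: dict = {}
    for rec in records:
        by_day.setdefault(rec.timestamp.date(), []).append(rec)

    for day in sorted(by_day):
        day_recs = sorted(by_day[day], key=lambda r: r.timestamp)
        survivors = []
        flagged = {}
        for rec in day_recs:
            if rec.max_pixel <= max_thresh:
                flagged[id(rec)] = "dark_max"
            elif rec.mean_pixel <= mean_thresh:
                flagged[id(rec)] = "dark_mean"
            elif not (w0 <= rec.timestamp.time() <= w1):
                flagged[id(rec)] = "out_of_window"
            else:
                survivors.append(rec)
        survivors.sort(
            key=lambda r: (abs(r.timestamp.hour * 60 + r.timestamp.minute - noon),
                           r.timestamp)
        )
        chosen = {id(r) for r in survivors[:cap]}
        for rec in day_recs:
            if id(rec) in chosen:
                out.append(replace(rec, selected=True, rejection_reason="none"))
            else:
                reason = flagged.get(id(rec), "over_cap")
                out.append(replace(rec, selected=False, rejection_reason=reason))
    return out


def _as_time(t) -> dtime:
    if isinstance(t, dtime):
        return t
    return datetime.strptime(str(t), "%H:%M").time()


def records_to_frame(records: Iterable[FrameRecord]) -> pd.DataFrame:
    """CSV-ready ledger of the selection run."""
    return pd.DataFrame(
        [
            {
                "path": r.path,
                "camera": r.camera_id,
                "timestamp": r.timestamp.isoformat(),
                "max_pixel": r.max_pixel,
                "mean_pixel": r.mean_pixel,
                "selected": r.selected,
                "reason": r.rejection_reason,
            }
            for r in records
        ]
    )
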