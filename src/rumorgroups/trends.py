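"""Temporal propagation analytics for a rumor group.

Daily report counts (local calendar days, default UTC+8 to match a Taiwan
corpus), resurfacing peaks, quoted-party attribution counts and exact-variant
first-seen timelines. Peaks are defined operationally — a day that reaches a
floor count and strictly dominates every day within a ±window — because viral
resurfacings are narrative judgements; the parameters are part of the result.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta, timezone
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "daily_counts", "find_peaks", "attribution_counts", "variant_timeline"]

TAIPEI = timezone(timedelta(hours=8))


@dataclass(frozen=True)
class DailySeries:
    """Zero-filled counts per consecutive calendar day for one group."""

    group_id: object
    series: pd.Series  # DatetimeIndex (daily, consecutive) -> int counts

    def __post_init__(self):
        if len(self.series) and not self.series.index.is_monotonic_increasing:
            raise ValueError("series index must be sorted")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def total(self) -> int:
        return int(self.series.sum())


def _to_local_days(timestamps, tz) -> pd.Series:
    stamps = pd.to_datetime(pd.Series(list(timestamps)), utc=True, format="ISO8601")
    return stamps.dt.tz_convert(tz).dt.normalize().dt.tz_localize(None)


def daily_counts(timestamps: Sequence, group_id=None, tz=TAIPEI) -> DailySeries:
    """Bin report timestamps by calendar day in ``tz``, zero-filling gaps."""
    if len(timestamps) == 0:
        return DailySeries(group_id, pd.Series(dtype=int))
    days = _to_local_days(timestamps, tz)
    counts = days.value_counts().sort_index()
    full = pd.date_range(counts.index.min(), counts.index.max(), freq="D")
    return DailySeries(group_id, counts.reindex(full, fill_value=0).astype(int))


def find_peaks(series: DailySeries, window: int = 3, min_count: int = 10) -> list[tuple]:
    """Days that reach ``min_count`` and strictly exceed all days within
    ±``window`` days; returned chronologically as (date, count)."""
    s = series.series
    if len(s) == 0:
        return []
    values = s.to_numpy()
    peaks = []
    for i, v in enumerate(values):
        if v < min_count:
            continue
        lo, hi = max(0, i - window), min(len(values), i + window + 1)
        neighbors = np.delete(values[lo:hi], i - lo)
        if neighbors.size == 0 or (v > neighbors).all():
            peaks.append((s.index[i].date(), int(v)))
    return peaks


def attribution_counts(
    texts: Sequence[str],
    lexicon: Mapping[str, Sequence[str]],
    timestamps: Optional[Sequence] = None,
    by_day: bool = False,
    tz=TAIPEI,
):
    """Count messages quoting each party via substring alias matching.

    A message counts toward every party whose alias it contains (multiple
    attribution is real: composite rumors quote several authorities). With
    ``by_day=True`` returns a day × party DataFrame, else a party → count dict.
    """
    hits = {
        party: np.fromiter(
            (any(alias in (t or "") for alias in aliases) for t in texts),
            dtype=bool,
            count=len(texts),
        )
        for party, aliases in lexicon.items()
    }
    if not by_day:
        return {party: int(mask.sum()) for party, mask in hits.items()}
    if timestamps is None:
        raise ValueError("by_day=True requires timestamps")
    days = _to_local_days(timestamps, tz)
    frame = pd.DataFrame(hits, index=days)
    return frame.groupby(level=0).sum().astype(int)


def _normalize(text: str) -> str:
    return " ".join((text or "").split())


def variant_timeline(
    texts: Sequence[str], timestamps: Sequence, tz=TAIPEI
) -> pd.DataFrame:
    """Exact text variants (whitespace-normalized) with first-seen date and
    count, sorted by first appearance.

    This is the quantitative scaffold for change-log curation: a human reads
    the variants in order of appearance to describe how the narrative mutated.
    """
    if len(texts) != len(timestamps):
        raise ValueError("texts and timestamps must align")
    if len(texts) == 0:
        return pd.DataFrame(columns=["variant", "first_seen", "count"])
    days = _to_local_days(timestamps, tz)
    frame = pd.DataFrame({"variant": [_normalize(t) for t in texts], "day": days})
    agg = frame.groupby("variant").agg(first_seen=("day", "min"), count=("day", "size"))
    agg = agg.reset_index().sort_values(["first_seen", "variant"]).reset_index(drop=True)
    agg["first_seen"] = agg["first_seen"].dt.date
    return agg
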