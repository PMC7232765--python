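"""Salinity stress-index profiles from daily series.

Oyster tolerance in the Gulf of Mexico is conventionally summarised by
five salinity regimes: >20 psu (no negative effects), 15–20 psu (reduced
reproduction), 6–15 psu (reduced spat recruitment), 3.5–6 psu (reduced
growth) and 0–3.5 psu (survival limited to months).  This module bins
daily practical-salinity values into those regimes and computes the mean
over a pre-collection window.

Boundary convention: internal edges (3.5, 6, 15) are upper-exclusive and
the top bin is lower-inclusive, so a day at exactly 20 psu counts as
">20" and statements like "above 15 psu" correspond to the top two bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["BIN_EDGES", "BIN_LABELS", "StressProfile",
           "bin_salinity_fractions", "window_mean", "read_salinity_csv"]

BIN_EDGES = (3.5, 6.0, 15.0, 20.0)
BIN_LABELS = ("0-3.5", "3.5-6", "6-15", "15-20", ">20")


@dataclass
class StressProfile:
    """Fractions of days per salinity regime over a date range."""

    site: str
    fractions: pd.Series          # indexed by BIN_LABELS, sums to 1
    n_days: int
    n_missing: int = 0
    window_mean_psu: Optional[float] = None
    window_mean_temp: Optional[float] = None

    def __post_init__(self) -> None:
        self.fractions = self.fractions.reindex(BIN_LABELS).fillna(0.0)
        if self.n_days > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("bin fractions must sum to 1")


def _daily(series: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated same-day measurements to one daily average."""
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    return df.groupby("date", as_index=False)["psu"].mean()


def bin_salinity_fractions(series: pd.DataFrame, site: str = "",
                           date_range: Optional[Tuple[str, str]] = None
                           ) -> StressProfile:
    """Fraction of days per stress regime.

    ``series`` needs columns date and psu (repeated same-day values are
    first averaged).  ``date_range`` (inclusive) restricts the days used;
    calendar days absent from the series are skipped and counted as
    missing.  Raises on negative salinity or an empty range.
    """
    df = _daily(series)
    n_missing = 0
    if date_range is not None:
        lo, hi = pd.to_datetime(date_range[0]), pd.to_datetime(date_range[1])
        df = df[(df["date"] >= lo) & (df["date"] <= hi)]
        n_missing = int((hi - lo).days + 1 - len(df))
    if df.empty:
        raise ValueError("no salinity observations in the requested range")
    vals = df["psu"].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative salinity value in series")
    idx = np.digitize(vals, BIN_EDGES, right=False)  # >=20 lands in top bin
    counts = np.bincount(idx, minlength=len(BIN_LABELS))
    frac = pd.Series(counts / len(vals), index=list(BIN_LABELS))
    return StressProfile(site, frac, n_days=len(vals), n_missing=n_missing)


def window_mean(series: pd.DataFrame, collection_date: str,
                window: int = 10, column: str = "psu"
                ) -> Tuple[float, int]:
    """Mean of daily values over the ``window`` days before collection.

    The window is the ``window`` calendar days strictly before
    ``collection_date``; missing days are skipped and their count
    returned.  Raises when no observation falls in the window.
    """
    df = _daily(series.rename(columns={column: "psu"}))
    end = pd.to_datetime(collection_date)
    start = end - pd.Timedelta(days=window)
    sub = df[(df["date"] >= start) & (df["date"] < end)]
    if sub.empty:
        raise ValueError(
            f"no observations in the {window} days before {collection_date}")
    return float(sub["psu"].mean()), window - len(sub)


def read_salinity_csv(path) -> pd.DataFrame:
    """Read a salinity CSV with columns site, date, psu[, temperature]."""
    df = pd.read_csv(path)
    need = {"site", "date", "psu"}
    if not need.issubset(df.columns):
        raise ValueError(f"salinity CSV needs columns {sorted(need)}")
    return df
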