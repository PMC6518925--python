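"""Daily water-temperature series.

The sole environmental driver of the package: a dated sequence of daily mean
water temperatures (°C).  Time within a series is measured in fractional days
post some start date; day ``k`` (``k = 0`` on the start date itself) spans
``[k, k + 1)`` and carries the daily mean temperature recorded for that
calendar day.  Accumulated thermal units (ATU) are the running sum of daily
means over that clock, pro-rating the final partial day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = ["TemperatureSeries", "atu_between"]


class SeriesSpanError(ValueError):
    """A requested span is not covered by the series."""


@dataclass
class TemperatureSeries:
    """Dated daily mean water temperatures for one site or tank.

    Parameters
    ----------
    site_id : str
        Free-text label (site name, tank/treatment id).
    data : pandas.Series
        Daily mean temperature (°C) indexed by normalized ``DatetimeIndex``.
        Dates must be strictly increasing; gaps are tolerated at construction
        (see :func:`hatchphen.wild.fill_gaps`) but rejected by operations that
        need a contiguous span.
    """

    site_id: str
    data: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        s = pd.Series(self.data, dtype=float)
        idx = pd.DatetimeIndex(s.index).normalize()
        s.index = idx
        if idx.has_duplicates:
            raise ValueError("duplicate dates in temperature series")
        if not idx.is_monotonic_increasing:
            s = s.sort_index()
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("non-finite temperature values")
        self.data = s

    # -- construction -----------------------------------------------------
    @classmethod
    def from_values(
        cls, start: date, temps, site_id: str = "series"
    ) -> "TemperatureSeries":
        temps = np.asarray(temps, dtype=float)
        idx = pd.date_range(start=pd.Timestamp(start), periods=len(temps), freq="D")
        return cls(site_id=site_id, data=pd.Series(temps, index=idx))

    @classmethod
    def from_csv(cls, path, site_id: str | None = None) -> "TemperatureSeries":
        """Read ``date,temp_c`` CSV with ISO-8601 dates, one row per day."""
        df = pd.read_csv(path)
        missing = {"date", "temp_c"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        if len(df) == 0:
            raise ValueError(f"{path}: empty temperature file")
        try:
            idx = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable date column: {exc}") from exc
        name = site_id if site_id is not None else str(path)
        return cls(site_id=name, data=pd.Series(df["temp_c"].to_numpy(), index=idx))

    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {"date": self.data.index.strftime("%Y-%m-%d"), "temp_c": self.data.to_numpy()}
        )
        out.to_csv(path, index=False)

    # -- basic views ------------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temps(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def start(self) -> date:
        return self.data.index[0].date()

    @property
    def end(self) -> date:
        return self.data.index[-1].date()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_contiguous(self) -> bool:
        if len(self.data) < 2:
            return True
        return bool((np.diff(self.data.index.to_numpy()) == np.timedelta64(1, "D")).all())

    def __contains__(self, day: date) -> bool:
        ts = pd.Timestamp(day)
        return bool(self.data.index.min() <= ts <= self.data.index.max())

    # -- span access ------------------------------------------------------
    def window(self, start: date, n_days: int) -> np.ndarray:
        """Temps for the ``n_days`` consecutive days beginning at ``start``.

        Raises :class:`SeriesSpanError` if any day is absent (series ends or a
        gap intersects the span).
        """
        if n_days < 0:
            raise ValueError("n_days must be >= 0")
        want = pd.date_range(pd.Timestamp(start), periods=n_days, freq="D")
        got = self.data.reindex(want)
        if got.isna().any():
            first_bad = want[got.isna().to_numpy()][0].date()
            raise SeriesSpanError(
                f"series {self.site_id!r} missing day {first_bad} in requested span"
            )
        return got.to_numpy()

    def max_span_days(self, start: date) -> int:
        """Number of consecutive covered days available from ``start``."""
        ts = pd.Timestamp(start)
        if ts < self.data.index[0] or ts > self.data.index[-1]:
            return 0
        sub = self.data.loc[ts:]
        steps = np.diff(sub.index.to_numpy()) == np.timedelta64(1, "D")
        if steps.all():
            return len(sub)
        return int(np.argmin(steps)) + 1


def atu_between(
    series: TemperatureSeries,
    start_date: date,
    end_point: float,
    atu_floor_c: float = 0.0,
) -> float:
    """ATU accumulated from ``start_date`` through fractional day ``end_point``.

    Sum of daily mean temperatures over whole days plus the pro-rated fraction
    of the final day; day 0 is ``start_date`` itself.  Daily means below
    ``atu_floor_c`` are clamped to it (thermal units are non-negative); pass
    ``atu_floor_c=-inf`` to disable.
    """
    if end_point < 0:
        raise SeriesSpanError("end_point must be >= 0")
    whole = int(np.floor(end_point))
    frac = end_point - whole
    n_days = whole + (1 if frac > 0 else 0)
    temps = series.window(start_date, n_days)
    temps = np.maximum(temps, atu_floor_c)
    total = float(temps[:whole].sum())
    if frac > 0:
        total += frac * float(temps[whole])
    return total
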