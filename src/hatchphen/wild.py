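"""Hatch and emergence windows for wild spawning from river temperature series.

A spawning window (default 24 Oct–7 Nov) is propagated through a development
model over a site's daily river temperatures: accumulation runs from each
boundary spawn date (optionally a daily grid), and the 50%-hatch and
emergence event dates from the earliest and latest spawn bound the predicted
hatch and emergence windows for that season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .models import ClampPolicy, DevelopmentModel, accumulate
from .series import TemperatureSeries

__all__ = [
    "SpawnWindow",
    "PredictionWindow",
    "fill_gaps",
    "predict_windows",
    "predict_all_seasons",
    "summarize_windows",
    "DEFAULT_SPAWN_WINDOW",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpawnWindow:
    """Year-relative calendar interval of egg deposition: (month, day) pairs."""

    start_month: int = 10
    start_day: int = 24
    end_month: int = 11
    end_day: int = 7

    def for_year(self, year: int) -> tuple[date, date]:
        start = date(year, self.start_month, self.start_day)
        end_year = year + (1 if (self.end_month, self.end_day) < (self.start_month, self.start_day) else 0)
        end = date(end_year, self.end_month, self.end_day)
        if start > end:
            raise ValueError("spawn window start after end")
        return start, end


DEFAULT_SPAWN_WINDOW = SpawnWindow()


@dataclass
class PredictionWindow:
    """Predicted hatch and emergence intervals for one site and season."""

    site_id: str
    season_year: int  # year of the spawn-window start
    hatch_window: tuple[date, date] | None
    emergence_window: tuple[date, date] | None
    hatch_duration_d: float | None
    emergence_duration_d: float | None
    flags: tuple[str, ...] = ()
    spawn_dates: tuple[date, ...] = ()

    @property
    def resolved(self) -> bool:
        return self.hatch_window is not None and self.emergence_window is not None


def fill_gaps(
    series: TemperatureSeries,
    max_gap_days: int = 3,
    clamp: ClampPolicy | None = None,
) -> TemperatureSeries:
    """Linearly interpolate gaps of at most ``max_gap_days`` missing days.

    Longer gaps are left missing (the affected season will come back flagged
    from :func:`predict_windows` rather than failing).  If a clamp policy is
    given, sub-zero logger readings are floored at its ATU floor.
    """
    data = series.data
    full = pd.date_range(data.index[0], data.index[-1], freq="D")
    re = data.reindex(full)
    if max_gap_days > 0:
        filled = re.interpolate(method="linear", limit=max_gap_days, limit_area="inside")
    else:
        filled = re.copy()
    # revert any gap longer than max_gap_days (interpolate's limit fills the
    # first max_gap_days of longer gaps too)
    isna = re.isna().to_numpy()
    if isna.any():
        run_start = None
        for i, miss in enumerate(list(isna) + [False]):
            if miss and run_start is None:
                run_start = i
            elif not miss and run_start is not None:
                run_len = i - run_start
                if run_len > max_gap_days:
                    filled.iloc[run_start:i] = np.nan
                    logger.info(
                        "%s: gap of %d days at %s left unfilled",
                        series.site_id, run_len, full[run_start].date(),
                    )
                run_start = None
    filled = filled.dropna()
    if clamp is not None:
        filled = filled.clip(lower=clamp.atu_floor_c)
    return TemperatureSeries(site_id=series.site_id, data=filled)


def predict_windows(
    series: TemperatureSeries,
    season_year: int,
    model: DevelopmentModel | None = None,
    spawn_window: SpawnWindow = DEFAULT_SPAWN_WINDOW,
    grid: str = "endpoints",
    clamp: ClampPolicy = ClampPolicy(),
) -> PredictionWindow:
    """Predicted hatch/emergence window for one site and spawn season.

    ``grid="endpoints"`` runs the two boundary spawn dates only;
    ``grid="daily"`` runs every date in the spawn window (the window bounds
    are then min/max over the grid, which coincide with the endpoint run
    whenever development is monotone in start date).
    """
    if model is None:
        model = DevelopmentModel.gorodilov()
    if grid not in ("endpoints", "daily"):
        raise ValueError("grid must be 'endpoints' or 'daily'")
    events = ["hatch50", "emergence"] if "emergence" in model.event_thresholds else [model.primary_event]
    start, end = spawn_window.for_year(season_year)
    if grid == "endpoints" or start == end:
        spawn_dates = [start] if start == end else [start, end]
    else:
        spawn_dates = [start + timedelta(days=k) for k in range((end - start).days + 1)]

    flags: list[str] = []
    hatch_times: list[tuple[date, float]] = []
    emerge_times: list[tuple[date, float]] = []
    for sd in spawn_dates:
        if sd not in series:
            flags.append(f"spawn date {sd} outside series")
            continue
        traj = accumulate(series, model, sd, events=events, clamp=clamp)
        ev_h = traj.event(events[0])
        if ev_h.resolved:
            hatch_times.append((sd, ev_h.fractional_day_offset))
        else:
            flags.append(f"{events[0]} {ev_h.status} from spawn {sd}")
        if "emergence" in events:
            ev_e = traj.event("emergence")
            if ev_e.resolved:
                emerge_times.append((sd, ev_e.fractional_day_offset))
            else:
                flags.append(f"emergence {ev_e.status} from spawn {sd}")

    def _window(times):
        if len(times) != len(spawn_dates) or not times:
            return None, None
        abs_times = [pd.Timestamp(sd).toordinal() + off for sd, off in times]
        lo, hi = min(abs_times), max(abs_times)
        w = (date.fromordinal(int(lo)), date.fromordinal(int(hi)))
        return w, float(hi - lo)

    hatch_w, hatch_dur = _window(hatch_times)
    emerge_w, emerge_dur = (None, None)
    if "emergence" in events:
        emerge_w, emerge_dur = _window(emerge_times)

    return PredictionWindow(
        site_id=series.site_id,
        season_year=season_year,
        hatch_window=hatch_w,
        emergence_window=emerge_w,
        hatch_duration_d=hatch_dur,
        emergence_duration_d=emerge_dur,
        flags=tuple(flags),
        spawn_dates=tuple(spawn_dates),
    )


def predict_all_seasons(
    series: TemperatureSeries,
    model: DevelopmentModel | None = None,
    spawn_window: SpawnWindow = DEFAULT_SPAWN_WINDOW,
    grid: str = "endpoints",
    clamp: ClampPolicy = ClampPolicy(),
) -> list[PredictionWindow]:
    """One :class:`PredictionWindow` per season whose spawn window the series covers."""
    out = []
    for year in range(series.start.year, series.end.year + 1):
        start, _ = spawn_window.for_year(year)
        if start in series:
            out.append(predict_windows(series, year, model, spawn_window, grid, clamp))
    return out


def summarize_windows(windows) -> dict:
    """Across-year/site summary: date ranges and mean ± SD window durations."""
    resolved = [w for w in windows if w.resolved]
    if not resolved:
        raise ValueError("no resolved prediction windows to summarize")

    def _summary(ws) -> dict:
        hatch_durs = np.array([w.hatch_duration_d for w in ws])
        emerge_durs = np.array([w.emergence_duration_d for w in ws])
        sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
        return {
            "n_windows": len(ws),
            "hatch_earliest": min(w.hatch_window[0] for w in ws).isoformat(),
            "hatch_latest": max(w.hatch_window[1] for w in ws).isoformat(),
            "emergence_earliest": min(w.emergence_window[0] for w in ws).isoformat(),
            "emergence_latest": max(w.emergence_window[1] for w in ws).isoformat(),
            "hatch_duration_mean_d": float(hatch_durs.mean()),
            "hatch_duration_sd_d": sd(hatch_durs),
            "emergence_duration_mean_d": float(emerge_durs.mean()),
            "emergence_duration_sd_d": sd(emerge_durs),
        }

    summary = {"pooled": _summary(resolved), "by_site": {}}
    for site in sorted({w.site_id for w in resolved}):
        summary["by_site"][site] = _summary([w for w in resolved if w.site_id == site])
    summary["n_unresolved"] = len(list(windows)) - len(resolved)
    return summary


def windows_to_frame(windows) -> pd.DataFrame:
    """Windows as the CSV dialect ``site,season_year,...,flags``."""
    rows = []
    for w in windows:
        rows.append(
            {
                "site": w.site_id,
                "season_year": w.season_year,
                "hatch_start": w.hatch_window[0].isoformat() if w.hatch_window else "",
                "hatch_end": w.hatch_window[1].isoformat() if w.hatch_window else "",
                "emerge_start": w.emergence_window[0].isoformat() if w.emergence_window else "",
                "emerge_end": w.emergence_window[1].isoformat() if w.emergence_window else "",
                "hatch_dur_d": w.hatch_duration_d if w.hatch_duration_d is not None else "",
                "emerge_dur_d": w.emergence_duration_d if w.emergence_duration_d is not None else "",
                "flags": ";".join(w.flags),
            }
        )
    return pd.DataFrame(rows)
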