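"""Thermal development models for Atlantic salmon embryos.

Four published closed forms map water temperature to a development rate or a
days-to-event prediction:

* **Crisp** — ``log10(D) = c − 2.6562·log10(T + 11.0)``; ``D`` = days from
  fertilization to 50% hatch.  The constant ``c`` defaults to 5.1908, the
  Atlantic salmon entry of the original desk study (``D = 155200·(T+11)^−2.6562``).
* **Gorodilov** — ``log10(τ_s) = 3.0984 − 0.0967·T + 0.00207·T²``; ``τ_s`` is
  the time in minutes to form one somite pair, a unit of relative
  developmental age.  Peak (50%) hatch at 315 accumulated somite-units,
  emergence from the gravel at 450.  Valid for 0.1–11.0 °C.
* **WinSIRP** (temperature-only form) — ``D = 11248/(T_wk + 5.3944)^2.0198``
  driven by weekly average temperatures; 50% hatch.
* **Kane** — ``ln(D) = 5.483·e^(−0.0347·T)``; 90% hatch.

Over an arbitrary daily temperature series, development is accumulated by
rate summation: each day contributes ``1/D(T)`` of the event (or
``1440/τ_s(T)`` somite-units for Gorodilov) and the event fires when the
running sum first reaches the threshold, with linear interpolation inside the
crossing day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np

from .series import SeriesSpanError, TemperatureSeries, atu_between

__all__ = [
    "CRISP_LOG10_INTERCEPT",
    "ClampPolicy",
    "DevelopmentModel",
    "DevelopmentTrajectory",
    "EventResult",
    "accumulate",
    "crisp_days_to_event",
    "gorodilov_tau_s",
    "winsirp_days_to_event",
    "kane_days_to_event",
    "get_model",
    "MINUTES_PER_DAY",
]

MINUTES_PER_DAY = 1440.0

#: log10 intercept of the Crisp Atlantic salmon equation (the printed form's
#: constant term is corrupt; this is the original source's value, overridable).
CRISP_LOG10_INTERCEPT = 5.1908

GORODILOV_VALID_RANGE = (0.1, 11.0)


class TemperatureDomainError(ValueError):
    """Temperature outside a model's mathematical domain."""


def _as_finite(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise TemperatureDomainError("non-finite temperature")
    return t


def crisp_days_to_event(t_avg, intercept: float = CRISP_LOG10_INTERCEPT):
    """Crisp: days from fertilization to 50% hatch at daily mean ``t_avg`` °C."""
    t = _as_finite(t_avg)
    if np.any(t <= -11.0):
        raise TemperatureDomainError("Crisp model requires T > -11.0 °C")
    out = 10.0 ** (intercept - 2.6562 * np.log10(t + 11.0))
    return out if out.ndim else float(out)


def gorodilov_tau_s(t_avg):
    """Gorodilov: minutes per somite pair at ``t_avg`` °C.

    Input is clamped to the 0.1–11.0 °C range the relationship was fitted on.
    """
    t = _as_finite(t_avg)
    t = np.clip(t, *GORODILOV_VALID_RANGE)
    out = 10.0 ** (3.0984 - 0.0967 * t + 0.00207 * t * t)
    return out if out.ndim else float(out)


def winsirp_days_to_event(t_wk):
    """WinSIRP (temperature-only): days to 50% hatch at weekly mean ``t_wk`` °C."""
    t = _as_finite(t_wk)
    if np.any(t <= -5.3944):
        raise TemperatureDomainError("WinSIRP model requires T > -5.3944 °C")
    out = 11248.0 / (t + 5.3944) ** 2.0198
    return out if out.ndim else float(out)


def kane_days_to_event(t_avg):
    """Kane: days to 90% hatch at daily mean ``t_avg`` °C."""
    t = _as_finite(t_avg)
    out = np.exp(5.483 * np.exp(-0.0347 * t))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ClampPolicy:
    """Temperature clamps applied during accumulation.

    ``rate_floor_c`` — daily means below this are raised to it before rate
    evaluation (default 0.1 °C, the lower bound of the Gorodilov data).
    ``atu_floor_c`` — daily means below this are raised to it in ATU sums
    (default 0 °C: thermal units are non-negative).
    """

    rate_floor_c: float = 0.1
    atu_floor_c: float = 0.0

    def clamp_for_rate(self, temps: np.ndarray) -> np.ndarray:
        return np.maximum(temps, self.rate_floor_c)


@dataclass(frozen=True)
class DevelopmentModel:
    """A named closed-form development model plus its event thresholds.

    ``event_thresholds`` are in model-native units: fractions of the event
    (threshold 1.0) for Crisp/WinSIRP/Kane, accumulated somite-units for
    Gorodilov.  ``time_step`` is the averaging window driving the daily rate.
    """

    name: str
    parameters: Mapping[str, float] = field(default_factory=dict)
    event_thresholds: Mapping[str, float] = field(default_factory=dict)
    time_step: str = "daily"  # "daily" or "weekly"
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.time_step not in ("daily", "weekly"):
            raise ValueError("time_step must be 'daily' or 'weekly'")
        for event, thr in self.event_thresholds.items():
            if thr < 0:
                raise ValueError(f"threshold for {event!r} must be >= 0")

    # -- constructors ------------------------------------------------------
    @classmethod
    def crisp(cls, intercept: float = CRISP_LOG10_INTERCEPT) -> "DevelopmentModel":
        return cls(
            name="crisp",
            parameters={"slope": -2.6562, "shift_c": 11.0, "intercept": intercept},
            event_thresholds={"hatch50": 1.0},
            log_base=10.0,
        )

    @classmethod
    def gorodilov(
        cls, hatch50: float = 315.0, emergence: float = 450.0
    ) -> "DevelopmentModel":
        return cls(
            name="gorodilov",
            parameters={"a": 3.0984, "b": -0.0967, "c": 0.00207},
            event_thresholds={"hatch50": hatch50, "emergence": emergence},
            log_base=10.0,
        )

    @classmethod
    def winsirp(cls) -> "DevelopmentModel":
        return cls(
            name="winsirp",
            parameters={"numerator": 11248.0, "shift_c": 5.3944, "power": 2.0198},
            event_thresholds={"hatch50": 1.0},
            time_step="weekly",
            log_base=np.e,
        )

    @classmethod
    def kane(cls) -> "DevelopmentModel":
        return cls(
            name="kane",
            parameters={"a": 5.483, "b": -0.0347},
            event_thresholds={"hatch90": 1.0},
            log_base=np.e,
        )

    def with_thresholds(self, **thresholds: float) -> "DevelopmentModel":
        merged = dict(self.event_thresholds)
        merged.update(thresholds)
        return replace(self, event_thresholds=merged)

    # -- closed forms ------------------------------------------------------
    @property
    def primary_event(self) -> str:
        return "hatch90" if self.name == "kane" else "hatch50"

    def daily_rate(self, temps) -> np.ndarray:
        """Development accrued per day, in model-native units, at ``temps``."""
        t = np.atleast_1d(_as_finite(temps))
        if self.name == "crisp":
            r = 1.0 / crisp_days_to_event(t, self.parameters["intercept"])
        elif self.name == "gorodilov":
            r = MINUTES_PER_DAY / gorodilov_tau_s(t)
        elif self.name == "winsirp":
            r = 1.0 / winsirp_days_to_event(t)
        elif self.name == "kane":
            r = 1.0 / kane_days_to_event(t)
        else:
            raise ValueError(f"unknown model {self.name!r}")
        return np.asarray(r, dtype=float)

    def days_to_event(self, temp: float, event: str | None = None) -> float:
        """Closed-form days to ``event`` at constant temperature ``temp``."""
        event = event or self.primary_event
        try:
            thr = self.event_thresholds[event]
        except KeyError:
            raise KeyError(f"model {self.name!r} has no event {event!r}") from None
        return float(thr / self.daily_rate(temp)[0])


@dataclass(frozen=True)
class EventResult:
    """Outcome of one development event within a trajectory."""

    event: str
    resolved: bool
    event_date: date | None = None
    fractional_day_offset: float | None = None  # DPF, fertilization day = 0
    atu_at_event: float | None = None
    dpf_at_event: float | None = None
    status: str = "ok"  # "ok" | "unresolved" | "gap"


@dataclass
class DevelopmentTrajectory:
    """Cumulative development and ATU per day from a start date."""

    model: DevelopmentModel
    start_date: date
    daily_fraction: np.ndarray
    cum_development: np.ndarray
    cum_atu: np.ndarray
    event_results: dict[str, EventResult]

    @property
    def resolved(self) -> bool:
        return all(r.resolved for r in self.event_results.values())

    def event(self, name: str) -> EventResult:
        return self.event_results[name]


def _weekly_block_means(temps: np.ndarray) -> np.ndarray:
    """Replace each consecutive non-overlapping 7-day block by its mean.

    Blocks are counted from the start of the array; a trailing partial block
    uses its own mean.
    """
    out = np.empty_like(temps)
    for b in range(0, len(temps), 7):
        out[b : b + 7] = temps[b : b + 7].mean()
    return out


def accumulate(
    series: TemperatureSeries,
    model: DevelopmentModel,
    start_date: date,
    events: Sequence[str] | None = None,
    clamp: ClampPolicy = ClampPolicy(),
) -> DevelopmentTrajectory:
    """Rate-summation accumulation of development over a temperature series.

    Day ``k`` (day 0 = ``start_date``) accrues ``rate(T_k)`` model-native
    units; an event fires at the fractional day where the running sum first
    reaches its threshold, found by linear interpolation inside the crossing
    day.  ATU at the event is the (clamped) daily-mean sum through the
    fractional crossing point.  If the series is exhausted — or interrupted by
    a gap — before a threshold is reached, that event is returned with
    ``resolved=False`` and a status flag; nothing is extrapolated.
    """
    if events is None:
        events = list(model.event_thresholds)
    unknown = [e for e in events if e not in model.event_thresholds]
    if unknown:
        raise KeyError(f"model {model.name!r} has no event(s) {unknown}")
    if start_date not in series:
        raise SeriesSpanError(
            f"start_date {start_date} outside series {series.site_id!r}"
        )

    n_avail = series.max_span_days(start_date)
    truncated_by_gap = n_avail < (series.end - start_date).days + 1
    temps = series.window(start_date, n_avail)
    rate_temps = clamp.clamp_for_rate(temps)
    if model.time_step == "weekly":
        rate_temps = _weekly_block_means(rate_temps)
    rates = model.daily_rate(rate_temps)
    cum_dev = np.cumsum(rates)
    atu_temps = np.maximum(temps, clamp.atu_floor_c)
    cum_atu = np.cumsum(atu_temps)

    results: dict[str, EventResult] = {}
    for event in events:
        thr = model.event_thresholds[event]
        if thr == 0:
            results[event] = EventResult(
                event=event,
                resolved=True,
                event_date=start_date,
                fractional_day_offset=0.0,
                atu_at_event=0.0,
                dpf_at_event=0.0,
            )
            continue
        idx = int(np.searchsorted(cum_dev, thr))
        if idx >= len(cum_dev):
            results[event] = EventResult(
                event=event,
                resolved=False,
                status="gap" if truncated_by_gap else "unresolved",
            )
            continue
        prev = cum_dev[idx - 1] if idx > 0 else 0.0
        tstar = idx + (thr - prev) / rates[idx]
        atu = (cum_atu[idx - 1] if idx > 0 else 0.0) + (tstar - idx) * atu_temps[idx]
        results[event] = EventResult(
            event=event,
            resolved=True,
            event_date=start_date + timedelta(days=idx),
            fractional_day_offset=float(tstar),
            atu_at_event=float(atu),
            dpf_at_event=float(tstar),
        )

    return DevelopmentTrajectory(
        model=model,
        start_date=start_date,
        daily_fraction=rates,
        cum_development=cum_dev,
        cum_atu=cum_atu,
        event_results=results,
    )


_CONSTRUCTORS: dict[str, Callable[..., DevelopmentModel]] = {
    "crisp": DevelopmentModel.crisp,
    "gorodilov": DevelopmentModel.gorodilov,
    "winsirp": DevelopmentModel.winsirp,
    "kane": DevelopmentModel.kane,
}


def get_model(name: str, **kwargs) -> DevelopmentModel:
    """Build one of the four named models (``crisp``/``gorodilov``/``winsirp``/``kane``)."""
    try:
        ctor = _CONSTRUCTORS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_CONSTRUCTORS)}"
        ) from None
    return ctor(**kwargs)
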