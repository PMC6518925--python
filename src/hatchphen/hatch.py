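"""Per-tube hatch-timing estimation.

Each incubation tube starts with a known number of eggs (50 in the split-brood
design) and yields daily counts of newly hatched and newly dead eggs.  Hatch
timing is summarized by fitting a binomial logistic regression of the
cumulative proportion hatched against cumulative ATU: the denominator is the
number of eggs that *eventually* hatched, so timing is conditional on hatching
and dead eggs never enter the trials.  ATU at 50% and 90% hatch are read off
the fitted curve; days post fertilization at 50% hatch (DPF_50) follow by
inverting the cumulative-ATU clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit

from .series import TemperatureSeries, atu_between

__all__ = [
    "TubeRecord",
    "HatchDataset",
    "HatchTimingEstimate",
    "fit_hatch_logistic",
    "fit_all_tubes",
    "exclude_low_success",
]

logger = logging.getLogger(__name__)

LOGIT_90 = float(logit(0.9))


class HatchEstimationError(ValueError):
    pass


@dataclass
class TubeRecord:
    """Daily hatch observations for one incubation tube."""

    tube_id: str
    family_id: str
    treatment: str
    fert_date: date
    obs: pd.DataFrame  # columns: obs_date, n_hatched_new, n_dead_new
    n_eggs: int = 50

    def __post_init__(self) -> None:
        obs = self.obs.copy()
        obs["obs_date"] = pd.to_datetime(obs["obs_date"]).dt.normalize()
        obs = obs.sort_values("obs_date").reset_index(drop=True)
        for col in ("n_hatched_new", "n_dead_new"):
            vals = obs[col].to_numpy()
            if (vals < 0).any() or not np.equal(np.mod(vals, 1), 0).all():
                raise ValueError(f"{self.tube_id}: {col} must be non-negative integers")
        if obs["n_hatched_new"].sum() + obs["n_dead_new"].sum() > self.n_eggs:
            raise ValueError(
                f"{self.tube_id}: hatched + dead exceeds initial egg count"
            )
        self.obs = obs

    @property
    def n_hatched(self) -> int:
        return int(self.obs["n_hatched_new"].sum())

    @property
    def hatch_success(self) -> float:
        return self.n_hatched / self.n_eggs


@dataclass
class HatchDataset:
    """Tube records plus the temperature series of each treatment tank."""

    records: list[TubeRecord]
    regimes: dict = field(default_factory=dict)  # treatment (or (treatment, fert_date)) -> TemperatureSeries

    def series_for(self, tube: TubeRecord) -> TemperatureSeries:
        key = (tube.treatment, tube.fert_date)
        if key in self.regimes:
            return self.regimes[key]
        return self.regimes[tube.treatment]

    def families(self) -> list[str]:
        return sorted({t.family_id for t in self.records})

    # -- CSV dialect: tube_id,family_id,treatment,fert_date,obs_date,n_hatched_new,n_dead_new
    @classmethod
    def from_csv(cls, path, regimes: dict | None = None, n_eggs: int = 50) -> "HatchDataset":
        df = pd.read_csv(path)
        required = {
            "tube_id", "family_id", "treatment", "fert_date",
            "obs_date", "n_hatched_new", "n_dead_new",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        records = []
        for tube_id, grp in df.groupby("tube_id", sort=True):
            fert = pd.to_datetime(grp["fert_date"].iloc[0]).date()
            records.append(
                TubeRecord(
                    tube_id=str(tube_id),
                    family_id=str(grp["family_id"].iloc[0]),
                    treatment=str(grp["treatment"].iloc[0]),
                    fert_date=fert,
                    obs=grp[["obs_date", "n_hatched_new", "n_dead_new"]],
                    n_eggs=n_eggs,
                )
            )
        return cls(records=records, regimes=regimes or {})

    def to_csv(self, path) -> None:
        rows = []
        for t in self.records:
            for _, r in t.obs.iterrows():
                rows.append(
                    {
                        "tube_id": t.tube_id,
                        "family_id": t.family_id,
                        "treatment": t.treatment,
                        "fert_date": t.fert_date.isoformat(),
                        "obs_date": r["obs_date"].strftime("%Y-%m-%d"),
                        "n_hatched_new": int(r["n_hatched_new"]),
                        "n_dead_new": int(r["n_dead_new"]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class HatchTimingEstimate:
    """Fitted hatch timing for one tube."""

    tube_id: str
    family_id: str
    treatment: str
    fert_date: date
    atu50: float
    atu90: float
    dpf50: float
    slope: float | None
    intercept: float | None
    hatch_success: float
    n_hatched: int
    n_eggs: int
    covariate: str = "atu"
    method: str = "glm"  # "glm" | "midpoint"
    flags: tuple[str, ...] = ()

    def predicted_proportion(self, x) -> np.ndarray:
        """Fitted cumulative hatch proportion at covariate value(s) ``x``."""
        if self.slope is None or self.intercept is None:
            raise HatchEstimationError(f"{self.tube_id}: degenerate fit has no curve")
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * np.asarray(x, float))))


def _cumulative_atu_at_day_end(series, fert_date, day_offsets, atu_floor_c=0.0):
    """ATU through the end of each observation day (day k ends at k+1 DPF)."""
    n = int(np.max(day_offsets)) + 1
    temps = np.maximum(series.window(fert_date, n), atu_floor_c)
    cum = np.cumsum(temps)
    return cum[np.asarray(day_offsets, dtype=int)]


def _invert_atu(series, fert_date, target_atu, atu_floor_c=0.0) -> float:
    """Fractional DPF at which cumulative ATU reaches ``target_atu``."""
    n = series.max_span_days(fert_date)
    temps = np.maximum(series.window(fert_date, n), atu_floor_c)
    cum = np.cumsum(temps)
    idx = int(np.searchsorted(cum, target_atu))
    if idx >= len(cum):
        raise HatchEstimationError("temperature series ends before target ATU")
    prev = cum[idx - 1] if idx > 0 else 0.0
    if temps[idx] <= 0:
        return float(idx)
    return float(idx + (target_atu - prev) / temps[idx])


def fit_hatch_logistic(
    tube: TubeRecord,
    series: TemperatureSeries,
    covariate: str = "atu",
    atu_floor_c: float = 0.0,
) -> HatchTimingEstimate:
    """Logistic estimate of ATU/DPF at 50% and 90% hatch for one tube.

    Daily cumulative proportions hatched (denominator = eggs that eventually
    hatched) are treated as independent binomial observations of a logistic
    curve in cumulative ATU (or DPF when ``covariate="dpf"``).  If every egg
    hatches on a single day the curve is unidentified and the estimate falls
    back to the midpoint between the last all-unhatched and the hatch day
    (flagged ``single_day``); a tube with zero hatch has no estimate and
    raises :class:`HatchEstimationError`.
    """
    if covariate not in ("atu", "dpf"):
        raise ValueError("covariate must be 'atu' or 'dpf'")
    total = tube.n_hatched
    if total == 0:
        raise HatchEstimationError(f"{tube.tube_id}: no eggs hatched; estimate undefined")

    obs = tube.obs
    day_off = (obs["obs_date"] - pd.Timestamp(tube.fert_date)).dt.days.to_numpy()
    if (day_off < 0).any():
        raise ValueError(f"{tube.tube_id}: observation before fertilization date")
    cum_hatched = obs["n_hatched_new"].cumsum().to_numpy()
    atu_end = _cumulative_atu_at_day_end(series, tube.fert_date, day_off, atu_floor_c)
    x = atu_end if covariate == "atu" else day_off + 1.0

    hatch_days = np.flatnonzero(obs["n_hatched_new"].to_numpy() > 0)
    flags: list[str] = []
    partial = (cum_hatched > 0) & (cum_hatched < total)

    if len(hatch_days) >= 2 and partial.any():
        endog = np.column_stack([cum_hatched, total - cum_hatched])
        model = sm.GLM(endog, sm.add_constant(x), family=sm.families.Binomial())
        try:
            res = model.fit()
            intercept, slope = float(res.params[0]), float(res.params[1])
        except Exception:  # perfect separation despite partial days
            res = None
        if res is not None and np.isfinite(slope) and slope > 0 and abs(slope) < 1e4:
            atu50_x = -intercept / slope
            atu90_x = (LOGIT_90 - intercept) / slope
            method = "glm"
        else:
            res = None
        if res is None:
            flags.append("separation_fallback")
            atu50_x, atu90_x = _midpoint_rule(x, cum_hatched, total)
            slope = intercept = None
            method = "midpoint"
    else:
        flags.append("single_day")
        atu50_x, atu90_x = _midpoint_rule(x, cum_hatched, total)
        slope = intercept = None
        method = "midpoint"
        logger.info("%s: all hatch on one day; midpoint rule applied", tube.tube_id)

    if covariate == "atu":
        atu50, atu90 = atu50_x, atu90_x
        dpf50 = _invert_atu(series, tube.fert_date, atu50, atu_floor_c)
    else:
        dpf50 = atu50_x
        atu50 = atu_between(series, tube.fert_date, atu50_x, atu_floor_c)
        atu90 = atu_between(series, tube.fert_date, atu90_x, atu_floor_c)

    return HatchTimingEstimate(
        tube_id=tube.tube_id,
        family_id=tube.family_id,
        treatment=tube.treatment,
        fert_date=tube.fert_date,
        atu50=float(atu50),
        atu90=float(atu90),
        dpf50=float(dpf50),
        slope=slope,
        intercept=intercept,
        hatch_success=tube.hatch_success,
        n_hatched=total,
        n_eggs=tube.n_eggs,
        covariate=covariate,
        method=method,
        flags=tuple(flags),
    )


def _midpoint_rule(x: np.ndarray, cum_hatched: np.ndarray, total: int):
    """Midpoint between the last all-unhatched and the first ≥50%/≥90% point."""
    def crossing(q: float) -> float:
        below = np.flatnonzero(cum_hatched < q * total)
        above = np.flatnonzero(cum_hatched >= q * total)
        lo = x[below[-1]] if len(below) else x[0]
        hi = x[above[0]]
        return 0.5 * (lo + hi)

    return crossing(0.5), crossing(0.9)


def fit_all_tubes(
    dataset: HatchDataset, covariate: str = "atu", atu_floor_c: float = 0.0
) -> tuple[list[HatchTimingEstimate], list[tuple[str, str]]]:
    """Fit every tube; returns (estimates, [(tube_id, reason) for skipped])."""
    estimates, skipped = [], []
    for tube in dataset.records:
        try:
            estimates.append(
                fit_hatch_logistic(tube, dataset.series_for(tube), covariate, atu_floor_c)
            )
        except HatchEstimationError as exc:
            logger.warning("skipping %s: %s", tube.tube_id, exc)
            skipped.append((tube.tube_id, str(exc)))
    return estimates, skipped


def exclude_low_success(
    dataset: HatchDataset, min_success: float = 0.15
) -> HatchDataset:
    """Drop maternal families whose every tube hatched below ``min_success``.

    Mirrors the pre-analysis exclusion of near-total hatch failure; removals
    are logged.  Raises if nothing survives.
    """
    by_family: dict[str, list[float]] = {}
    for t in dataset.records:
        by_family.setdefault(t.family_id, []).append(t.hatch_success)
    removed = {
        fam for fam, succ in by_family.items() if all(s < min_success for s in succ)
    }
    for fam in sorted(removed):
        logger.info(
            "excluding family %s: hatch success %s all < %.2f",
            fam, [round(s, 3) for s in by_family[fam]], min_success,
        )
    kept = [t for t in dataset.records if t.family_id not in removed]
    if not kept:
        raise HatchEstimationError("all families removed by low-success filter")
    return HatchDataset(records=kept, regimes=dataset.regimes)


def estimates_to_frame(estimates: list[HatchTimingEstimate]) -> pd.DataFrame:
    """One row per tube, ready for the repeatability/mixed-model analyses."""
    return pd.DataFrame(
        [
            {
                "tube_id": e.tube_id,
                "family_id": e.family_id,
                "treatment": e.treatment,
                "fert_date": e.fert_date.isoformat(),
                "atu50": e.atu50,
                "atu90": e.atu90,
                "dpf50": e.dpf50,
                "hatch_success": e.hatch_success,
                "method": e.method,
            }
            for e in estimates
        ]
    )
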