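"""Repeatability and model-evaluation statistics.

Three pieces of machinery:

* a one-way random-effects ANOVA intraclass correlation (ICC) with an F-based
  95% interval, quantifying how repeatable ATU-at-hatch is across replicate
  tubes within maternal families;
* random-intercept linear mixed models (REML via statsmodels) with a
  likelihood-ratio test for the family intercept and Satterthwaite-type
  denominator degrees of freedom for the fixed effects;
* paired t-tests of observed versus model-predicted ATU at hatch across
  treatment × fertilization-date cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .models import ClampPolicy, DevelopmentModel, accumulate
from .series import TemperatureSeries

__all__ = [
    "RepeatabilityResult",
    "MixedModelResult",
    "ModelEvaluation",
    "icc_oneway",
    "fit_family_model",
    "fit_treatment_model",
    "collapse_replicates",
    "evaluate_models",
    "paired_t",
]


class EvaluationError(RuntimeError):
    """A model evaluation could not be completed (e.g. unresolved event)."""


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    n_groups: int
    mean_group_size: float
    msb: float
    msw: float
    f_stat: float
    alpha: float = 0.05


def icc_oneway(values, groups, alpha: float = 0.05) -> RepeatabilityResult:
    """One-way random-effects ANOVA ICC with an F-distribution interval.

    ``ICC = (MSB − MSW) / (MSB + (k0 − 1)·MSW)`` where ``k0`` is the
    unbalanced-design average group size ``(N − Σn_i²/N)/(k − 1)``.  The
    confidence interval follows Searle's F bounds.  A slightly negative point
    estimate (no group effect) is reported as computed.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    n = len(values)
    if k < 2:
        raise ValueError("ICC requires at least two groups")
    sizes = np.bincount(inverse)
    if n - k == 0:
        raise ValueError("ICC requires at least one group with >= 2 observations")
    group_means = np.bincount(inverse, weights=values) / sizes
    grand = values.mean()
    ssb = float(np.sum(sizes * (group_means - grand) ** 2))
    ssw = float(np.sum((values - group_means[inverse]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    k0 = (n - np.sum(sizes**2) / n) / (k - 1)
    if msw == 0.0:  # zero within-group variance: perfect repeatability
        icc, f, ci_low, ci_high = 1.0, float("inf"), 1.0, 1.0
    else:
        icc = (msb - msw) / (msb + (k0 - 1) * msw)
        f = msb / msw
        f_low = f / scipy.stats.f.ppf(1 - alpha / 2, k - 1, n - k)
        f_up = f * scipy.stats.f.ppf(1 - alpha / 2, n - k, k - 1)
        ci_low = (f_low - 1) / (f_low + k0 - 1)
        ci_high = (f_up - 1) / (f_up + k0 - 1)
    return RepeatabilityResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_groups=k,
        mean_group_size=float(n / k),
        msb=msb,
        msw=msw,
        f_stat=float(f),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Random-intercept mixed models
# ---------------------------------------------------------------------------

@dataclass
class FixedEffectTest:
    term: str
    f_stat: float
    df_num: int
    df_den: float
    p_value: float
    method: str = "satterthwaite"


@dataclass
class MixedModelResult:
    formula: str
    fixed_effects: dict[str, float]
    random_intercept_variance: float
    residual_variance: float
    lrt_chi2: float
    lrt_p: float
    lrt_p_halved: float  # boundary-corrected (χ²₀:χ²₁ mixture) p-value
    fixed_tests: dict[str, FixedEffectTest]
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool


def _reml_pieces(theta, y, X, group_idx):
    """REML log-likelihood, beta-hat and (X'V⁻¹X)⁻¹ for a random-intercept model.

    ``theta = (sigma_b2, sigma_e2)``; per-group inverses use the rank-one
    Woodbury identity so no dense V is formed.
    """
    sb2, se2 = theta
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    logdet_v = 0.0
    for idx in group_idx:
        ni = len(idx)
        Xi, yi = X[idx], y[idx]
        w = sb2 / (se2 * (se2 + ni * sb2))
        xs, ys = Xi.sum(axis=0), yi.sum()
        XtViX += Xi.T @ Xi / se2 - w * np.outer(xs, xs)
        XtViy += Xi.T @ yi / se2 - w * xs * ys
        logdet_v += (ni - 1) * np.log(se2) + np.log(se2 + ni * sb2)
    C = np.linalg.inv(XtViX)
    beta = C @ XtViy
    quad = 0.0
    for idx in group_idx:
        ri = y[idx] - X[idx] @ beta
        w = sb2 / (se2 * (se2 + len(idx) * sb2))
        quad += ri @ ri / se2 - w * ri.sum() ** 2
    n = len(y)
    sign, logdet_c = np.linalg.slogdet(XtViX)
    ll = -0.5 * (logdet_v + logdet_c + quad + (n - p) * np.log(2 * np.pi))
    return ll, beta, C


def _satterthwaite_df(contrast, theta, y, X, group_idx, cov_theta):
    """Satterthwaite df for one fixed-effect contrast: 2f²/(∇f'A∇f)."""
    def f(th):
        _, _, C = _reml_pieces(th, y, X, group_idx)
        return float(contrast @ C @ contrast)

    grad = np.zeros(2)
    for j in range(2):
        h = max(abs(theta[j]), 1e-8) * 1e-4
        tp, tm = np.array(theta, float), np.array(theta, float)
        tp[j] += h
        tm[j] = max(tm[j] - h, 0.0)
        grad[j] = (f(tp) - f(tm)) / (tp[j] - tm[j])
    denom = float(grad @ cov_theta @ grad)
    f0 = f(theta)
    if denom <= 0 or f0 <= 0:
        return np.inf
    return 2.0 * f0**2 / denom


def _reml_hessian(theta, y, X, group_idx):
    """Finite-difference Hessian of the REML log-likelihood in theta."""
    def ll(th):
        return _reml_pieces(th, y, X, group_idx)[0]

    h = np.array([max(abs(t), 1e-8) * 1e-3 for t in theta])
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ti, tj = h[i], h[j]
            pp = theta + np.array([ti if k == i else 0 for k in range(2)]) \
                       + np.array([tj if k == j else 0 for k in range(2)])
            pm = theta + np.array([ti if k == i else 0 for k in range(2)]) \
                       - np.array([tj if k == j else 0 for k in range(2)])
            mp = theta - np.array([ti if k == i else 0 for k in range(2)]) \
                       + np.array([tj if k == j else 0 for k in range(2)])
            mm = theta - np.array([ti if k == i else 0 for k in range(2)]) \
                       - np.array([tj if k == j else 0 for k in range(2)])
            mm = np.maximum(mm, 0.0)
            pm = np.maximum(pm, 0.0)
            mp = np.maximum(mp, 0.0)
            H[i, j] = H[j, i] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * ti * tj)
    return H


def _robust_lmm_fit(md, reml: bool):
    """MixedLM fit with optimizer fallbacks (singular fits can break a solver).

    Returns the first converged fit, or the first successful one if no
    optimizer converges.
    """
    first = None
    last_exc = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            res = md.fit(reml=reml, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if res.converged:
            return res
        if first is None:
            first = res
    if first is not None:
        return first
    raise last_exc


def _fit_mixed(df: pd.DataFrame, response: str, fixed: str, group_col: str) -> MixedModelResult:
    formula = f"{response} ~ {fixed}"
    md = smf.mixedlm(formula, data=df, groups=df[group_col])
    res = _robust_lmm_fit(md, reml=True)
    sigma_b2 = float(np.squeeze(res.cov_re.to_numpy()))
    sigma_e2 = float(res.scale)
    var_y = float(np.var(df[response].to_numpy()))
    singular = sigma_b2 < 1e-8 * max(var_y, 1.0)

    # likelihood-ratio test for the random intercept (ML fits, 1 df)
    res_ml = _robust_lmm_fit(md, reml=False)
    ols = smf.ols(formula, data=df).fit()
    lrt = max(0.0, 2.0 * (res_ml.llf - ols.llf))
    if singular:
        lrt = 0.0
    lrt_p = float(scipy.stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    lrt_p_halved = lrt_p / 2.0 if lrt > 0 else 1.0

    # design pieces for the Satterthwaite machinery
    y = np.asarray(md.endog, dtype=float)
    X = np.asarray(md.exog, dtype=float)
    labels = pd.Series(df[group_col].to_numpy())
    group_idx = [np.flatnonzero((labels == g).to_numpy()) for g in labels.unique()]
    theta = np.array([sigma_b2, sigma_e2])
    _, beta, C = _reml_pieces(np.maximum(theta, [0.0, 1e-12]), y, X, group_idx)

    n, p = X.shape
    design_info = md.data.design_info
    fixed_tests: dict[str, FixedEffectTest] = {}
    if singular:
        cov_theta = None
    else:
        H = _reml_hessian(theta, y, X, group_idx)
        try:
            cov_theta = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov_theta = None

    for term, slc in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        cols = np.arange(p)[slc]
        q = len(cols)
        L = np.zeros((q, p))
        L[np.arange(q), cols] = 1.0
        M = L @ C @ L.T
        Lb = L @ beta
        f_stat = float(Lb @ np.linalg.solve(M, Lb)) / q
        if cov_theta is None:
            df_den, method = float(n - p), "residual"
        else:
            # per-eigencontrast Satterthwaite dfs pooled via 2E/(E - q)
            eigval, eigvec = np.linalg.eigh(M)
            nus = []
            for i in range(q):
                if eigval[i] <= 0:
                    continue
                li = eigvec[:, i] @ L
                nus.append(_satterthwaite_df(li, theta, y, X, group_idx, cov_theta))
            nus = [v for v in nus if np.isfinite(v) and v > 2]
            if len(nus) == q:
                E = sum(v / (v - 2) for v in nus)
                df_den = 2 * E / (E - q) if E > q else float(n - p)
                method = "satterthwaite"
            else:
                df_den, method = float(n - p), "residual"
        p_val = float(scipy.stats.f.sf(f_stat, q, df_den))
        fixed_tests[term] = FixedEffectTest(term, f_stat, q, df_den, p_val, method)

    return MixedModelResult(
        formula=formula,
        fixed_effects={k: float(v) for k, v in res.fe_params.items()},
        random_intercept_variance=max(sigma_b2, 0.0),
        residual_variance=sigma_e2,
        lrt_chi2=float(lrt),
        lrt_p=lrt_p,
        lrt_p_halved=lrt_p_halved,
        fixed_tests=fixed_tests,
        n_obs=n,
        n_groups=len(group_idx),
        converged=bool(res.converged),
        singular=singular,
    )


def fit_family_model(
    estimates: pd.DataFrame,
    response: str = "atu50",
    date_col: str = "fert_date",
    family_col: str = "family_id",
) -> MixedModelResult:
    """Repeatability-among-families model on constant-treatment replicates.

    ``response ~ fertilization date (fixed) + family (random intercept)``; a
    significant family intercept marks hatch-timing differences among families
    fertilized on the same day.
    """
    return _fit_mixed(estimates, response, f"C({date_col})", family_col)


def collapse_replicates(
    estimates: pd.DataFrame,
    treatment: str = "A",
    response: str = "atu50",
    treatment_col: str = "treatment",
    family_col: str = "family_id",
    date_col: str = "fert_date",
) -> pd.DataFrame:
    """Average replicate tubes of one treatment to one value per family."""
    df = estimates.copy()
    mask = df[treatment_col] == treatment
    rep = (
        df[mask]
        .groupby([family_col, date_col, treatment_col], as_index=False)[response]
        .mean()
    )
    other = df[~mask][[family_col, date_col, treatment_col, response]]
    return pd.concat([rep, other], ignore_index=True)


def fit_treatment_model(
    estimates: pd.DataFrame,
    response: str = "atu50",
    treatment_col: str = "treatment",
    date_col: str = "fert_date",
    family_col: str = "family_id",
    pre_average: str | None = "A",
) -> MixedModelResult:
    """Thermal-regime model: treatment × fertilization date fixed, family random.

    Replicate tubes of ``pre_average`` (the constant treatment) are first
    collapsed to one value per family so every family contributes one
    observation per treatment.
    """
    df = estimates
    if pre_average is not None:
        df = collapse_replicates(
            estimates, pre_average, response, treatment_col, family_col, date_col
        )
    fixed = f"C({treatment_col}) * C({date_col})"
    return _fit_mixed(df, response, fixed, family_col)


# ---------------------------------------------------------------------------
# Observed vs predicted model evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedT:
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    sd_diff: float


def paired_t(diffs) -> PairedT:
    """Two-sided paired t-test on a vector of differences (df = n − 1).

    Zero variance across pairs leaves t undefined; it is reported as NaN.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedT(float("nan"), n - 1, float("nan"), mean, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 1))
    return PairedT(float(t), n - 1, p, mean, sd)


@dataclass
class ModelEvaluation:
    model: str
    event: str
    mode: str
    n_pairs: int
    observed_atu: np.ndarray = field(repr=False)
    predicted_atu: np.ndarray = field(repr=False)
    observed_dpf: np.ndarray | None = field(repr=False, default=None)
    predicted_dpf: np.ndarray | None = field(repr=False, default=None)
    mean_difference: float = float("nan")  # predicted − observed; negative = under-estimate
    t_stat: float = float("nan")
    df: int = 0
    p_value: float = float("nan")

    @property
    def mean_abs_dpf_difference(self) -> float:
        return float(np.mean(np.abs(self.predicted_dpf - self.observed_dpf)))

    @property
    def mean_dpf_difference(self) -> float:
        """Predicted-minus-observed average hatch timing, in days."""
        return float(np.mean(self.predicted_dpf) - np.mean(self.observed_dpf))


def evaluate_models(
    observed: pd.DataFrame,
    models: Sequence[DevelopmentModel],
    regimes: Mapping | None = None,
    mode: str = "closed_form",
    clamp: ClampPolicy = ClampPolicy(),
) -> dict[str, ModelEvaluation]:
    """Observed-vs-predicted ATU at hatch, paired by treatment × fertilization date.

    ``observed`` needs columns ``treatment``, ``fert_date``, ``mean_temp_c``,
    ``atu50``, ``dpf50`` (and ``atu90``/``dpf90`` for the Kane model, which
    predicts 90% hatch).  Two prediction modes:

    * ``"closed_form"`` — each model's days-to-event closed form is evaluated
      at the cell's mean incubation temperature; predicted ATU is
      ``D(T̄)·T̄``.  This mirrors the laboratory evaluation the printed
      treatment means support.
    * ``"profile"`` — rate-summation accumulation over a daily
      :class:`TemperatureSeries` per cell, supplied in ``regimes`` keyed by
      ``(treatment, fert_date)``.  An unresolved event aborts the evaluation
      (no pair is silently dropped).
    """
    if mode not in ("closed_form", "profile"):
        raise ValueError("mode must be 'closed_form' or 'profile'")
    if mode == "profile" and regimes is None:
        raise ValueError("profile mode requires regimes")
    required = {"treatment", "fert_date", "mean_temp_c", "atu50", "dpf50"}
    missing = required - set(observed.columns)
    if missing:
        raise ValueError(f"observed table missing column(s) {sorted(missing)}")

    out: dict[str, ModelEvaluation] = {}
    for model in models:
        event = model.primary_event
        obs_col = "atu90" if event == "hatch90" else "atu50"
        dpf_col = "dpf90" if event == "hatch90" else "dpf50"
        if obs_col not in observed.columns:
            raise EvaluationError(
                f"model {model.name!r} predicts {event}; observed table lacks "
                f"column {obs_col!r}"
            )
        pred_atu, pred_dpf = [], []
        for _, row in observed.iterrows():
            if mode == "closed_form":
                t_bar = float(row["mean_temp_c"])
                d = model.days_to_event(max(t_bar, clamp.rate_floor_c), event)
                pred_dpf.append(d)
                pred_atu.append(d * max(t_bar, clamp.atu_floor_c))
            else:
                fert = pd.Timestamp(row["fert_date"]).date()
                series = regimes[(row["treatment"], fert)]
                traj = accumulate(series, model, fert, events=[event], clamp=clamp)
                ev = traj.event(event)
                if not ev.resolved:
                    raise EvaluationError(
                        f"{model.name}: event {event!r} unresolved for pair "
                        f"({row['treatment']}, {fert}) — evaluation refused"
                    )
                pred_dpf.append(ev.dpf_at_event)
                pred_atu.append(ev.atu_at_event)
        obs_atu = observed[obs_col].to_numpy(dtype=float)
        obs_dpf = (
            observed[dpf_col].to_numpy(dtype=float)
            if dpf_col in observed.columns
            else None
        )
        diffs = np.asarray(pred_atu) - obs_atu
        tt = paired_t(diffs)
        out[model.name] = ModelEvaluation(
            model=model.name,
            event=event,
            mode=mode,
            n_pairs=len(diffs),
            observed_atu=obs_atu,
            predicted_atu=np.asarray(pred_atu),
            observed_dpf=obs_dpf,
            predicted_dpf=np.asarray(pred_dpf),
            mean_difference=tt.mean_diff,
            t_stat=tt.t_stat,
            df=tt.df,
            p_value=tt.p_value,
        )
    return out
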