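"""Kaplan–Meier estimation, log-rank testing and Cox proportional hazards.

Time is measured in months throughout; "5-year" survival is the
product-limit estimate evaluated at exactly 60 months (right-continuous).

The Kaplan–Meier estimator and the k-group log-rank statistic are computed
directly (the log-rank statistic is also the inner loop of the optimal
cut-point scan, which needs a vectorizable form); Cox regression and the
Schoenfeld proportional-hazards diagnostic delegate to lifelines, and VIF
to statsmodels.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor


# --------------------------------------------------------------------------
# Kaplan–Meier


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve over the distinct observed times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S(0) = 1.
    ``greenwood_se`` is the Greenwood standard error of S at each step.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )


def _check_endpoints(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("no subjects")
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValueError("survival times must be finite and >= 0")
    return time, event


def km_fit(time, event) -> KMCurve:
    """Kaplan–Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored-only times appear in the grid with ``events == 0`` (they change
    the at-risk count only). Greenwood's formula supplies the standard error.
    """
    time, event = _check_endpoints(time, event)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    grid, first = np.unique(t_sorted, return_index=True)
    n = time.size
    # at risk just before each distinct time
    at_risk = n - first
    d = np.zeros(grid.size, dtype=int)
    np.add.at(d, np.searchsorted(grid, t_sorted[e_sorted]), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        gw = surv * np.sqrt(np.cumsum(gw_terms))
    gw[np.isnan(gw)] = 0.0
    return KMCurve(
        event_times=grid,
        at_risk=at_risk.astype(int),
        events=d,
        survival=surv,
        greenwood_se=gw,
        n_subjects=n,
    )


def km_survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step evaluation of S at time ``t`` (months)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


# --------------------------------------------------------------------------
# Log-rank


@dataclasses.dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    groups: np.ndarray


def logrank_test(time, event, groups) -> LogRankResult:
    """k-group log-rank test: O - E with hypergeometric variance at each
    distinct event time, chi-square on k - 1 degrees of freedom."""
    time, event = _check_endpoints(time, event)
    groups = np.asarray(groups)
    if groups.shape != time.shape:
        raise ValueError("groups must match subjects")
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if not event.any():
        raise ValueError("log-rank needs >= 1 event")
    chi2, df, O, E = _logrank_chi2(time, event, gidx, k)
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2=float(chi2), df=df, p=p, observed=O, expected=E, groups=labels)


def _logrank_chi2(time, event, gidx, k):
    """Core O-E statistic; gidx are integer group codes 0..k-1."""
    ev_times = np.unique(time[event])
    m = ev_times.size
    # n_jt: at risk per group at each event time; d_jt: events per group
    ge_mask = time[None, :] >= ev_times[:, None]              # m × n
    onehot = np.eye(k, dtype=float)[gidx]                      # n × k
    n_jt = ge_mask @ onehot                                    # m × k
    at_event = (time[None, :] == ev_times[:, None]) & event[None, :]
    d_jt = at_event @ onehot                                   # m × k
    n_t = n_jt.sum(axis=1)
    d_t = d_jt.sum(axis=1)
    O = d_jt.sum(axis=0)
    E = (d_t[:, None] * n_jt / n_t[:, None]).sum(axis=0)
    # hypergeometric covariance, groups 0..k-2
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    p_jt = n_jt / n_t[:, None]
    V = -np.einsum("t,tj,tl->jl", scale, p_jt, p_jt)
    V[np.diag_indices(k)] += scale @ p_jt
    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    return max(chi2, 0.0), k - 1, O, E


def logrank_2group_scan(time, event, x, thresholds) -> np.ndarray:
    """Two-group log-rank p for every split ``x >= c``, vectorized over
    candidate thresholds ``c``. Used by the optimal cut-point search."""
    time, event = _check_endpoints(time, event)
    x = np.asarray(x, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    ev_times = np.unique(time[event])
    ge_mask = time[None, :] >= ev_times[:, None]                   # m × n
    at_event = (time[None, :] == ev_times[:, None]) & event[None, :]
    high = x[None, :] >= thresholds[:, None]                       # c × n
    n_t = ge_mask.sum(axis=1).astype(float)                        # m
    d_t = at_event.sum(axis=1).astype(float)                       # m
    n1 = ge_mask @ high.T.astype(float)                            # m × c
    d1 = at_event @ high.T.astype(float)                           # m × c
    E1 = d_t[:, None] * n1 / n_t[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
        V1 = scale[:, None] * (n1 / n_t[:, None]) * (1.0 - n1 / n_t[:, None])
    z = (d1 - E1).sum(axis=0)
    v = V1.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(v > 0, z * z / v, 0.0)
    return stats.chi2.sf(chi2, 1)


# --------------------------------------------------------------------------
# Cox regression and diagnostics


@dataclasses.dataclass
class CoxResult:
    """Per-covariate summary of a proportional-hazards fit (Efron ties)."""

    summary: pd.DataFrame  # coefficient, hr, ci_lower, ci_upper, p per covariate
    log_likelihood: float
    ties: str
    fitter: CoxPHFitter

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coefficient"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hr"]


def cox_fit(covariates: pd.DataFrame, time, event) -> CoxResult:
    """Cox proportional-hazards fit by partial likelihood (Efron ties).

    ``covariates`` is subjects × p with named columns; constant columns are
    rejected, and fewer events than covariates triggers a warning.
    """
    time, event = _check_endpoints(time, event)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if cov.shape[0] != time.size:
        raise ValueError("covariates and endpoints must have the same length")
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    if event.sum() < cov.shape[1]:
        warnings.warn(
            f"only {int(event.sum())} events for {cov.shape[1]} covariates",
            RuntimeWarning,
        )
    df = cov.copy()
    df["_time"] = time
    df["_event"] = event.astype(int)
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="_time", event_col="_event")
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "coefficient": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxResult(
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        ties="efron",
        fitter=fitter,
    )


def vif(covariates: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R_j^2)."""
    cov = pd.DataFrame(covariates)
    if cov.shape[1] < 2:
        raise ValueError("vif needs >= 2 covariates")
    if cov.shape[0] < cov.shape[1] + 2:
        raise ValueError("vif needs >= p + 2 subjects")
    X = np.column_stack([np.ones(cov.shape[0]), cov.to_numpy(dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = [variance_inflation_factor(X, j + 1) for j in range(cov.shape[1])]
    return pd.Series(vals, index=cov.columns, name="vif")


def schoenfeld_test(
    fit: CoxResult, covariates: pd.DataFrame, time, event
) -> pd.Series:
    """Per-covariate p-value for proportional-hazards violation.

    Correlates scaled Schoenfeld residuals with Kaplan–Meier-transformed
    event time (the cox.zph convention), via lifelines.
    """
    time, event = _check_endpoints(time, event)
    if not event.any():
        raise ValueError("schoenfeld test needs >= 1 event")
    df = pd.DataFrame(covariates).reset_index(drop=True)
    df["_time"] = time
    df["_event"] = event.astype(int)
    res = proportional_hazard_test(fit.fitter, df, time_transform="km")
    pvals = res.summary["p"]
    if isinstance(pvals.index, pd.MultiIndex):
        pvals = pvals.droplevel(-1)
    pvals = pvals[~pvals.index.duplicated()]
    return pd.Series(pvals, name="p_ph")
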