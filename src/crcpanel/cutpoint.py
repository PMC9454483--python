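"""Outcome-based optimal cut-points and the three-gene count risk score.

A gene is dichotomized at the expression threshold whose two-arm split
minimizes the log-rank p-value over all admissible splits ("minimal-p"
dichotomization). Candidate thresholds are the midpoints between
consecutive distinct expression values whose split leaves both arms at
least a configured fraction of the cohort. The minimal-p choice is
anti-conservative under the null; no multiplicity correction is applied,
and the inflation is documented rather than corrected (see the methods
note and the null-inflation tests).

The prognostic score counts genes in their high-risk expression state.
Default thresholds and directions, in normalized log2 units:
ADH1B (NM_001286650) >= 4.39 is high risk; BST2 < 10.34 is high risk;
FER1L4 < 4.73 is high risk. The score is min(count, 2), yielding low (0),
intermediate (1) and high (2) risk groups.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .survival import (
    KMCurve,
    LogRankResult,
    _check_endpoints,
    km_fit,
    km_survival_at,
    logrank_2group_scan,
    logrank_test,
)

HIGH_IF_GE = ">="
HIGH_IF_LT = "<"


@dataclasses.dataclass
class CutpointResult:
    """Outcome of the minimal-p threshold search for one gene."""

    gene: str
    candidates: np.ndarray
    p_per_candidate: np.ndarray
    chosen: float
    p_chosen: float
    arm_sizes: tuple[int, int]  # (below, at-or-above) at the chosen threshold
    direction: str              # which side is high risk (">=" or "<")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"candidate": self.candidates, "logrank_p": self.p_per_candidate}
        )


class OptimalCutpointFinder(BaseEstimator):
    """Minimal-p survival dichotomization of a single continuous marker.

    ``fit(x, y)`` takes per-patient marker values ``x`` and survival
    endpoints ``y`` (an (n, 2) array-like of time, event). Fitted
    attributes: ``threshold_``, ``pvalue_``, ``candidates_``, ``pvalues_``,
    ``direction_`` (which side of the threshold carries the higher hazard)
    and ``arm_sizes_``.

    Parameters
    ----------
    min_arm_fraction : float
        Each arm of an admissible split must hold at least this fraction of
        the cohort (default 0.10).
    """

    def __init__(self, min_arm_fraction: float = 0.10):
        self.min_arm_fraction = min_arm_fraction

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of (time, event)")
        time, event = _check_endpoints(y[:, 0], y[:, 1].astype(bool))
        n = x.size
        if n != time.size:
            raise ValueError("x and y must have the same length")
        if not (0 < self.min_arm_fraction < 0.5):
            raise ValueError("min_arm_fraction must lie in (0, 0.5)")
        if n < 2.0 / self.min_arm_fraction:
            raise ValueError(
                f"need >= {int(np.ceil(2.0 / self.min_arm_fraction))} patients"
            )
        if not event.any():
            raise ValueError("cut-point search needs >= 1 event")
        if not np.all(np.isfinite(x)):
            raise ValueError("marker values must be finite")
        distinct = np.unique(x)
        if distinct.size < 2:
            raise ValueError("no admissible split: marker is constant")
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        min_arm = self.min_arm_fraction * n
        n_high = (x[None, :] >= mids[:, None]).sum(axis=1)
        admissible = (n_high >= min_arm) & ((n - n_high) >= min_arm)
        if not admissible.any():
            raise ValueError(
                "no candidate split satisfies the minimum arm size "
                f"({min_arm:.1f} patients per arm)"
            )
        candidates = mids[admissible]
        pvals = logrank_2group_scan(time, event, x, candidates)
        best = int(np.argmin(pvals))  # argmin takes the first = smaller threshold on ties
        chosen = float(candidates[best])
        high = x >= chosen
        # direction: the arm with the higher event rate per unit follow-up
        # (two-arm hazard contrast) is the high-risk side
        rate_high = event[high].sum() / max(time[high].sum(), 1e-300)
        rate_low = event[~high].sum() / max(time[~high].sum(), 1e-300)
        self.threshold_ = chosen
        self.pvalue_ = float(pvals[best])
        self.candidates_ = candidates
        self.pvalues_ = pvals
        self.direction_ = HIGH_IF_GE if rate_high >= rate_low else HIGH_IF_LT
        self.arm_sizes_ = (int((~high).sum()), int(high.sum()))
        return self

    def predict(self, x) -> np.ndarray:
        """High-risk indicator for new marker values under the fitted split."""
        check_is_fitted(self, "threshold_")
        x = np.asarray(x, dtype=float)
        at_or_above = x >= self.threshold_
        return at_or_above if self.direction_ == HIGH_IF_GE else ~at_or_above


def optimal_cutpoint(
    expr, time, event, min_arm_fraction: float = 0.10, gene: str = ""
) -> CutpointResult:
    """Minimal-p log-rank threshold for one gene's expression values."""
    est = OptimalCutpointFinder(min_arm_fraction=min_arm_fraction)
    y = np.column_stack([np.asarray(time, float), np.asarray(event, float)])
    est.fit(expr, y)
    return CutpointResult(
        gene=gene,
        candidates=est.candidates_,
        p_per_candidate=est.pvalues_,
        chosen=est.threshold_,
        p_chosen=est.pvalue_,
        arm_sizes=est.arm_sizes_,
        direction=est.direction_,
    )


# --------------------------------------------------------------------------
# The three-gene count score


@dataclasses.dataclass(frozen=True)
class GeneRule:
    """One gene's high-risk rule: threshold and which side is high risk."""

    gene: str
    transcript_id: str
    threshold: float
    high_risk_side: str  # ">=" or "<"

    def is_high_risk(self, value) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        if self.high_risk_side == HIGH_IF_GE:
            return value >= self.threshold
        if self.high_risk_side == HIGH_IF_LT:
            return value < self.threshold
        raise ValueError(f"high_risk_side must be '>=' or '<', got {self.high_risk_side!r}")


@dataclasses.dataclass(frozen=True)
class ScoreConfig:
    """The three-gene rule set for the prognostic score."""

    rules: tuple[GeneRule, ...]

    def __post_init__(self):
        if len(self.rules) != 3:
            raise ValueError("the prognostic score uses exactly three genes")
        for r in self.rules:
            if not np.isfinite(r.threshold):
                raise ValueError(f"threshold for {r.gene} must be finite")

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.rules]

    @property
    def transcript_ids(self) -> list[str]:
        return [r.transcript_id for r in self.rules]

    def to_dict(self) -> list[dict]:
        return [dataclasses.asdict(r) for r in self.rules]

    @classmethod
    def from_dict(cls, rules: list[dict]) -> "ScoreConfig":
        return cls(rules=tuple(GeneRule(**r) for r in rules))


#: Default rules: high ADH1B (NM_001286650), low BST2, low FER1L4 are the
#: high-risk states, at thresholds 4.39 / 10.34 / 4.73 log2 units.
DEFAULT_SCORE_CONFIG = ScoreConfig(
    rules=(
        GeneRule("ADH1B", "NM_001286650", 4.39, HIGH_IF_GE),
        GeneRule("BST2", "NM_004335", 10.34, HIGH_IF_LT),
        GeneRule("FER1L4", "NR_119376", 4.73, HIGH_IF_LT),
    )
)


class CountRiskScorer(TransformerMixin, BaseEstimator):
    """Count-of-high-risk-genes score, truncated to {0, 1, 2}.

    ``transform(X)`` on an (n, 3) array of per-patient expression values
    (columns in config order) returns the high-risk count k in 0..3;
    ``predict(X)`` returns the score min(k, 2).
    """

    def __init__(self, config: ScoreConfig = DEFAULT_SCORE_CONFIG):
        self.config = config

    def fit(self, X=None, y=None):
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_patients, 3) in config gene order")
        if np.any(~np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"missing value for patient index {i}, gene {self.config.genes[j]}"
            )
        flags = np.column_stack(
            [rule.is_high_risk(X[:, j]) for j, rule in enumerate(self.config.rules)]
        )
        return flags.sum(axis=1)

    def predict(self, X) -> np.ndarray:
        return np.minimum(self.transform(X), 2)


def apply_score(
    expr3, config: ScoreConfig = DEFAULT_SCORE_CONFIG, patient_ids=None
) -> pd.DataFrame:
    """Per-patient high-risk count and truncated score.

    ``expr3`` is (n, 3) with columns ordered as ``config.rules`` (default
    ADH1B, BST2, FER1L4). Returns a DataFrame with columns ``k`` (0..3) and
    ``score`` (0/1/2).
    """
    scorer = CountRiskScorer(config=config).fit()
    k = scorer.transform(expr3)
    out = pd.DataFrame({"k": k, "score": np.minimum(k, 2)})
    if patient_ids is not None:
        out.insert(0, "patient_id", list(patient_ids))
    return out


@dataclasses.dataclass
class StratifiedSummary:
    """Per-score-group survival summary with the overall log-rank test."""

    curves: dict[int, KMCurve]
    five_year_os: dict[int, float]
    group_sizes: dict[int, int]
    logrank: LogRankResult | None
    single_group: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.curves):
            rows.append(
                {
                    "score": g,
                    "n": self.group_sizes[g],
                    "five_year_os": self.five_year_os[g],
                }
            )
        return pd.DataFrame(rows)


def stratify_and_summarize(scores, time, event, horizon: float = 60.0) -> StratifiedSummary:
    """KM curve, survival at ``horizon`` months and log-rank across score
    groups. With a single populated group the summary is returned with
    ``single_group=True`` and no test."""
    scores = np.asarray(scores)
    time, event = _check_endpoints(time, event)
    if scores.shape != time.shape:
        raise ValueError("scores and endpoints must have the same length")
    groups = np.unique(scores)
    curves: dict[int, KMCurve] = {}
    five: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for g in groups:
        mask = scores == g
        curves[int(g)] = km_fit(time[mask], event[mask])
        five[int(g)] = km_survival_at(curves[int(g)], horizon)
        sizes[int(g)] = int(mask.sum())
    if groups.size < 2:
        return StratifiedSummary(curves, five, sizes, logrank=None, single_group=True)
    lr = logrank_test(time, event, scores)
    return StratifiedSummary(curves, five, sizes, logrank=lr, single_group=False)
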