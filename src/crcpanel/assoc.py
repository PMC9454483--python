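"""Association of dichotomized expression with clinicopathological categories.

Each gene is split at a stated cut-off (strict-less-than vs
greater-or-equal) and cross-tabulated against categorical clinical
variables; independence is tested with Pearson's chi-square without
continuity correction. Cells with expected counts below 5 are flagged but
the chi-square is still reported (Yates correction is available as an
option).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix


def dichotomize(values, threshold: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Partition values into below / at-or-above the threshold.

    Returns the boolean at-or-above indicator and the (below, at_or_above)
    counts; boundary values fall on the >= side.
    """
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite")
    ge = values >= threshold
    return ge, (int((~ge).sum()), int(ge.sum()))


@dataclasses.dataclass
class ChisqResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    small_expected_flag: bool


def chisq_test(counts, correction: bool = False) -> ChisqResult:
    """Pearson chi-square test of independence on an r × c count table."""
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("counts must be finite and >= 0")
    if t.sum() <= 0:
        raise ValueError("table total must be > 0")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("table has an all-zero row or column")
    chi2, p, df, expected = stats.chi2_contingency(t, correction=correction)
    return ChisqResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        expected=expected,
        small_expected_flag=bool((expected < 5).any()),
    )


def crosstab(binary_a, categories_b) -> pd.DataFrame:
    """Contingency table of a binary split against a categorical variable."""
    a = pd.Series(np.asarray(binary_a), name="at_or_above")
    b = pd.Series(np.asarray(categories_b), name="category")
    return pd.crosstab(b, a)


def association_report(
    m: ExpressionMatrix,
    clinical: pd.DataFrame,
    gene_cutoffs: dict[str, float],
    variables: dict[str, str | pd.Series],
    correction: bool = False,
) -> pd.DataFrame:
    """Gene × clinical-variable association table (counts, percentages, p).

    ``gene_cutoffs`` maps transcript_id → threshold (normalized log2 units);
    ``variables`` maps a display name → clinical column name (or a
    precomputed categorical Series aligned with the matrix samples).
    """
    rows = []
    n = m.n_samples
    for tid, cut in gene_cutoffs.items():
        expr = m.gene_row(tid)
        ge, _ = dichotomize(expr, cut)
        for var_name, col in variables.items():
            cats = clinical[col] if isinstance(col, str) else pd.Series(col)
            tab = crosstab(ge, cats.to_numpy())
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append(
                    {
                        "transcript_id": tid,
                        "cutoff": cut,
                        "variable": var_name,
                        "chi2": np.nan,
                        "df": 0,
                        "p": np.nan,
                        "small_expected": False,
                        "note": "degenerate table",
                    }
                )
                continue
            res = chisq_test(tab.to_numpy(), correction=correction)
            rows.append(
                {
                    "transcript_id": tid,
                    "cutoff": cut,
                    "variable": var_name,
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                    "small_expected": res.small_expected_flag,
                    "note": "",
                }
            )
    out = pd.DataFrame(rows)
    out["n"] = n
    return out
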