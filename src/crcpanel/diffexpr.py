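"""Two-group differential expression with empirical-Bayes moderated t.

The tumour-vs-normal comparison on the log2 scale uses a moderated
t-statistic: per-transcript pooled variances s_g^2 (d_g = n1 + n2 - 2
degrees of freedom) are shrunk towards a common prior s0^2 with prior
degrees of freedom d0,

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and t_g = (mean_tumour - mean_normal) / (s_tilde_g * sqrt(1/n1 + 1/n2)) is
referred to a t distribution on d0 + d_g degrees of freedom. The prior
(d0, s0^2) is estimated by moment-matching the log sample variances to a
scaled F distribution: with e_g = log(s_g^2) - psi(d_g/2) + log(d_g/2),
E[e_g] = log(s0^2) - psi(d0/2) + log(d0/2) and
Var[e_g] = psi'(d_g/2) + psi'(d0/2), so d0 solves a trigamma equation
(Newton iteration) and s0^2 follows. A Welch t test is available as a
plain-likelihood fallback.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import NORMAL, TUMOUR, ExpressionMatrix

DE_COLUMNS = ["symbol", "transcript_id", "log2fc", "stat", "p", "q", "significant"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match per-gene variances to s0^2 * F(d_g, d0); return (d0, s0^2)."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - ebar) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess dispersion: infinite prior df, complete shrinkage
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t_stats(
    group1: np.ndarray,
    group2: np.ndarray,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Moderated t per row of two genes × samples blocks (group1 - group2).

    ``d0``/``s0_2`` override the estimated prior; ``d0=0`` reduces to the
    ordinary pooled-variance t test.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    dg = n1 + n2 - 2
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    s2 = (g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)) / dg
    if d0 is None:
        d0, s0_est = _fit_f_dist(s2, dg)
        if s0_2 is None:
            s0_2 = s0_est
    elif s0_2 is None:
        s0_2 = float(np.mean(s2)) if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {"log2fc": diff, "stat": t, "p": p, "df": df_total, "s2_post": s2_post}
    )


def _welch_stats(g1: np.ndarray, g2: np.ndarray) -> pd.DataFrame:
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    zero_var = (g1.var(axis=1) == 0) & (g2.var(axis=1) == 0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # identical degenerate rows: no evidence of difference
    t[zero_var & (diff == 0)] = 0.0
    p[zero_var & (diff == 0)] = 1.0
    # zero-variance with a real shift: infinitely strong evidence, flagged
    inf_rows = zero_var & (diff != 0)
    if inf_rows.any():
        warnings.warn("zero-variance transcript(s) under welch_t", RuntimeWarning)
        t[inf_rows] = np.inf * np.sign(diff[inf_rows])
        p[inf_rows] = 0.0
    return pd.DataFrame({"log2fc": diff, "stat": t, "p": p})


def differential_expression(
    m: ExpressionMatrix,
    alpha: float = 0.05,
    method: str = "moderated_t",
    exclude_housekeeping: bool = True,
) -> pd.DataFrame:
    """Tumour-vs-normal differential expression with BH-FDR.

    Returns one row per panel transcript with columns ``symbol``,
    ``transcript_id``, ``log2fc`` (tumour minus normal, log2 units),
    ``stat``, ``p``, ``q`` and ``significant`` (q < alpha).
    """
    if m.scale != "normalized_log2":
        raise ValueError("differential_expression expects a normalized_log2 matrix")
    if method not in ("moderated_t", "welch_t"):
        raise ValueError(f"unknown method {method!r}")
    cls = m.class_array
    tum = cls == TUMOUR
    nor = cls == NORMAL
    if tum.sum() < 2 or nor.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {int(tum.sum())} tumour / "
            f"{int(nor.sum())} normal"
        )
    keep = (
        ~m.housekeeping_index if exclude_housekeeping else np.ones(m.n_genes, bool)
    )
    g1 = m.values[keep][:, tum]
    g2 = m.values[keep][:, nor]
    if method == "moderated_t":
        res = moderated_t_stats(g1, g2)
    else:
        res = _welch_stats(g1, g2)
    out = pd.DataFrame(
        {
            "symbol": [g.symbol for g, k in zip(m.genes, keep) if k],
            "transcript_id": [g.transcript_id for g, k in zip(m.genes, keep) if k],
            "log2fc": res["log2fc"].to_numpy(),
            "stat": res["stat"].to_numpy(),
            "p": res["p"].to_numpy(),
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False)
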