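"""Synthetic sCRC cohorts with the statistical structure the pipeline assumes.

The generator emulates a NanoString panel study: 28 target transcripts plus
three housekeeping genes (GAPDH, ACTB, TUBB) measured on tumour and
nontumoral samples, with

* log-normal counts around per-transcript baseline log2 means, a shared
  per-sample library-size effect (removed by housekeeping normalization),
  and tumour-vs-normal log2 shifts defaulting to the panel's reported fold
  changes (e.g. SALL4 +5.86, SPP1 +5.84, ADH1B -5.38, MYLK -2.40);
* three score genes (ADH1B/BST2/FER1L4) whose tumour expression is drawn on
  a definite side of its risk threshold (4.39 / 10.34 / 4.73 log2 units,
  margin >= 0.5), so each patient has a known true high-risk state;
* overall survival exponential with a hazard set by the patient's risk
  group, calibrated so the expected 5-year survival of score groups 0/1/2
  is 0.91/0.83/0.52; disease-free survival as min(relapse, death) with a
  proportional relapse hazard; censoring from an administrative follow-up
  limit at 79 months plus uniform early drop-out for a configurable
  fraction of patients.

The default panel is synthetic: it carries the 14 reported transcripts, the
remaining study isoforms, and null filler transcripts (log2fc = 0) to
complete the 28 targets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cutpoint import DEFAULT_SCORE_CONFIG, HIGH_IF_GE, ScoreConfig
from .matrix import NORMAL, TUMOUR, ExpressionMatrix, GeneAnnotation


@dataclasses.dataclass(frozen=True)
class PanelGene:
    symbol: str
    transcript_id: str
    baseline_log2: float
    log2fc: float = 0.0
    noise_sd: float = 1.0
    is_housekeeping: bool = False


def default_panel() -> list[PanelGene]:
    """Synthetic default panel: 28 targets + 3 housekeeping genes.

    Reported fold changes are attached to their transcripts; the remaining
    panel members are nulls with log2fc = 0. Baseline log2 means are
    arbitrary but fixed; score-gene baselines are set at generation time
    from the risk thresholds.
    """
    g = PanelGene
    targets = [
        g("SALL4", "NM_001318031", 4.0, 5.86),
        g("SPP1", "NM_000582", 6.5, 5.84),
        g("THBS2", "NM_003247", 6.0, 4.81),
        g("CXCL3", "NM_002090", 6.8, 3.94),
        g("SRPX2", "NM_014467", 7.2, 3.08),
        g("SERPINA1", "NM_000295", 9.0, 2.65),
        g("FER1L4", "NR_119376", 3.5, 2.56),
        g("IL13RA2", "NM_000640", 5.0, 1.75),
        g("MOCOS", "NM_017947", 6.2, 1.73),
        g("BST2", "NM_004335", 9.8, 0.89),
        g("ADH1B", "NM_001286650", 9.5, -5.38),
        g("ADH1B", "NM_000668", 9.2, -4.40),
        g("MYLK", "NM_001321309", 8.7, -2.41),
        g("MYLK", "NM_053026", 8.5, -2.40),
        # further study isoforms, not significant: null shifts
        g("SPP1", "NM_001040058", 6.0, 0.0),
        g("ITIH1", "NM_002215", 7.5, 0.0),
        g("ITIH1", "NM_001166434", 7.0, 0.0),
        g("FBXO32", "NM_058229", 8.0, 0.0),
        g("FBXO32", "NM_148177", 7.8, 0.0),
        # null filler transcripts completing the 28-target panel
        g("CDH17", "NM_004063", 10.0, 0.0),
        g("MMP7", "NM_002423", 8.8, 0.0),
        g("TIMP1", "NM_003254", 11.0, 0.0),
        g("CXCL8", "NM_000584", 9.4, 0.0),
        g("LGR5", "NM_003667", 6.6, 0.0),
        g("AXIN2", "NM_004655", 7.9, 0.0),
        g("CEACAM5", "NM_004363", 11.5, 0.0),
        g("REG4", "NM_032044", 8.2, 0.0),
        g("OLFM4", "NM_006418", 10.6, 0.0),
    ]
    housekeeping = [
        g("GAPDH", "NM_002046", 16.5, 0.0, 0.15, True),
        g("ACTB", "NM_001101", 17.0, 0.0, 0.15, True),
        g("TUBB", "NM_178014", 13.5, 0.0, 0.15, True),
    ]
    return targets + housekeeping


def calibrate_hazards(target_5yr, horizon: float = 60.0) -> np.ndarray:
    """Exponential rates per group: lambda = -ln(S_horizon) / horizon.

    ``target_5yr`` are 5-year survival proportions in (0, 1); the horizon is
    60 months.
    """
    s = np.asarray(target_5yr, dtype=float)
    if np.any(s <= 0) or np.any(s >= 1):
        raise ValueError("survival proportions must lie strictly in (0, 1)")
    return -np.log(s) / horizon


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    66 tumours vs 10 nontumoral samples, the synthetic 28+3 panel, the
    three-gene risk thresholds, score-group 5-year survival targets
    0.91/0.83/0.52 over a 79-month follow-up, and 20% uniform early
    drop-out. The seed is mandatory.
    """

    seed: int
    n_tumour: int = 66
    n_normal: int = 10
    panel: list[PanelGene] = dataclasses.field(default_factory=default_panel)
    score_config: ScoreConfig = DEFAULT_SCORE_CONFIG
    p_high: float = 0.415  # per-gene high-risk prevalence; (1-p)^3 ~ 0.20
    state_margin_mean: float = 1.2  # mean log2 distance from threshold
    state_margin_sd: float = 0.5
    state_margin_min: float = 0.5
    five_year_targets: tuple[float, float, float] = (0.91, 0.83, 0.52)
    per_gene_hazard_multipliers: tuple[float, float, float] | None = None
    baseline_hazard: float | None = None  # used with per-gene multipliers
    horizon: float = 60.0
    followup_max: float = 79.0
    dropout_prob: float = 0.20
    relapse_multiplier: float = 1.5
    lib_size_sd: float = 0.25
    count_model: str = "lognormal"  # or "negbin"
    negbin_dispersion: float = 10.0

    def validate(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed is required")
        if self.n_tumour < 4 or self.n_normal < 2:
            problems.append("need n_tumour >= 4 and n_normal >= 2")
        if not 0 < self.p_high < 1:
            problems.append("p_high must lie in (0, 1)")
        if any(g.noise_sd <= 0 for g in self.panel):
            problems.append("all noise_sd must be > 0")
        if not any(g.is_housekeeping for g in self.panel):
            problems.append("panel needs >= 1 housekeeping gene")
        if not all(0 < s < 1 for s in self.five_year_targets):
            problems.append("five_year_targets must lie in (0, 1)")
        if self.per_gene_hazard_multipliers is not None:
            if any(m <= 0 for m in self.per_gene_hazard_multipliers):
                problems.append("hazard multipliers must be > 0")
            if self.baseline_hazard is None or self.baseline_hazard <= 0:
                problems.append("baseline_hazard must be > 0 with per-gene multipliers")
        if not 0 <= self.dropout_prob < 1:
            problems.append("dropout_prob must lie in [0, 1)")
        if self.count_model not in ("lognormal", "negbin"):
            problems.append("count_model must be 'lognormal' or 'negbin'")
        if self.state_margin_min <= 0:
            problems.append("state_margin_min must be > 0")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


@dataclasses.dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # raw counts
    clinical: pd.DataFrame
    truth: pd.DataFrame  # per-tumour-patient states, k, score, hazard
    config: SimulationConfig


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort: raw-count expression matrix, clinical table, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nt, nn = config.n_tumour, config.n_normal
    tumour_ids = [f"T{i + 1:02d}" for i in range(nt)]
    normal_ids = [f"N{i + 1:02d}" for i in range(nn)]
    samples = tumour_ids + normal_ids
    classes = [TUMOUR] * nt + [NORMAL] * nn
    rules = {r.transcript_id: r for r in config.score_config.rules}

    # true high-risk states and risk groups
    states = rng.random((nt, 3)) < config.p_high
    k = states.sum(axis=1)
    score = np.minimum(k, 2)
    if config.per_gene_hazard_multipliers is not None:
        mult = np.asarray(config.per_gene_hazard_multipliers, dtype=float)
        hazard = config.baseline_hazard * np.prod(
            np.where(states, mult[None, :], 1.0), axis=1
        )
    else:
        rates = calibrate_hazards(config.five_year_targets, config.horizon)
        hazard = rates[score]

    # expression on the log2 scale
    lib = rng.normal(0.0, config.lib_size_sd, size=nt + nn)
    log2 = np.empty((len(config.panel), nt + nn))
    score_col = {tid: j for j, tid in enumerate(config.score_config.transcript_ids)}
    for i, gene in enumerate(config.panel):
        if gene.transcript_id in score_col and not gene.is_housekeeping:
            j = score_col[gene.transcript_id]
            rule = rules[gene.transcript_id]
            side = 1.0 if rule.high_risk_side == HIGH_IF_GE else -1.0
            margin = np.maximum(
                np.abs(rng.normal(config.state_margin_mean, config.state_margin_sd, nt)),
                config.state_margin_min,
            )
            sign = np.where(states[:, j], side, -side)
            tum = rule.threshold + sign * margin
            # normal-tissue mean consistent with the configured fold change
            mean_tum = rule.threshold + side * config.state_margin_mean * (
                2 * config.p_high - 1
            )
            nor = rng.normal(mean_tum - gene.log2fc, gene.noise_sd, nn)
            log2[i] = np.concatenate([tum, nor])
        else:
            shift = np.r_[np.full(nt, gene.log2fc), np.zeros(nn)]
            log2[i] = gene.baseline_log2 + shift + rng.normal(
                0.0, gene.noise_sd, nt + nn
            )
    log2 = log2 + lib[None, :]

    if config.count_model == "lognormal":
        counts = np.rint(np.exp2(log2)).clip(min=0)
    else:
        mean = np.exp2(log2)
        r = config.negbin_dispersion
        counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
    # housekeeping counts must stay positive for geometric-mean scaling
    hk = np.array([g.is_housekeeping for g in config.panel])
    counts[hk] = np.maximum(counts[hk], 1.0)

    expression = ExpressionMatrix(
        values=counts,
        genes=[
            GeneAnnotation(g.symbol, g.transcript_id, g.is_housekeeping)
            for g in config.panel
        ],
        samples=samples,
        sample_class=classes,
        scale="raw_counts",
    )

    os_time, os_event, dfs_time, dfs_event = _draw_survival(
        rng, hazard, config.relapse_multiplier, config.followup_max, config.dropout_prob
    )
    clinical = _draw_clinical(rng, tumour_ids)
    clinical["os_time"] = os_time
    clinical["os_event"] = os_event.astype(int)
    clinical["dfs_time"] = dfs_time
    clinical["dfs_event"] = dfs_event.astype(int)

    truth = pd.DataFrame(
        {
            "patient_id": tumour_ids,
            **{
                f"state_{tid}": states[:, j]
                for tid, j in score_col.items()
            },
            "k": k,
            "score": score,
            "hazard": hazard,
        }
    )
    return SyntheticCohort(
        expression=expression, clinical=clinical, truth=truth, config=config
    )


def _draw_survival(rng, hazard, relapse_multiplier, followup_max, dropout_prob):
    n = hazard.size
    death = rng.exponential(1.0 / hazard)
    relapse = rng.exponential(1.0 / (relapse_multiplier * hazard))
    censor = np.full(n, followup_max)
    drop = rng.random(n) < dropout_prob
    censor[drop] = rng.uniform(0.0, followup_max, size=int(drop.sum()))
    os_time = np.minimum(death, censor)
    os_event = death <= censor
    progression = np.minimum(relapse, death)
    dfs_time = np.minimum(progression, censor)
    dfs_event = progression <= censor
    return os_time, os_event, dfs_time, dfs_event


def simulate_score_group_survival(
    rng,
    group_sizes=(11, 23, 21),
    five_year_targets=(0.91, 0.83, 0.52),
    horizon: float = 60.0,
    followup_max: float = 79.0,
    dropout_prob: float = 0.20,
):
    """Survival data for fixed score-group sizes (no expression layer).

    Returns (scores, time, event) for sum(group_sizes) patients with
    exponential hazards calibrated to the per-group 5-year targets.
    """
    rates = calibrate_hazards(five_year_targets, horizon)
    scores = np.repeat(np.arange(len(group_sizes)), group_sizes)
    hazard = rates[scores]
    os_time, os_event, _, _ = _draw_survival(
        rng, hazard, 1.5, followup_max, dropout_prob
    )
    return scores, os_time, os_event


def _draw_clinical(rng, patient_ids) -> pd.DataFrame:
    """Clinical covariates drawn from the study's marginal distributions.

    Covariates are independent of the expression layer and of survival;
    they exercise table plumbing and the association/Cox interfaces.
    """
    n = len(patient_ids)
    age = np.clip(np.rint(rng.normal(68, 11, n)), 38, 92).astype(int)
    sex = rng.choice(["F", "M"], size=n, p=[29 / 66, 37 / 66])
    size = np.clip(np.exp(rng.normal(np.log(4.0), 0.5, n)), 0.5, 13.0).round(1)
    site = rng.choice(
        ["right colon", "left colon", "rectum"], size=n, p=[26 / 66, 7 / 66, 33 / 66]
    )
    cea = np.exp(rng.normal(np.log(2.53), 1.1, n)).round(2)
    grade = rng.choice(
        ["well", "moderate", "poor", "undifferentiated"],
        size=n,
        p=[18 / 66, 46 / 66, 1 / 66, 1 / 66],
    )
    lvi = (rng.random(n) < 22 / 66).astype(int)
    pT = rng.choice([1, 2, 3, 4], size=n, p=[5 / 66, 16 / 66, 39 / 66, 6 / 66])
    pN = rng.choice([0, 1, 2], size=n, p=[35 / 66, 15 / 66, 16 / 66])
    M = (rng.random(n) < 5 / 66).astype(int)
    stage = np.where(M == 1, "IV", np.where(pN > 0, "III", np.where(pT >= 3, "II", "I")))
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": age,
            "sex": sex,
            "tumour_size": size,
            "site": site,
            "cea": cea,
            "grade": grade,
            "lymphovascular_invasion": lvi,
            "pT": pT,
            "pN": pN,
            "M": M,
            "tnm_stage": stage,
        }
    )
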