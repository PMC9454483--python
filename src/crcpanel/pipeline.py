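"""End-to-end orchestration: preprocessing through risk stratification.

``run_pipeline`` is a pure function of (inputs, config, seed): every stage
writes its artifact under one output directory, and a manifest records the
SHA-256 of each file together with the effective config, so identical
inputs and seed yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from .cutpoint import (
    DEFAULT_SCORE_CONFIG,
    ScoreConfig,
    apply_score,
    optimal_cutpoint,
    stratify_and_summarize,
)
from .diffexpr import differential_expression, write_de_table
from .matrix import (
    ExpressionMatrix,
    align_samples,
    endpoints_from_clinical,
    read_clinical_table,
    read_expression_matrix,
    write_expression_matrix,
)
from .preprocess import preprocess
from .unsupervised import classical_mds, gmm_select, hcluster

logger = logging.getLogger("crcpanel")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    expression_path: str
    clinical_path: str
    out_dir: str
    format: str = "tsv"
    alpha: float = 0.05
    de_method: str = "moderated_t"
    min_arm_fraction: float = 0.10
    score_config: ScoreConfig = DEFAULT_SCORE_CONFIG
    endpoint: str = "OS"
    log2_offset: float = 1.0
    seed: int = 0
    stages: tuple[str, ...] = (
        "normalize",
        "de",
        "mds",
        "cluster",
        "cutpoint",
        "score",
        "stratify",
        "assoc",
    )

    def validate(self) -> None:
        if self.endpoint.upper() not in ("OS", "DFS"):
            raise ValueError("endpoint must be 'OS' or 'DFS'")
        for p in (self.expression_path, self.clinical_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage_log: list[dict] = []

    def record(name: str, path: Path, t0: float, shape) -> None:
        artifacts[name] = path
        entry = {"stage": name, "file": path.name, "shape": shape,
                 "elapsed_s": round(_time.perf_counter() - t0, 4)}
        stage_log.append(entry)
        logger.info("stage %(stage)s -> %(file)s shape=%(shape)s in %(elapsed_s)ss", entry)

    def run_stage(name, fn):
        if name not in config.stages:
            return None
        t0 = _time.perf_counter()
        try:
            return fn(t0)
        except Exception as exc:  # propagate with stage context
            raise PipelineStageError(name, exc) from exc

    raw = read_expression_matrix(config.expression_path, format=config.format)
    clinical = read_clinical_table(config.clinical_path)

    norm = preprocess(raw, offset=config.log2_offset)

    def _normalize(t0):
        path = out / "normalized_matrix.tsv"
        write_expression_matrix(norm, path)
        record("normalize", path, t0, list(norm.values.shape))

    run_stage("normalize", _normalize)

    def _de(t0):
        de = differential_expression(norm, alpha=config.alpha, method=config.de_method)
        path = out / "de.tsv"
        write_de_table(de, path)
        record("de", path, t0, list(de.shape))

    run_stage("de", _de)

    def _mds(t0):
        res = classical_mds(norm, k=2)
        path = out / "mds.tsv"
        df = res.to_frame()
        df["sample_class"] = norm.sample_class
        df.to_csv(path, sep="\t")
        gmm = gmm_select(res.coordinates, random_state=config.seed)
        gpath = out / "gmm.json"
        gpath.write_text(
            json.dumps(
                {
                    "n_components": gmm.n_components,
                    "bic_per_k": {str(k): v for k, v in gmm.bic_per_k.items()},
                    "weights": gmm.weights.tolist(),
                    "assignments": gmm.assignments.tolist(),
                },
                sort_keys=True,
                indent=1,
            )
        )
        artifacts["gmm"] = gpath
        record("mds", path, t0, list(res.coordinates.shape))

    run_stage("mds", _mds)

    def _cluster(t0):
        dend = hcluster(norm)
        path = out / "dendrogram.nwk"
        path.write_text(dend.to_newick() + "\n")
        record("cluster", path, t0, list(dend.linkage.shape))

    run_stage("cluster", _cluster)

    tumour, cl = align_samples(norm, clinical)
    time_, event = endpoints_from_clinical(cl, config.endpoint)

    def _cutpoint(t0):
        rows = []
        for tid in config.score_config.transcript_ids:
            res = optimal_cutpoint(
                tumour.gene_row(tid), time_, event,
                min_arm_fraction=config.min_arm_fraction, gene=tid,
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "chosen": res.chosen,
                    "p": res.p_chosen,
                    "direction": res.direction,
                    "n_below": res.arm_sizes[0],
                    "n_at_or_above": res.arm_sizes[1],
                    "n_candidates": len(res.candidates),
                }
            )
        path = out / "cutpoints.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        record("cutpoint", path, t0, [len(rows), 7])

    run_stage("cutpoint", _cutpoint)

    expr3 = np.column_stack(
        [tumour.gene_row(tid) for tid in config.score_config.transcript_ids]
    )
    scores_df = apply_score(expr3, config.score_config, patient_ids=tumour.samples)

    def _score(t0):
        path = out / "scores.tsv"
        scores_df.to_csv(path, sep="\t", index=False)
        record("score", path, t0, list(scores_df.shape))

    run_stage("score", _score)

    def _stratify(t0):
        summary = stratify_and_summarize(scores_df["score"].to_numpy(), time_, event)
        path = out / "stratified_survival.tsv"
        frames = []
        for g, curve in summary.curves.items():
            df = curve.to_frame()
            df.insert(0, "score", g)
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)
        jpath = out / "stratified_summary.json"
        jpath.write_text(
            json.dumps(
                {
                    "endpoint": config.endpoint.upper(),
                    "group_sizes": {str(k): v for k, v in summary.group_sizes.items()},
                    "five_year_survival": {
                        str(k): round(v, 6) for k, v in summary.five_year_os.items()
                    },
                    "logrank_p": None if summary.single_group else summary.logrank.p,
                    "single_group": summary.single_group,
                },
                sort_keys=True,
                indent=1,
            )
        )
        artifacts["stratify_summary"] = jpath
        record("stratify", path, t0, list(scores_df.shape))

    run_stage("stratify", _stratify)

    def _assoc(t0):
        cutoffs = {r.transcript_id: r.threshold for r in config.score_config.rules}
        variables = {
            "tumour_size_ge4": pd.Series(cl["tumour_size"] >= 4).map(
                {True: ">=4", False: "<4"}
            ),
            "site": pd.Series(
                np.where(cl["site"].eq("rectum"), "rectum", "colon")
            ),
            "cea_gt5": pd.Series(cl["cea"] > 5).map({True: ">5", False: "<=5"}),
            "pT_group": pd.Series(np.where(cl["pT"] >= 3, "pT3-4", "pT1-2")),
            "pN_group": pd.Series(np.where(cl["pN"] >= 1, "pN1-2", "pN0")),
        }
        rep = assoc_mod.association_report(tumour, cl, cutoffs, variables)
        path = out / "assoc.tsv"
        rep.to_csv(path, sep="\t", index=False)
        record("assoc", path, t0, list(rep.shape))

    run_stage("assoc", _assoc)

    manifest = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "score_config"
            },
            "score_config": config.score_config.to_dict(),
        },
        # elapsed times go to the log only, keeping the manifest deterministic
        "stages": [
            {k: v for k, v in e.items() if k != "elapsed_s"} for e in stage_log
        ],
        "files": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
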