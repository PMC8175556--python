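"""End-to-end pipeline orchestration.

One configured, seeded run ties the stages together in the order of the
analysis: baseline table -> pathway scores -> pathway and gene association ->
drug response scores and comparison -> immune consensus clustering ->
summary.  Every run directory carries a machine-readable provenance record
(config hash, seed, package and library versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pcatx import io as pio
from pcatx.association import (
    call_de_genes,
    covariates_from_clinical,
    feature_association,
)
from pcatx.cohort_stats import VariableDescriptor, build_table_one, render_table_one_markdown
from pcatx.drug_response import compare_drs, drs_matrix
from pcatx.immune import cluster_enrichment, consensus_cluster, derive_adverse_pathology
from pcatx.pathway import pathway_score

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    expression: str
    clinical: str
    gene_sets: str | None = None
    signatures: str | None = None
    drug_models: str | None = None
    immune_panel: str | None = None
    outcome_col: str = "group"
    positive_label: str = "AAM"
    q_threshold: float = 1e-5
    seed: int = 0
    out_dir: str = "run_out"
    consensus_resamples: int = 100
    table_one_vars: list = field(
        default_factory=lambda: [
            ("grade_group", "categorical"),
            ("pt_stage", "categorical"),
            ("pn_stage", "categorical"),
            ("psa", "continuous"),
        ]
    )

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("expression", "clinical", "gene_sets", "signatures", "drug_models", "immune_panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name} points to missing file {p}")


def _provenance(config: RunConfig) -> dict:
    import pcatx
    import scipy
    import sklearn
    import statsmodels

    cfg = {k: v for k, v in vars(config).items()}
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "pcatx": pcatx.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the output directory.

    A stage failure aborts the run with the stage name in the error message.
    Deterministic for a fixed config and seed.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        expr = pio.read_expression(config.expression)
        clinical = pio.read_clinical(config.clinical)
        expr = pio.align_to_clinical(expr, clinical)
        outcome = pd.Series(
            (clinical[config.outcome_col] == config.positive_label).astype(float).to_numpy(),
            index=clinical["sample_id"].to_numpy(),
        )
        cov = covariates_from_clinical(clinical)

        stage = "table-one"
        t0 = time.time()
        descriptors = [VariableDescriptor(name=n, kind=k) for n, k in config.table_one_vars]
        tab1 = build_table_one(clinical, descriptors, group_col=config.outcome_col)
        tab1.to_csv(out / "table_one.tsv", sep="\t", index=False)
        (out / "table_one.md").write_text(render_table_one_markdown(tab1))
        logger.info("table-one done in %.1fs", time.time() - t0)

        scores = None
        if config.gene_sets:
            stage = "pathway-scores"
            sets = pio.read_gmt(config.gene_sets)
            scores = pd.DataFrame({s.name: pathway_score(expr, s) for s in sets}).T
            pio.write_scores(scores, out / "pathway_scores.tsv")

            stage = "pathway-association"
            path_assoc = feature_association(scores, outcome, cov)
            path_assoc.to_csv(out / "pathway_association.tsv", sep="\t")

        stage = "gene-association"
        gene_assoc = feature_association(expr, outcome, cov)
        gene_assoc.to_csv(out / "gene_association.tsv", sep="\t")
        de = call_de_genes(gene_assoc, config.q_threshold)
        (out / "de_genes.json").write_text(json.dumps(de, indent=1) + "\n")

        drs_assoc = None
        if config.drug_models:
            stage = "drug-response"
            models = pio.read_drug_models(config.drug_models)
            drs = drs_matrix(expr, models)
            pio.write_scores(drs, out / "drs.tsv")
            drs_assoc = compare_drs(drs, outcome, cov)
            drs_assoc.to_csv(out / "drs_association.tsv", sep="\t")

        if config.immune_panel:
            stage = "immune-clustering"
            panel = pio.read_gene_panel(config.immune_panel)
            present = [g for g in panel if g in expr.index]
            group1 = clinical.loc[
                clinical[config.outcome_col] == config.positive_label, "sample_id"
            ]
            sub = expr.loc[present, group1]
            results, best_k = consensus_cluster(
                sub,
                n_resamples=config.consensus_resamples,
                seed=config.seed,
            )
            best = results[best_k]
            best.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t")
            best.labels.rename_axis("sample_id").to_csv(out / "immune_clusters.csv")
            flags = derive_adverse_pathology(clinical)
            enrich = cluster_enrichment(best.labels, flags)
            enrich.drop(columns=["table"]).to_csv(out / "cluster_enrichment.tsv", sep="\t")

        stage = "summary"
        summary = {
            "n_samples": int(expr.shape[1]),
            "n_genes": int(expr.shape[0]),
            "n_de_up_group1": len(de["up_group1"]),
            "n_de_up_group0": len(de["up_group0"]),
            "q_threshold": config.q_threshold,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
        (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=1) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
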