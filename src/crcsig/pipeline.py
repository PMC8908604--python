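"""End-to-end orchestration: score -> classify -> correlate -> stratify -> survive.

A run is driven by a single :class:`RunConfig` (YAML-serializable); inputs
are either file paths (expression matrix, optional probe map, clinical
table, GMT signatures, CMS marker template) or a synthetic-cohort
configuration — never both. Every tabular artifact is written as TSV with
``#``-prefixed provenance comment lines (config hash, seed, package
version); figures are derived artifacts only and never feed downstream
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cms import ntp_classify, read_template_tsv
from .expression import read_expression_tsv, read_probe_map
from .scoring import score_pipeline
from .signatures import read_gmt
from .simulate import SyntheticCohortConfig, simulate_cohort, recovery_report
from .stats import ClinicalTable, correlation_matrix, median_split_quadrants, table_one
from .survival import km_fit, logrank, quartile_survival

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_clinical_tsv"]

log = logging.getLogger("crcsig")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    # real-data inputs
    expr_path: str | None = None
    probe_map_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    template_path: str | None = None
    feature_kind: str = "gene"
    # or a synthetic cohort
    synthetic: SyntheticCohortConfig | None = None
    # scoring options
    cell_line_mode: bool = False
    min_coverage: float = 0.5
    log2_transform: bool = False
    # NTP options
    n_perm: int = 1000
    fdr_threshold: float = 0.05
    seed: int = 0
    # survival quartile column (defaults to SRC when present)
    survival_score: str | None = None
    out_dir: str = "crcsig_run"

    def validate(self) -> None:
        real = self.expr_path is not None
        if real == (self.synthetic is not None):
            raise PipelineError("provide exactly one of expression paths or a synthetic config")
        if real:
            for label, p in [
                ("expression", self.expr_path),
                ("clinical", self.clinical_path),
                ("signatures GMT", self.gmt_path),
                ("CMS template", self.template_path),
            ]:
                if p is None or not Path(p).exists():
                    raise PipelineError(f"{label} file missing: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            syn = d["synthetic"]
            syn["latent_correlation"] = self.synthetic.latent_correlation.to_dict()
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # output location is not part of the analysis
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_clinical_tsv(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV (first column sample id, ``#`` comments allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in ("os_event", "kras", "nras", "braf_v600e", "apc", "tp53"):
        if col in df:
            df[col] = df[col].astype(bool)
    return ClinicalTable(df=df)


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"crcsig {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]


def _write_df(df: pd.DataFrame, path: Path, header: list[str], index_label="sample_id") -> None:
    with path.open("w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _heatmap(rho: pd.DataFrame, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(rho), 1 + 0.5 * len(rho)))
    im = ax.imshow(rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho)), rho.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(rho)), rho.index, fontsize=7)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _km_plot(curves: dict, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(
            np.concatenate([[0.0], curve.times]),
            np.concatenate([[1.0], curve.survival]),
            where="post",
            label=label,
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact set; returns them in-memory.

    Stages abort with a stage-named error; nothing partial is written
    silently. Deterministic given the config (including its seeds).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    artifacts: dict = {}

    # ---- inputs -----------------------------------------------------------
    cohort = None
    if config.synthetic is not None:
        cohort = simulate_cohort(config.synthetic)
        expr, registry, template = cohort.expression, cohort.registry, cohort.template
        clinical = cohort.clinical
        log.info("simulated cohort: %d samples x %d features",
                 expr.n_samples, len(expr.feature_ids))
    else:
        probe_map = read_probe_map(config.probe_map_path) if config.probe_map_path else None
        expr = read_expression_tsv(config.expr_path, config.feature_kind, probe_map)
        registry = read_gmt(config.gmt_path)
        template = read_template_tsv(config.template_path)
        clinical = read_clinical_tsv(config.clinical_path)
        log.info("loaded cohort: %d samples x %d features",
                 expr.n_samples, len(expr.feature_ids))

    # ---- scoring ----------------------------------------------------------
    score_table = score_pipeline(
        expr,
        registry,
        cell_line_mode=config.cell_line_mode,
        min_coverage=config.min_coverage,
        log2_transform=config.log2_transform,
    )
    score_table.to_tsv(out / "scores.tsv", header_lines=header)
    artifacts["scores"] = score_table

    # ---- CMS classification ----------------------------------------------
    cms = ntp_classify(
        expr,
        template,
        n_perm=config.n_perm,
        fdr_threshold=config.fdr_threshold,
        seed=config.seed,
    )
    cms.to_tsv(out / "cms.tsv", header_lines=header)
    artifacts["cms"] = cms
    log.info("CMS labels: %s", cms.labels.value_counts().to_dict())

    # ---- correlations ------------------------------------------------------
    joint = score_table.scores.join(
        cms.table[[c for c in cms.table.columns if c.endswith("*")]]
    )
    corr = correlation_matrix(joint, method="spearman")
    _write_df(corr.rho, out / "correlation_rho.tsv", header, index_label="variable")
    _write_df(corr.p, out / "correlation_p.tsv", header, index_label="variable")
    _heatmap(corr.rho, out / "correlation_heatmap.png", "Spearman correlation")
    artifacts["correlation"] = corr

    # ---- quadrant tables ---------------------------------------------------
    cols = list(score_table.scores.columns)
    quad_counts = {}
    for x, y in zip(cols, cols[1:]):
        _, counts = median_split_quadrants(score_table.scores[x], score_table.scores[y])
        quad_counts[f"{x}|{y}"] = counts
    artifacts["quadrants"] = quad_counts
    with (out / "quadrants.tsv").open("w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for pair, counts in quad_counts.items():
            fh.write(f"# pair {pair}\n")
            counts.to_csv(fh, sep="\t")

    # ---- table one ---------------------------------------------------------
    t1 = table_one(clinical, cms.labels)
    _write_df(t1, out / "table_one.tsv", header, index_label="cms_class")
    artifacts["table_one"] = t1

    # ---- survival ----------------------------------------------------------
    surv_col = config.survival_score or ("SRC" if "SRC" in score_table.scores else cols[0])
    clin_df = clinical.df
    if {"os_time", "os_event"}.issubset(clin_df.columns):
        qs = quartile_survival(score_table.scores[surv_col], clinical)
        km_frames = pd.concat([c.to_frame() for c in qs["curves"].values()])
        _write_df(km_frames, out / "km_quartiles.tsv", header, index_label="step")
        _km_plot(qs["curves"], out / "km_quartiles.png", f"{surv_col} quartiles")
        artifacts["quartile_survival"] = qs

        labeled = cms.labels[cms.labels != "NA"]
        sub = clin_df.loc[labeled.index].dropna(subset=["os_time", "os_event"])
        cms_curves = {
            k: km_fit(g["os_time"], g["os_event"].astype(bool), label=k)
            for k, g in sub.groupby(labeled.loc[sub.index])
        }
        cms_lr = logrank(
            sub["os_time"], sub["os_event"].astype(bool), labeled.loc[sub.index]
        )
        _km_plot(cms_curves, out / "km_cms.png", "overall survival by CMS class")
        artifacts["cms_survival"] = {"curves": cms_curves, "logrank": cms_lr}

    # ---- recovery (synthetic only) ----------------------------------------
    if cohort is not None:
        lr = artifacts.get("quartile_survival", {}).get("logrank")
        report = recovery_report(
            cohort, scores=score_table.scores, cms_labels=cms.labels, logrank_result=lr
        )
        (out / "recovery.json").write_text(json.dumps(report, indent=2, default=str))
        artifacts["recovery"] = report

    (out / "run_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=False)
    )
    return artifacts
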