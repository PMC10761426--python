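"""End-to-end orchestration: preprocess -> integrate -> metabotype.

A single :class:`PipelineConfig` drives the whole workflow; every numeric
artefact (retained-variable lists, loadings, factor scores, labels, the run
report) can be written to an output directory tagged with the seed and a
hash of the configuration, so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrate, metabotype, preprocess
from .data_model import StudyBundle, align_study_samples
from .preprocess import PreprocessParams

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline."""

    matrix_paths: list[str] = dataclasses.field(default_factory=list)
    metadata_path: str | None = None
    is_features: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    knn_k: int = 5
    max_cv_pct: float = 30.0
    svrc_C: float | str = "auto"
    svrc_epsilon: float | str = "auto"
    svrc_gamma: float | str = "auto"
    outlier_alpha: float = 0.05
    outlier_log10: bool = True
    drop_outliers: bool = False
    decorrelation_threshold: float = 0.9
    retention_threshold: float = 0.5
    retention_gap: float = 0.1
    min_cum_var: float = 0.60
    candidate_k: tuple[int, ...] = (2, 3, 4)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.decorrelation_threshold <= 1:
            raise ValueError("decorrelation_threshold must be in (0, 1]")
        if not 0 < self.retention_threshold < 1:
            raise ValueError("retention_threshold must be in (0, 1)")
        if self.retention_gap < 0 or self.min_cum_var <= 0:
            raise ValueError("invalid retention_gap / min_cum_var")

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            knn_k=self.knn_k, max_cv_pct=self.max_cv_pct,
            svrc_C=self.svrc_C, svrc_epsilon=self.svrc_epsilon,
            svrc_gamma=self.svrc_gamma, outlier_alpha=self.outlier_alpha,
            outlier_log10=self.outlier_log10, drop_outliers=self.drop_outliers)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "candidate_k" in raw:
            raw["candidate_k"] = tuple(raw["candidate_k"])
        return cls(**raw)


@dataclasses.dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    bundle: StudyBundle                       # preprocessed + aligned
    preprocess_reports: dict
    decorrelation: list
    cascades: dict
    combined_model: integrate.ComponentModel
    combined_decisions: list
    scores: integrate.FactorScores
    metabotypes: metabotype.MetabotypeResult
    clinical: pd.DataFrame | None
    report: dict


def _stage_report(result: PipelineResult, config: PipelineConfig) -> dict:
    counts = {}
    for pid, cas in result.cascades.items():
        counts[pid] = {
            "after_decorrelation": len(cas.pca_decisions) if cas.pca_model
            else 0,
            "after_pca_retention": len(integrate.retained_variables(
                cas.pca_decisions)),
            "after_fa_retention": cas.retained_table.shape[1],
        }
    final_members = {}
    for d in result.combined_decisions:
        if d.retained:
            final_members[d.variable] = int(d.assigned_component) + 1
    return {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_study_samples": len(result.scores.sample_ids),
        "feature_counts": counts,
        "n_factors": result.combined_model.n_components,
        "combined_kmo": float(result.combined_model.kmo),
        "combined_cumulative_variance":
            float(result.combined_model.cumulative_variance),
        "n_final_variables": len(final_members),
        "factor_membership": final_members,
        "loo_accuracy": {int(k): float(v)
                         for k, v in result.metabotypes.loo_accuracy.items()},
        "chosen_k": int(result.metabotypes.chosen_k),
        "metabotype_sizes": [int(s) for s in result.metabotypes.cluster_sizes],
        "factor_means": result.metabotypes.factor_means.round(4).to_dict(),
    }


def run_study(bundle: StudyBundle, config: PipelineConfig | None = None
              ) -> PipelineResult:
    """Run the whole workflow on an in-memory bundle."""
    config = config or PipelineConfig()
    pp = config.preprocess_params()

    processed = []
    reports = {}
    for m in bundle.matrices:
        cleaned, reps = preprocess.preprocess_platform(m, pp)
        processed.append(cleaned)
        reports[m.platform_id] = reps
    bundle = StudyBundle(matrices=processed, metadata=bundle.metadata)
    bundle = align_study_samples(bundle)
    shared = bundle.shared_study_ids()
    log.info("aligned %d shared study samples", len(shared))

    # log10-transform and standardize the study samples for integration
    tables = {}
    for m in bundle.matrices:
        vals = m.study_values().loc[shared]
        if (vals.to_numpy() <= 0).any():
            raise integrate.IntegrateError(
                f"{m.platform_id}: non-positive intensities before log10")
        tables[m.platform_id] = integrate.standardize(np.log10(vals))

    tables, decorr = integrate.decorrelate(
        tables, threshold=config.decorrelation_threshold)

    cascades = {}
    retained_tables = []
    for pid, table in tables.items():
        cas = integrate.cascade_reduce(
            table, platform_id=pid, threshold=config.retention_threshold,
            gap=config.retention_gap, min_cum_var=config.min_cum_var)
        cascades[pid] = cas
        if cas.retained_table.shape[1]:
            retained_tables.append(cas.retained_table)

    model, decisions = integrate.combined_fa(
        retained_tables, threshold=config.retention_threshold,
        gap=config.retention_gap, min_cum_var=config.min_cum_var)
    pooled = pd.concat(retained_tables, axis=1)
    scores = integrate.regression_scores(model, pooled)

    merges = metabotype.ward_cluster(scores)
    result_k = metabotype.choose_k_by_da(scores, merges,
                                         candidates=config.candidate_k)

    clinical = None
    if bundle.metadata is not None and len(bundle.metadata.columns):
        try:
            clinical = metabotype.compare_clinical(
                result_k.labels, bundle.metadata, alpha=config.alpha)
        except metabotype.MetabotypeError as e:
            log.warning("clinical comparison skipped: %s", e)

    result = PipelineResult(
        bundle=bundle, preprocess_reports=reports, decorrelation=decorr,
        cascades=cascades, combined_model=model,
        combined_decisions=decisions, scores=scores, metabotypes=result_k,
        clinical=clinical, report={})
    result.report = _stage_report(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig,
                  outdir: str | Path) -> None:
    """Persist the run's numeric artefacts (text formats only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = {"seed": config.seed, "config_hash": config.config_hash()}

    loadings = result.combined_model.loadings.round(6).copy()
    assigned = {d.variable: (d.assigned_component + 1 if d.retained else 0)
                for d in result.combined_decisions}
    loadings.insert(0, "assigned_factor",
                    [assigned[v] for v in loadings.index])
    loadings.to_csv(outdir / "combined_loadings.tsv", sep="\t",
                    index_label="variable")
    result.scores.scores.round(6).to_csv(outdir / "factor_scores.tsv",
                                         sep="\t", index_label="sample_id")
    result.metabotypes.labels.to_csv(outdir / "metabotypes.tsv", sep="\t",
                                     index_label="sample_id")
    result.metabotypes.factor_means.round(4).to_csv(
        outdir / "factor_means.tsv", sep="\t")
    if result.clinical is not None:
        result.clinical.to_csv(outdir / "clinical_comparison.tsv", sep="\t")
    (outdir / "report.json").write_text(
        json.dumps({**tag, **result.report}, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Read inputs per the config, run the workflow, write artefacts."""
    from .synthetic_data import read_bundle
    if not config.matrix_paths or config.metadata_path is None:
        raise ValueError("config must list matrix_paths and metadata_path")
    bundle = read_bundle(config.matrix_paths, config.metadata_path,
                         {k: tuple(v) for k, v in config.is_features.items()})
    result = run_study(bundle, config)
    if config.output_dir:
        write_outputs(result, config, config.output_dir)
    return result.report


def run_default_study(seed: int, config: PipelineConfig | None = None
                      ) -> tuple[PipelineResult, pd.DataFrame,
                                 "np.ndarray"]:
    """Simulate the default study at ``seed`` and run the workflow on it.

    Returns the pipeline result, the true latent factor scores and the true
    cluster assignment (1-based, aligned to the latent index).
    """
    from .synthetic_data import default_ground_truth, simulate_study
    truth = default_ground_truth(seed=seed)
    bundle, latent = simulate_study(truth)
    cfg = config or PipelineConfig(seed=seed)
    result = run_study(bundle, cfg)
    clusters = bundle.metadata.loc[latent.index, "true_metabotype"].to_numpy()
    return result, latent, clusters
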