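"""End-to-end pipeline: simulate/load -> calibrate -> match -> discover ->
train/score -> severity -> report.

Every stage writes its artifacts into the run directory and the
effective configuration is echoed there, so a run is reproducible from
(inputs, config, seed) alone.  Any stage failure raises
:class:`PipelineError` naming the stage; artifacts of completed stages
are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from . import core, discovery, diagnostic, evaluation, severity as sev
from .cohort import CohortConfig, generate_cohort

log = logging.getLogger("pkdpeptidome")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Run settings for the full pipeline (all thresholds config-exposed)."""

    out_dir: str = "run"
    # inputs; when peak_table is None a synthetic cohort is simulated
    peak_table: str | None = None
    metadata_table: str | None = None
    tkv_table: str | None = None
    standards_table: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # matching / calibration
    mass_rel: float = 1e-4
    time_abs: float = 0.5
    min_standards: int = 3
    # discovery
    q_threshold: float = 0.05
    min_freq: float = 0.3
    max_panel: int = 142
    # diagnostic model
    C_grid: tuple = (diagnostic.PRESET_C,)
    gamma_grid: tuple = (diagnostic.PRESET_GAMMA,)
    cv: str | int = "loo"
    class_weight: str | None = "balanced"
    # severity
    r_threshold: float = 0.25
    severity_method: str = "ols"
    severity_train_frac: float = 0.46
    # reporting
    report_cutoffs: tuple = ()
    seed: int = 0
    overwrite: bool = True

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "wt") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            doc = yaml.safe_load(fh) or {}
        if "cohort" in doc and isinstance(doc["cohort"], dict):
            for key in ("fold_range", "detect_freq_beta", "height_range",
                        "time_shift_range", "time_scale_range",
                        "intensity_scale_range"):
                if key in doc["cohort"] and doc["cohort"][key] is not None:
                    doc["cohort"][key] = tuple(doc["cohort"][key])
            doc["cohort"] = CohortConfig(**doc["cohort"])
        for key in ("C_grid", "gamma_grid", "report_cutoffs"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = _time.time()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done in %.1fs", name, _time.time() - t0)
            return result
        return inner
    return wrap


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    samples, truth = generate_cohort(cohort_cfg)
    core.write_peak_table(samples, out / "peaks.tsv")
    core.write_metadata_table(
        {s.sample_id: s.metadata for s in samples},
        out / "metadata.tsv", out / "tkv.tsv",
    )
    truth.peptides.to_csv(out / "truth_peptides.tsv", sep="\t", index=False)
    truth.standards.to_csv(out / "standards.tsv", sep="\t", index=False)
    truth.drift.to_csv(out / "truth_drift.tsv", sep="\t")
    return samples, truth.standards


@_stage("load")
def _load(config: PipelineConfig):
    samples = core.read_peak_table(
        config.peak_table, config.metadata_table, config.tkv_table
    )
    if config.standards_table is None:
        raise ValueError("standards_table required when loading real peak data")
    standards = pd.read_csv(config.standards_table, sep="\t")
    return samples, standards


@_stage("calibrate")
def _calibrate(config: PipelineConfig, out: Path, samples, standards):
    tol = cal.MatchTolerances(config.mass_rel, config.time_abs)
    normalized, records, failed = cal.calibrate_cohort(
        samples, standards, tol, config.min_standards
    )
    cal.records_to_frame(records).to_csv(out / "calibration.tsv", sep="\t", index=False)
    if failed:
        log.warning("calibration excluded %d sample(s): %s", len(failed), failed)
    if not normalized:
        raise ValueError("no sample survived calibration")
    return normalized


@_stage("match")
def _match(config: PipelineConfig, out: Path, normalized):
    tol = cal.MatchTolerances(config.mass_rel, config.time_abs)
    catalog, matrix = cal.match_peptides(normalized, tol)
    core.write_matrix(matrix, out / "matrix.tsv", catalog, overwrite=config.overwrite)
    return catalog, matrix


@_stage("discover")
def _discover(config: PipelineConfig, out: Path, matrix):
    result = discovery.differential_stats(matrix, min_freq=config.min_freq)
    result.stats.to_csv(out / "marker_stats.tsv", sep="\t", index=False)
    markers = discovery.select_markers(result, config.q_threshold)
    (out / "markers.json").write_text(json.dumps(markers))
    log.info("discovery: %d significant markers at q<%g", len(markers), config.q_threshold)
    return result, markers


@_stage("train")
def _train(config: PipelineConfig, out: Path, matrix, markers):
    if not markers:
        raise ValueError(
            f"no markers significant at q<{config.q_threshold}; cannot train"
        )
    panel = markers[: config.max_panel]
    model, cv_scores = diagnostic.train_svm(
        matrix, markers=panel, C_grid=config.C_grid, gamma_grid=config.gamma_grid,
        cv=config.cv, class_weight=config.class_weight, seed=config.seed,
    )
    y = matrix.labels
    model.cutoff = diagnostic.choose_cutoff(
        pd.Series(cv_scores, index=matrix.values.index), y
    )
    model.to_json(out / "diagnostic_model.json")
    pd.DataFrame(
        dict(sample_id=matrix.sample_ids, cv_score=cv_scores)
    ).to_csv(out / "cv_scores.tsv", sep="\t", index=False)
    log.info("train: panel=%d cv_auc=%.3f cutoff=%.3f",
             len(panel), model.cv_auc, model.cutoff)
    return model


@_stage("score")
def _score(config: PipelineConfig, out: Path, model, matrix):
    scores = diagnostic.score_samples(model, matrix)
    calls = scores >= model.cutoff
    pd.DataFrame(
        dict(sample_id=scores.index, score=scores.to_numpy(),
             call=np.where(calls, "ADPKD", "negative"))
    ).to_csv(out / "scores.tsv", sep="\t", index=False)
    return scores


@_stage("severity")
def _severity(config: PipelineConfig, out: Path, matrix, metadata):
    httkv = pd.Series(
        {sid: md.httkv for sid, md in metadata.items() if md.httkv is not None},
        dtype=float,
    )
    httkv = httkv.reindex(matrix.values.index).dropna()
    if len(httkv) < 20:
        log.warning("severity: only %d samples with htTKV; stage skipped", len(httkv))
        return None
    rng = np.random.default_rng(config.seed)
    ids = httkv.index.to_numpy()
    rng.shuffle(ids)
    n_train = max(10, int(round(config.severity_train_frac * len(ids))))
    train_ids, test_ids = ids[:n_train], ids[n_train:]
    sub_train = core.IntensityMatrix(matrix.values.loc[train_ids])
    screened = sev.screen_spearman(sub_train, httkv[train_ids], config.r_threshold)
    if screened.empty:
        log.warning("severity: no peptide passed |r|>%g; stage skipped",
                    config.r_threshold)
        return None
    model = sev.fit_severity(sub_train, httkv[train_ids], screened,
                             method=config.severity_method)
    model.to_json(out / "severity_model.json")
    screened.to_csv(out / "severity_screen.tsv", sep="\t", index=False)
    result = dict(train=dict(n=len(train_ids),
                             pearson_r=model.train_pearson,
                             spearman_r=model.train_spearman))
    if len(test_ids) >= 10:
        sub_test = core.IntensityMatrix(matrix.values.loc[test_ids])
        result["test"] = sev.evaluate_severity(model, sub_test, httkv[test_ids])
        pred = sev.predict_severity(model, sub_test)
        _scatter_plot(pred, httkv[test_ids], out / "severity_scatter.png")
    (out / "severity_eval.json").write_text(json.dumps(result, indent=1))
    log.info("severity: %s", result)
    return model


def _scatter_plot(pred: pd.Series, obs: pd.Series, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = pred.index.intersection(obs.index)
    x, y = pred[common], obs[common]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    if len(common) > 1 and np.ptp(x) > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, b * xs + a, color="crimson")
    ax.set_xlabel("severity score (predicted htTKV, ml/m)")
    ax.set_ylabel("observed htTKV (ml/m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@_stage("report")
def _report(config: PipelineConfig, out: Path, scores, matrix, metadata, model):
    labels = matrix.labels
    auc, ci, curve = evaluation.roc_auc(scores, labels)
    curve.to_csv(out / "roc.tsv", sep="\t", index=False)
    _roc_plot(curve, auc, ci, out / "roc.png")
    cutoffs = list(config.report_cutoffs) or [model.cutoff]
    meta_df = pd.DataFrame(
        {sid: dict(age=md.age, genotype=md.genotype) for sid, md in metadata.items()}
    ).T
    table4 = evaluation.subgroup_report(scores, labels, meta_df, cutoffs)
    table4.to_csv(out / "subgroups.tsv", sep="\t", index=False)
    op = evaluation.operating_point(scores, labels, cutoffs[0])
    clin = pd.DataFrame(
        {
            sid: dict(
                tkv=md.tkv_series[0][1] if md.tkv_series else np.nan,
                httkv=md.httkv if md.httkv is not None else np.nan,
                egfr=md.egfr if md.egfr is not None else np.nan,
            )
            for sid, md in metadata.items()
        }
    ).T
    growth = {}
    for sid, md in metadata.items():
        if md.tkv_series and md.height:
            g = evaluation.tkv_growth(md.tkv_series, md.height, min_points=2)
            growth[sid] = dict(tkv_change_ml_yr=g["abs_rate"], tkv_change_pct_yr=g["rel_rate"])
    if growth:
        clin = clin.join(pd.DataFrame(growth).T)
    case_scores = scores[labels.reindex(scores.index) == "ADPKD"]
    corr = evaluation.correlate_clinical(case_scores, clin)
    corr.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)

    lines = [
        "# Pipeline report",
        "",
        f"- samples: {len(scores)} ({int((labels == 'ADPKD').sum())} ADPKD)",
        f"- AUC: {auc:.3f} (95% CI {ci[0]:.3f}-{ci[1]:.3f})",
        f"- cutoff {op.cutoff:.3f}: sensitivity {100 * op.sensitivity:.1f}% "
        f"(95% CI {100 * op.sensitivity_ci[0]:.1f}-{100 * op.sensitivity_ci[1]:.1f}), "
        f"specificity {100 * op.specificity:.1f}% "
        f"(95% CI {100 * op.specificity_ci[0]:.1f}-{100 * op.specificity_ci[1]:.1f})",
        "",
        "See roc.tsv, subgroups.tsv, clinical_correlations.tsv for tables.",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    summary = dict(auc=auc, auc_ci=list(ci), **op.as_dict())
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _roc_plot(curve: pd.DataFrame, auc: float, ci, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve["fpr"], curve["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC {auc:.3f} (95% CI {ci[0]:.3f}-{ci[1]:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run(config: PipelineConfig, out: Path) -> Path:
    if config.peak_table is None:
        samples, standards = _simulate(config, out)
    else:
        samples, standards = _load(config)
    metadata = {s.sample_id: s.metadata for s in samples if s.metadata is not None}
    normalized = _calibrate(config, out, samples, standards)
    catalog, matrix = _match(config, out, normalized)
    result, markers = _discover(config, out, matrix)
    model = _train(config, out, matrix, markers)
    scores = _score(config, out, model, matrix)
    if metadata:
        case_meta = {sid: md for sid, md in metadata.items() if md.diagnosis == "ADPKD"}
        _severity(config, out, matrix, case_meta)
        _report(config, out, scores, matrix, metadata, model)
    return out
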