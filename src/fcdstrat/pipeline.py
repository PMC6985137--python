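"""Config-driven orchestration of the full stratification analysis.

``run_pipeline`` executes: cohort simulation -> BOLD preprocessing (frame
trimming, tCompCor, band-pass) -> FCD maps -> task slopes -> robust PCA ->
discretization -> LOSO-CV stratification per measure -> pre-HD-vs-control
classification -> test-retest reliability -> optional confound-control
variants.  All stages are deterministic given the config and seed; outputs
are JSON reports, CSV tables and (optionally) NIfTI maps in the run
directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (CohortConfig, SubjectRecord, TaskSpec, cohort_structure,
                     generate_cohort, generate_task_scores, generate_gmc,
                     iter_bold)
from .confounds import ComBatHarmonizer, GmcResidualizer, MotionDetrender
from .fcd import (bandpass, compute_fcd, discard_initial_frames, smooth_map,
                  tcompcor_denoise, write_map_nifti)
from .reliability import (fingerprint, outcome_labels, transition_matrix,
                          transition_null)
from .stratify import (AgeSexCorrector, DeclineLabels, ModelSpec, discretize,
                       evaluate_stratification, loso_cv)
from .trajectories import (iqr_normalize, residualize_on_controls, robust_pca,
                           slopes_from_panel)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "preprocess_bold",
    "compute_cohort_fcd",
    "read_cognitive_table",
    "write_report",
]

log = logging.getLogger("fcdstrat")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything a run needs; serializable and reproducible."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    outdir: str = "fcdstrat_run"
    n_perm: int = 1000
    n_boot: int = 1000
    measures: tuple = ("tasks", "pcs")   # what to stratify on
    n_pcs: int = 5
    run_group_classification: bool = True
    run_reliability: bool = True
    run_confound_controls: bool = False
    visit_for_features: int = 1
    fast_model: bool = True              # reduced hyper-grid
    save_nifti: bool = False
    log_level: str = "INFO"

    def model_spec(self) -> ModelSpec:
        return ModelSpec.fast() if self.fast_model else ModelSpec()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["tasks"] = [dataclasses.asdict(t) for t in self.cohort.tasks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        tasks = cohort.pop("tasks", None)
        cfg = CohortConfig(**cohort) if tasks is None else CohortConfig(
            **cohort, tasks=[TaskSpec(**{**t, "visit_count_range":
                                         tuple(t["visit_count_range"])})
                             for t in tasks])
        for key in ("measures",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(cohort=cfg, **d)


def preprocess_bold(series, n_discard: int = 5, mask_fraction: float = 0.02,
                    n_components: int = 5, low: float = 0.01,
                    high: float = 0.16):
    """The computational preprocessing chain: trim, tCompCor, band-pass."""
    series = discard_initial_frames(series, n_discard=n_discard)
    series = tcompcor_denoise(series, mask_fraction=mask_fraction,
                              n_components=n_components)
    return bandpass(series, low=low, high=high)


def compute_cohort_fcd(cohort, config: CohortConfig, seed: int,
                       visit: int = 1, structure=None
                       ) -> tuple[np.ndarray, object]:
    """Subjects x voxels matrix of unsmoothed FCD values for one visit."""
    if structure is None:
        structure = cohort_structure(cohort, config, seed)
    maps = np.empty((len(cohort), config.n_voxels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, (record, series) in enumerate(
                iter_bold(cohort, config, seed, visits=(visit,), structure=structure)):
            clean = preprocess_bold(series)
            maps[i] = compute_fcd(clean).values
    return maps, structure


def _cohort_meta(cohort: list[SubjectRecord], visit: int = 1) -> pd.DataFrame:
    return pd.DataFrame({
        "row": np.arange(len(cohort)),
        "subject_id": [r.subject_id for r in cohort],
        "site": [r.site for r in cohort],
        "group": [r.group for r in cohort],
        "sex": [r.sex for r in cohort],
        "age": [r.age for r in cohort],
        "cag": [r.cag if r.cag is not None else np.nan for r in cohort],
        "fd_mean": [r.fd_mean.get(visit, np.nan) for r in cohort],
    })


def read_cognitive_table(path) -> pd.DataFrame:
    """Validated long-format cognitive panel from CSV.

    Requires columns subject_id, site, group, sex, age, cag, task,
    visit_date, score.  Dates are parsed and converted to fractional years
    from each subject-task's first visit (``time_years``).
    """
    panel = pd.read_csv(path, dtype={"subject_id": str, "task": str})
    required = {"subject_id", "site", "group", "sex", "age", "cag", "task",
                "visit_date", "score"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"cognitive table is missing columns {sorted(missing)}")
    dup = panel.duplicated(subset=["subject_id", "task", "visit_date"])
    if dup.any():
        row = panel[dup].iloc[0]
        raise ValueError(
            "duplicate visit row for subject "
            f"{row['subject_id']!r}, task {row['task']!r}, "
            f"visit {row['visit_date']!r}")
    dates = pd.to_datetime(panel["visit_date"])
    first = dates.groupby([panel["subject_id"], panel["task"]]).transform("min")
    panel["time_years"] = (dates - first).dt.days / 365.25
    return panel


def write_report(report: dict, path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    log.info("fcdstrat %s | seed=%d | python %s", __version__, config.seed,
             sys.version.split()[0])
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=_json_default))

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        cohort = generate_cohort(config.cohort)
        panel = generate_task_scores(cohort, config.cohort, config.seed)
        panel.to_csv(outdir / "cognitive_panel.csv", index=False)
        meta = _cohort_meta(cohort, visit=config.visit_for_features)
        meta.assign(latent_decline=[r.latent_decline for r in cohort]).to_csv(
            outdir / "subjects.csv", index=False)

        stage("fcd")
        fcd_v1, structure = compute_cohort_fcd(
            cohort, config.cohort, config.seed, visit=config.visit_for_features)
        features = fcd_v1

        stage("slopes")
        orient = {t.name: t.decline_sign for t in config.cohort.tasks}
        task_names = [t.name for t in config.cohort.tasks]
        slopes = slopes_from_panel(panel, tasks=task_names, orient=orient)
        slopes = slopes.reindex([r.subject_id for r in cohort])
        age = pd.Series({r.subject_id: r.age for r in cohort})
        sex = pd.Series({r.subject_id: r.sex for r in cohort})
        control_ids = [r.subject_id for r in cohort if not r.is_prehd]
        prehd_ids = [r.subject_id for r in cohort if r.is_prehd]
        corrected = residualize_on_controls(slopes, age, sex, control_ids)
        normalized = iqr_normalize(corrected)
        normalized.to_csv(outdir / "slopes_corrected_iqr.csv")

        stage("pca")
        pc_scores = None
        if "pcs" in config.measures:
            pc_model = robust_pca(normalized, population="preHD_only",
                                  fit_ids=prehd_ids, n_components=config.n_pcs,
                                  seed=config.seed)
            pc_scores = pc_model.project(normalized.dropna(axis=0))
            pd.DataFrame(pc_model.loadings[:, :config.n_pcs],
                         index=normalized.columns,
                         columns=[f"PC{i+1}" for i in range(config.n_pcs)]
                         ).to_csv(outdir / "pc_loadings.csv")

        stage("stratify")
        prehd_mask = meta["group"].values == "preHD"
        sites = meta["site"].values
        measures: dict[str, pd.Series] = {}
        if "tasks" in config.measures:
            for t in task_names:
                measures[t] = normalized[t]
        if pc_scores is not None:
            for c in pc_scores.columns:
                measures[c] = pc_scores[c]

        rows = []
        reports = {}
        loso_results = {}
        for name, series in measures.items():
            vals = series.reindex(meta["subject_id"]).values.astype(float)
            vals_prehd = pd.Series(np.where(prehd_mask, vals, np.nan),
                                   index=meta.index)
            if vals_prehd.dropna().size < 8:
                log.warning("measure %s: too few pre-HD values; skipped", name)
                continue
            labels = discretize(vals_prehd.dropna(), measure=name)
            full_labels = DeclineLabels(
                measure=name, values=vals_prehd,
                labels=labels.labels.reindex(meta.index).fillna("intermediate"),
                median=labels.median, robust_sd=labels.robust_sd)
            result = loso_cv(features, full_labels.binary().values, sites,
                             model_spec=config.model_spec(), meta=meta,
                             seed=config.seed)
            report = evaluate_stratification(
                result, full_labels, eval_mask=prehd_mask,
                n_perm=config.n_perm, n_boot=config.n_boot, seed=config.seed)
            reports[name] = report
            loso_results[name] = result
            rows.append({"measure": name, "auc": report.site_avg_auc,
                         "auc_p": report.auc_permutation_p,
                         "spearman": report.pooled_spearman,
                         "spearman_p": report.spearman_permutation_p})
        per_measure = pd.DataFrame(rows)
        per_measure.to_csv(outdir / "stratification_table.csv", index=False)
        write_report({"stratification": {k: r.to_dict()
                                         for k, r in reports.items()}},
                     outdir / "stratification_report.json")

        group_result = None
        if config.run_group_classification:
            stage("group_classification")
            y_group = prehd_mask.astype(float)
            group_result = loso_cv(
                features, y_group, sites, model_spec=config.model_spec(),
                meta=meta, preprocessor_factories=(AgeSexCorrector,),
                seed=config.seed)
            from .stratify import permutation_pvalue, site_avg_auc
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                auc, boot, per_site = site_avg_auc(
                    group_result.decisions, y_group, sites,
                    n_boot=config.n_boot, seed=config.seed)

                def stat(perm_y):
                    m, _, _ = site_avg_auc(group_result.decisions, perm_y,
                                           sites, n_boot=0, seed=0)
                    return m

                p = permutation_pvalue(auc, stat, y_group, sites,
                                       n_perm=config.n_perm, seed=config.seed)
            write_report({"group_classification": {
                "site_avg_auc": auc, "bootstrap_median_auc": boot,
                "per_site_auc": {str(k): v for k, v in per_site.items()},
                "permutation_p": p}}, outdir / "group_report.json")

        if config.run_reliability:
            stage("reliability")
            fcd_v2, _ = compute_cohort_fcd(cohort, config.cohort, config.seed,
                                           visit=2, structure=structure)
            fp = fingerprint(fcd_v1, fcd_v2)
            rel_report = {"fingerprint": {
                "identification_rate": fp.identification_rate,
                "chance_level": fp.chance_level,
                "mean_self_rank": float(fp.self_ranks.mean())}}
            if group_result is not None:
                truth = prehd_mask.astype(int)
                pred1 = _predict_by_heldout_site(group_result, fcd_v1, sites, meta)
                pred2 = _predict_by_heldout_site(group_result, fcd_v2, sites, meta)
                out1 = outcome_labels(pred1, truth)
                out2 = outcome_labels(pred2, truth)
                tm = transition_matrix(out1, out2)
                chance, pvals = transition_null(
                    out1, out2, meta["group"].values,
                    n_perm=config.n_perm, seed=config.seed)
                rel_report["transition"] = {
                    "matrix": tm.probabilities, "counts": tm.counts,
                    "chance_matrix": chance, "diagonal_p": pvals,
                    "outcomes": list(tm.outcomes)}
            write_report(rel_report, outdir / "reliability_report.json")

        if config.run_confound_controls and reports:
            stage("confound_controls")
            gmc = generate_gmc(cohort, config.cohort, config.seed)
            best = per_measure.sort_values("auc", ascending=False).iloc[0]["measure"]
            series = measures[best]
            vals = series.reindex(meta["subject_id"]).values.astype(float)
            vals_prehd = pd.Series(np.where(prehd_mask, vals, np.nan),
                                   index=meta.index)
            labels = discretize(vals_prehd.dropna(), measure=best)
            full_labels = DeclineLabels(
                measure=best, values=vals_prehd,
                labels=labels.labels.reindex(meta.index).fillna("intermediate"),
                median=labels.median, robust_sd=labels.robust_sd)
            variants = {
                "combat": (ComBatHarmonizer,),
                "gmc_residualized": (lambda: GmcResidualizer(gmc),),
                "motion_detrended": (MotionDetrender,),
            }
            conf_reports = {}
            for vname, factories in variants.items():
                res = loso_cv(features, full_labels.binary().values, sites,
                              model_spec=config.model_spec(), meta=meta,
                              preprocessor_factories=factories,
                              seed=config.seed)
                rep = evaluate_stratification(
                    res, full_labels, eval_mask=prehd_mask,
                    n_perm=config.n_perm, n_boot=config.n_boot,
                    seed=config.seed)
                conf_reports[vname] = rep.to_dict()
            from .confounds import gmc_only_classifier
            _, gmc_rep = gmc_only_classifier(
                gmc, full_labels.binary().values, sites,
                model_spec=config.model_spec(), meta=meta,
                n_perm=config.n_perm, n_boot=config.n_boot, seed=config.seed)
            conf_reports["gmc_only"] = gmc_rep
            write_report({"confound_controls": conf_reports,
                          "measure": best},
                         outdir / "confound_report.json")

        if config.save_nifti:
            stage("export")
            from .fcd import FcdMap
            mean_map = FcdMap(values=fcd_v1.mean(axis=0),
                              coords=structure.coords, shape=structure.shape)
            write_map_nifti(mean_map, outdir / "mean_fcd_visit1.nii.gz")
            write_map_nifti(smooth_map(mean_map),
                            outdir / "mean_fcd_visit1_smoothed.nii.gz")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    return outdir


def _predict_by_heldout_site(result, maps: np.ndarray, sites,
                             meta: pd.DataFrame) -> np.ndarray:
    """Score each subject's map with the model whose held-out site is theirs."""
    pred = np.zeros(len(maps), dtype=int)
    for s, model in result.models.items():
        m = sites == s
        d = model.decision_values(maps[m], meta[m].reset_index(drop=True))
        pred[m] = (d > 0).astype(int)
    return pred
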