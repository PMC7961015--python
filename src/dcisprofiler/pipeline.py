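"""End-to-end orchestration: simulate -> QC -> preprocess -> univariate ->
cluster -> Escore -> survival, with persisted intermediates and a run
report.  Every stage is also callable on its own from the library; the
pipeline just wires them together, records the filtering audit at each
stage, and keeps everything deterministic under one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_qc, clustering, preprocess, survival, univariate
from . import escore_model as escore
from .errors import DcisProfilerError
from .synthetic_cohort import (Cohort, SimulationConfig, default_archetypes,
                               generate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    outdir: str | Path = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig | None = None  # None -> read tables from paths
    cells_path: str | None = None
    patients_path: str | None = None
    fovs_path: str | None = None
    panel_path: str | None = None
    qc: cell_qc.QcCriteria = field(default_factory=cell_qc.QcCriteria)
    log2_offset: float = 1.0
    cap_tail: float = 0.01
    #: fixed k; None -> select k by consensus PAC over k_range
    cluster_k: int | None = None
    k_range: tuple[int, int] = (2, 15)
    consensus_reps: int = 100
    consensus_subsample: float = 0.8
    consensus_cells: int | None = 10000  # subsample for the consensus sweep
    kmeans_restarts: int = 10
    use_published_escore: bool = False
    fdr_q: float = 0.2


@dataclass
class RunResult:
    cohort: Cohort | None
    audit: cell_qc.FilterAudit
    univariate: pd.DataFrame
    cluster_model: clustering.ClusterModel
    consensus: clustering.ConsensusResult | None
    profiles: pd.DataFrame
    escore_model: escore.EscoreModel
    predictions: pd.DataFrame
    metrics: escore.ClassificationMetrics
    loocv: escore.LoocvResult
    logrank: survival.LogRankResult
    report: dict


def _load_tables(config: RunConfig):
    if config.simulation is not None:
        sim = config.simulation
        cohort = generate_cohort(sim)
        return cohort, cohort.cells, cohort.patients, cohort.fovs, cohort.panel
    if not all([config.cells_path, config.patients_path, config.fovs_path,
                config.panel_path]):
        raise DcisProfilerError(
            "run needs either a simulation config or all four input paths")
    cells = pd.read_csv(config.cells_path)
    patients = pd.read_csv(config.patients_path)
    fovs = pd.read_csv(config.fovs_path)
    panel = preprocess.MarkerPanel.from_csv(config.panel_path)
    return None, cells, patients, fovs, panel


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis; writes all intermediates under ``outdir``.

    Raises with the failing stage's name in the message; outputs of the
    stages already completed remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage = "load"
    try:
        cohort, cells, patients, fovs, panel = _load_tables(config)
        if cohort is not None:
            cohort.save(outdir / "simulated")

        stage = "qc"
        cells_f, patients_f, fovs_f, audit = cell_qc.apply_qc(
            cells, fovs, patients, config.qc)
        audit.log()
        audit.to_frame().to_csv(outdir / "filter_audit.csv", index=False)
        cells_f.to_csv(outdir / "cells_filtered.csv", index=False)
        if len(cells_f) == 0 or len(patients_f) == 0:
            raise DcisProfilerError("no cells or patients survive QC")

        stage = "preprocess"
        norm = preprocess.preprocess_cells(cells_f, panel,
                                           log2_offset=config.log2_offset,
                                           tail=config.cap_tail)
        norm.values.assign(cell_id=cells_f["cell_id"].to_numpy()).to_csv(
            outdir / "normalized_values.csv", index=False)
        with open(outdir / "transform_params.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(norm.params_dict(), fh)

        stage = "univariate"
        outcomes = patients_f.set_index("patient_id")["bce"].astype(bool)
        patient_vals = univariate.aggregate_patients(
            norm.values, cells_f["patient_id"])
        patient_vals = patient_vals.loc[
            patient_vals.index.isin(outcomes.index)]
        uni = univariate.compare_groups(patient_vals, outcomes, q=config.fdr_q)
        uni.to_csv(outdir / "univariate.csv", index=False)

        stage = "cluster"
        consensus = None
        z = norm.z
        if config.cluster_k is None:
            n_sub = config.consensus_cells
            if n_sub is not None and n_sub < len(z):
                idx = rng.choice(len(z), size=n_sub, replace=False)
                z_cons = z.iloc[idx]
            else:
                z_cons = z
            consensus = clustering.consensus_cluster(
                z_cons, k_range=range(config.k_range[0], config.k_range[1] + 1),
                reps=config.consensus_reps,
                subsample_fraction=config.consensus_subsample,
                seed=int(rng.integers(2 ** 31)))
            pd.DataFrame({"k": list(consensus.pac),
                          "pac": list(consensus.pac.values())}).to_csv(
                outdir / "pac.csv", index=False)
            k = consensus.chosen_k
        else:
            k = config.cluster_k
        model = clustering.kmeans_fit(z, k, seed=int(rng.integers(2 ** 31)),
                                      restarts=config.kmeans_restarts)
        if k == 6:
            model, _ = clustering.canonicalize_labels(model, default_archetypes())
        labels = clustering.assign_clusters(model, z)
        assignments = pd.DataFrame({
            "cell_id": cells_f["cell_id"].to_numpy(),
            "patient_id": cells_f["patient_id"].to_numpy(),
            "core_id": cells_f["core_id"].to_numpy()
            if "core_id" in cells_f.columns else "",
            "cluster": labels})
        assignments.to_csv(outdir / "assignments.csv", index=False)

        stage = "escore"
        profiles = escore.cluster_profiles(assignments, k=k)
        profiles.to_csv(outdir / "profiles.csv")
        outcomes = outcomes.reindex(profiles.index)
        if config.use_published_escore:
            emodel = escore.PUBLISHED_ESCORE
        else:
            emodel = escore.fit_escore(profiles, outcomes)
        cov = escore.escore_covariates(profiles)
        scores = escore.escore(profiles, emodel)
        high = escore.classify(scores, emodel)
        predictions = pd.DataFrame({
            "pct_c56": cov["pct_c56"], "pct_c24": cov["pct_c24"],
            "escore": scores,
            "probability": emodel.predict_proba(cov["pct_c56"], cov["pct_c24"]),
            "high_risk": high, "bce": outcomes})
        predictions.to_csv(outdir / "predictions.csv")
        metrics = escore.evaluate(scores, outcomes, emodel)
        cv = escore.loocv(profiles, outcomes)
        with open(outdir / "escore_model.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({**emodel.to_dict(), "seed": config.seed}, fh)

        stage = "survival"
        surv = survival.survival_table(patients_f.set_index("patient_id")
                                       .loc[profiles.index].reset_index(),
                                       pd.Series(high, index=profiles.index))
        surv.to_csv(outdir / "survival.csv")
        lr = survival.logrank(surv["time"], surv["event"], surv["group"])
        km_high = survival.km_estimate(
            surv.loc[surv["group"] == "high", "time"],
            surv.loc[surv["group"] == "high", "event"])
        km_low = survival.km_estimate(
            surv.loc[surv["group"] == "low", "time"],
            surv.loc[surv["group"] == "low", "event"])
        km_high.assign(group="high").pipe(
            lambda a: pd.concat([a, km_low.assign(group="low")])
        ).to_csv(outdir / "km_curves.csv", index=False)

        report = {
            "seed": config.seed,
            "stages": audit.to_frame().to_dict(orient="records"),
            "n_patients_analyzed": int(len(profiles)),
            "n_cells_analyzed": int(len(cells_f)),
            "chosen_k": int(k),
            "pac": {int(kk): float(v) for kk, v in consensus.pac.items()}
            if consensus else None,
            "escore_model": emodel.to_dict(),
            "metrics": metrics.to_dict(),
            "loocv_auc": cv.auc,
            "loocv_failed_folds": cv.n_failed,
            "logrank": {"statistic": lr.statistic, "df": lr.df, "p": lr.p},
        }
        with open(outdir / "run_report.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
    except DcisProfilerError as exc:
        raise DcisProfilerError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return RunResult(cohort=cohort, audit=audit, univariate=uni,
                     cluster_model=model, consensus=consensus,
                     profiles=profiles, escore_model=emodel,
                     predictions=predictions, metrics=metrics, loocv=cv,
                     logrank=lr, report=report)
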