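"""Cell-, FOV- and patient-level quality filtering with an audit trail.

Filtering rules for iteratively stained multiplexed-immunofluorescence
single-cell tables:

* cells: epithelial, 1-2 nuclei, each sub-cellular compartment area
  strictly between 10 and 1500 pixels, and perfect round-to-round
  registration (per-cell QC score, the Pearson correlation of the baseline
  nuclear image with each round's, must reach the threshold in every round);
* fields of view: manual quality pass and DCIS fraction
  ``%DCIS / (%DCIS + %Normal) >= 0.5``;
* patients (outcome analysis): at least 100 retained cells, non-event
  patients followed >= 3 years, event patients with the event < 10 years
  (later events are treated as probable second primaries and excluded).

Every stage reports a :class:`FilterAudit` with conserved counts
(input = excluded + output) and per-rule tallies; a cell failing several
rules is tallied under each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: float tolerance when comparing registration summaries to the threshold
REGISTRATION_TOL = 1e-9


@dataclass
class QcCriteria:
    """Thresholds for all filtering rules (defaults = study rules)."""

    nuclei_min: int = 1
    nuclei_max: int = 2
    area_min_px: float = 10.0  # exclusive
    area_max_px: float = 1500.0  # exclusive
    registration_threshold: float = 1.0
    dcis_fraction_min: float = 0.5
    min_cells_per_patient: int = 100
    nonbce_min_followup_years: float = 3.0
    bce_max_followup_years: float = 10.0

    def __post_init__(self):
        if self.nuclei_min > self.nuclei_max:
            raise DataError("nuclei_min must be <= nuclei_max")
        if self.area_min_px >= self.area_max_px:
            raise DataError("area_min_px must be < area_max_px")


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_excluded: int
    n_out: int
    rule_counts: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_in - self.n_excluded != self.n_out:
            raise DataError(f"stage {self.name}: counts not conserved")


@dataclass
class FilterAudit:
    """Ordered record of filtering stages with conserved counts."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        stage.check()
        if self.stages and self.stages[-1].n_out != stage.n_in:
            raise DataError(
                f"stage {stage.name}: input {stage.n_in} does not equal "
                f"previous output {self.stages[-1].n_out}")
        self.stages.append(stage)

    def extend(self, other: "FilterAudit") -> None:
        for stage in other.stages:
            self.add(stage)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            rows.append({"stage": s.name, "n_in": s.n_in,
                         "n_excluded": s.n_excluded, "n_out": s.n_out,
                         **{f"rule_{k}": v for k, v in s.rule_counts.items()}})
        return pd.DataFrame(rows)

    def log(self) -> None:
        for s in self.stages:
            logger.info("filter stage %-16s in=%-8d excluded=%-7d out=%-8d %s",
                        s.name, s.n_in, s.n_excluded, s.n_out,
                        dict(s.rule_counts))


# ---------------------------------------------------------------------------
# registration scoring


def score_registration(baseline: np.ndarray, round_patches) -> tuple[np.ndarray, float]:
    """Per-round registration score and summary.

    The score for a round is the Pearson correlation between the baseline
    nuclear patch and that round's patch, with negative correlations
    clipped to 0: a score of 1 means perfect registration, 0 means the cell
    was lost.  A zero-variance patch (blank image, i.e. complete signal
    loss) scores 0 with a warning.  The per-cell summary is the minimum
    over rounds, since the cell must stay aligned in every round.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size < 4:
        raise DataError("registration patches need >= 4 pixels")
    scores = []
    b = baseline.ravel()
    b_centered = b - b.mean()
    b_norm = np.sqrt((b_centered ** 2).sum())
    for patch in round_patches:
        p = np.asarray(patch, dtype=float).ravel()
        if p.shape != b.shape:
            raise DataError("round patch shape differs from baseline")
        p_centered = p - p.mean()
        p_norm = np.sqrt((p_centered ** 2).sum())
        if b_norm == 0 or p_norm == 0:
            warnings.warn("zero-variance patch: scoring 0 (complete signal loss)",
                          stacklevel=2)
            scores.append(0.0)
            continue
        r = float(b_centered @ p_centered / (b_norm * p_norm))
        scores.append(max(0.0, min(1.0, r)))
    scores = np.asarray(scores)
    return scores, float(scores.min()) if scores.size else 0.0


def registration_summary(cells: pd.DataFrame) -> pd.Series:
    """Minimum per-cell QC score across all ``qc_score_r*`` columns."""
    qc_cols = [c for c in cells.columns if c.startswith("qc_score_r")]
    if not qc_cols:
        raise DataError("cell table has no qc_score_r* columns")
    return cells[qc_cols].min(axis=1)


# ---------------------------------------------------------------------------
# filters

_CELL_REQUIRED = ("cell_id", "tissue_class", "n_nuclei", "area_nucleus_px",
                  "area_membrane_px", "area_cytoplasm_px")


def _require(df: pd.DataFrame, columns, id_col: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise DataError(f"required field {col!r} missing from table")
        bad = df[col].isna()
        if bad.any():
            ident = df.loc[bad, id_col].iloc[0] if id_col in df.columns else "?"
            raise DataError(f"{id_col}={ident}: missing value in field {col!r}")


def filter_cells(cells: pd.DataFrame,
                 criteria: QcCriteria | None = None) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the cell-level rules; returns (retained cells, audit).

    Rules (a cell may fail several; each failed rule is tallied):
    ``epithelial``, ``nuclei``, ``area`` (strict bounds on every
    compartment), ``registration`` (min round score >= threshold).
    """
    criteria = criteria or QcCriteria()
    _require(cells, _CELL_REQUIRED, "cell_id")
    summary = registration_summary(cells)

    ok_epi = cells["tissue_class"].eq("epithelial").to_numpy()
    nn = cells["n_nuclei"].to_numpy()
    ok_nuc = (nn >= criteria.nuclei_min) & (nn <= criteria.nuclei_max)
    ok_area = np.ones(len(cells), dtype=bool)
    for comp in ("area_nucleus_px", "area_membrane_px", "area_cytoplasm_px"):
        a = cells[comp].to_numpy(dtype=float)
        ok_area &= (a > criteria.area_min_px) & (a < criteria.area_max_px)
    ok_reg = summary.to_numpy() >= criteria.registration_threshold - REGISTRATION_TOL

    keep = ok_epi & ok_nuc & ok_area & ok_reg
    audit = FilterAudit()
    audit.add(FilterStage(
        name="cells",
        n_in=len(cells), n_excluded=int((~keep).sum()), n_out=int(keep.sum()),
        rule_counts={
            "epithelial": int((~ok_epi).sum()),
            "nuclei": int((~ok_nuc).sum()),
            "area": int((~ok_area).sum()),
            "registration": int((~ok_reg).sum()),
        }))
    return cells.loc[keep].copy(), audit


def filter_fovs(fovs: pd.DataFrame,
                criteria: QcCriteria | None = None) -> tuple[pd.DataFrame, FilterAudit]:
    """FOV-level rules: manual pass and DCIS fraction >= threshold.

    A FOV with no evaluable tissue (``pct_dcis + pct_normal == 0``) is
    excluded under the rule ``no_evaluable_tissue``.  The boundary value
    (fraction exactly 0.5) is retained.
    """
    criteria = criteria or QcCriteria()
    _require(fovs, ("fov_id", "pct_dcis", "pct_normal", "manual_quality_pass"),
             "fov_id")
    total = fovs["pct_dcis"].to_numpy(dtype=float) \
        + fovs["pct_normal"].to_numpy(dtype=float)
    evaluable = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(evaluable,
                            fovs["pct_dcis"].to_numpy(dtype=float)
                            / np.where(evaluable, total, 1.0), 0.0)
    ok_manual = fovs["manual_quality_pass"].astype(bool).to_numpy()
    ok_dcis = evaluable & (fraction >= criteria.dcis_fraction_min)
    keep = ok_manual & ok_dcis
    audit = FilterAudit()
    audit.add(FilterStage(
        name="fovs",
        n_in=len(fovs), n_excluded=int((~keep).sum()), n_out=int(keep.sum()),
        rule_counts={
            "manual_quality": int((~ok_manual).sum()),
            "low_dcis_fraction": int((evaluable & (fraction < criteria.dcis_fraction_min)).sum()),
            "no_evaluable_tissue": int((~evaluable).sum()),
        }))
    return fovs.loc[keep].copy(), audit


def filter_patients(patients: pd.DataFrame, cells: pd.DataFrame,
                    criteria: QcCriteria | None = None) -> tuple[pd.DataFrame, FilterAudit]:
    """Patient-level outcome-analysis rules.

    A patient is retained iff they have ``>= min_cells_per_patient``
    retained cells, non-BCE patients were followed at least 3 years, and
    BCE patients had the event before 10 years.  Cells whose patient is
    not in the patient table raise a :class:`DataError`.
    """
    criteria = criteria or QcCriteria()
    _require(patients, ("patient_id", "bce", "followup_years"), "patient_id")
    known = set(patients["patient_id"])
    orphans = set(cells["patient_id"]) - known
    if orphans:
        raise DataError(f"cells reference unknown patient(s): {sorted(orphans)[:5]}")
    counts = cells.groupby("patient_id").size()
    n_cells = patients["patient_id"].map(counts).fillna(0).to_numpy(dtype=int)
    bce = patients["bce"].astype(bool).to_numpy()
    fu = patients["followup_years"].to_numpy(dtype=float)

    ok_count = n_cells >= criteria.min_cells_per_patient
    ok_fu = np.where(bce, fu < criteria.bce_max_followup_years,
                     fu >= criteria.nonbce_min_followup_years)
    keep = ok_count & ok_fu
    audit = FilterAudit()
    audit.add(FilterStage(
        name="patients",
        n_in=len(patients), n_excluded=int((~keep).sum()), n_out=int(keep.sum()),
        rule_counts={
            "too_few_cells": int((~ok_count).sum()),
            "short_followup_nonbce": int((~bce & ~ok_fu).sum()),
            "late_event_bce": int((bce & ~ok_fu).sum()),
        }))
    return patients.loc[keep].copy(), audit


def apply_qc(cells: pd.DataFrame, fovs: pd.DataFrame, patients: pd.DataFrame,
             criteria: QcCriteria | None = None):
    """Full QC cascade: cell rules -> FOV rules -> patient rules.

    FOV filtering removes the cells of excluded FOVs before patients are
    counted.  Returns ``(cells, patients, fovs, audit)`` where the audit's
    cell-count stages compose (cells -> cells_in_retained_fovs ->
    cells_of_retained_patients).
    """
    criteria = criteria or QcCriteria()
    cells_f, audit = filter_cells(cells, criteria)
    fovs_f, fov_audit = filter_fovs(fovs, criteria)
    keep = cells_f["fov_id"].isin(set(fovs_f["fov_id"]))
    audit.add(FilterStage(
        name="cells_in_fovs", n_in=len(cells_f),
        n_excluded=int((~keep).sum()), n_out=int(keep.sum()),
        rule_counts={"fov_excluded": int((~keep).sum())}))
    cells_f = cells_f.loc[keep]
    patients_f, pat_audit = filter_patients(patients, cells_f, criteria)
    keep_p = cells_f["patient_id"].isin(set(patients_f["patient_id"]))
    audit.add(FilterStage(
        name="cells_of_patients", n_in=len(cells_f),
        n_excluded=int((~keep_p).sum()), n_out=int(keep_p.sum()),
        rule_counts={"patient_excluded": int((~keep_p).sum())}))
    cells_f = cells_f.loc[keep_p].copy()
    full = FilterAudit(stages=audit.stages + fov_audit.stages + pat_audit.stages)
    return cells_f, patients_f, fovs_f, full
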