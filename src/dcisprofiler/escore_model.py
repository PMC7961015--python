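"""Patient cluster profiles and the logistic Escore risk model.

Each patient's cluster profile is the vector of fractions of their cells
in the six canonical phenotype clusters.  The Escore is a logistic
regression of the breast-cancer-event (BCE) outcome on two compositional
covariates measured on the 0-100 percentage scale:

    x1 = %cells in clusters 5 & 6   (HER2-high phenotypes, risk-raising)
    x2 = %cells in clusters 2 & 4   (ER-high phenotypes, risk-lowering)

The linear Escore is ``slope_c56 * x1 + slope_c24 * x2`` and a patient is
called high risk when the score exceeds the linear threshold.  The
threshold is tied to the cohort base rate: a patient is high risk iff the
model probability exceeds the observed event rate, which is equivalent to
``score > logit(base_rate) - intercept``.  The published model
(1.77, -2.78, threshold 13 at base rate 0.255) ships as a frozen constant
usable without refitting; its intercept is reconstructed from the
base-rate rule since only the slopes and threshold were reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from .errors import DataError, EscoreFitError, StatisticalError


def cluster_profiles(assignments: pd.DataFrame, k: int = 6) -> pd.DataFrame:
    """Per-patient cluster proportions.

    ``assignments`` needs columns ``patient_id`` and ``cluster`` (labels
    1..k).  Returns a patients x k table of proportions (columns
    ``cluster_1`` .. ``cluster_k``; absent clusters are 0) plus an
    ``n_cells`` column.  Proportions sum to 1 per patient.
    """
    if len(assignments) == 0:
        raise DataError("no assigned cells: cannot build profiles")
    counts = (assignments.groupby(["patient_id", "cluster"]).size()
              .unstack(fill_value=0)
              .reindex(columns=range(1, k + 1), fill_value=0))
    n_cells = counts.sum(axis=1)
    if (n_cells == 0).any():
        raise DataError("patient with zero cells in profile computation")
    profiles = counts.div(n_cells, axis=0)
    profiles.columns = [f"cluster_{c}" for c in profiles.columns]
    profiles["n_cells"] = n_cells
    return profiles


def escore_covariates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Percentage covariates (%C5&6, %C2&4) from a 6-cluster profile table."""
    for col in ("cluster_2", "cluster_4", "cluster_5", "cluster_6"):
        if col not in profiles.columns:
            raise DataError(f"profile table lacks {col!r}")
    return pd.DataFrame({
        "pct_c56": 100.0 * (profiles["cluster_5"] + profiles["cluster_6"]),
        "pct_c24": 100.0 * (profiles["cluster_2"] + profiles["cluster_4"]),
    }, index=profiles.index)


@dataclass
class EscoreModel:
    """Two-covariate logistic risk model on the percentage scale."""

    slope_c56: float
    slope_c24: float
    intercept: float
    base_rate: float
    source: str = "fitted"

    @property
    def linear_threshold(self) -> float:
        """High-risk cut on the linear score: logit(base_rate) - intercept."""
        return float(logit(self.base_rate) - self.intercept)

    def linear_score(self, pct_c56, pct_c24):
        return (self.slope_c56 * np.asarray(pct_c56, dtype=float)
                + self.slope_c24 * np.asarray(pct_c24, dtype=float))

    def predict_proba(self, pct_c56, pct_c24):
        return expit(self.intercept + self.linear_score(pct_c56, pct_c24))

    def to_dict(self) -> dict:
        return {"slope_c56": self.slope_c56, "slope_c24": self.slope_c24,
                "intercept": self.intercept, "base_rate": self.base_rate,
                "linear_threshold": self.linear_threshold,
                "source": self.source}


#: The published model: slopes 1.77 / -2.78, high risk when the linear
#: score exceeds 13, thresholded at the cohort base rate 13/51 = 0.255.
#: The intercept follows from the base-rate rule (logit(0.255) - 13) as the
#: published report gives only slopes and threshold.
PUBLISHED_ESCORE = EscoreModel(
    slope_c56=1.77, slope_c24=-2.78,
    intercept=float(logit(0.255)) - 13.0,
    base_rate=0.255, source="published")


def fit_escore(profiles: pd.DataFrame, outcomes: pd.Series) -> EscoreModel:
    """Maximum-likelihood logistic fit of outcome on (%C5&6, %C2&4).

    Unpenalised; raises :class:`EscoreFitError` on non-convergence or
    complete separation rather than silently regularising.
    """
    cov = escore_covariates(profiles)
    y = pd.Series(outcomes).reindex(cov.index)
    if y.isna().any():
        raise DataError("outcome missing for some patients")
    y = y.astype(bool)
    if y.all() or (~y).all():
        raise StatisticalError("both outcomes must be present to fit")
    # constant covariates carry no information: drop them from the design
    # (intercept-only limit gives slope 0 and intercept = logit(base rate))
    varying = [c for c in ("pct_c56", "pct_c24") if cov[c].nunique() > 1]
    X = sm.add_constant(cov[varying].to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y.to_numpy(dtype=float), X).fit(disp=0, maxiter=200)
        except Exception as exc:  # separation, singular hessian, ...
            raise EscoreFitError(
                "logistic fit failed (likely complete separation); inspect "
                "the covariates or use the published model") from exc
    if not res.mle_retvals.get("converged", False) \
            or not np.all(np.isfinite(res.bse)):
        raise EscoreFitError("logistic fit did not converge")
    slopes = dict.fromkeys(("pct_c56", "pct_c24"), 0.0)
    for name, value in zip(varying, res.params[1:]):
        slopes[name] = float(value)
    return EscoreModel(slope_c56=slopes["pct_c56"], slope_c24=slopes["pct_c24"],
                       intercept=float(res.params[0]),
                       base_rate=float(y.mean()), source="fitted")


def escore(profiles: pd.DataFrame, model: EscoreModel) -> pd.Series:
    """Linear Escore per patient from a canonical 6-cluster profile table."""
    cov = escore_covariates(profiles)
    return pd.Series(model.linear_score(cov["pct_c56"], cov["pct_c24"]),
                     index=profiles.index, name="escore")


def classify(scores, model: EscoreModel) -> np.ndarray:
    """High-risk call: strictly above the linear threshold."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise DataError("scores must be finite")
    return s > model.linear_threshold


@dataclass
class ClassificationMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    auc: float = float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def error_rate(self) -> float:
        return (self.fp + self.fn) / (self.tp + self.fn + self.tn + self.fp)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "error_rate": self.error_rate, "auc": self.auc}

    @classmethod
    def from_counts(cls, tp, fn, tn, fp, auc=float("nan")):
        return cls(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp), auc=auc)


def evaluate(scores, outcomes, model: EscoreModel) -> ClassificationMetrics:
    """Confusion counts at the model threshold plus rank (Mann-Whitney) AUC.

    AUC uses the midrank convention for ties on the continuous score.
    """
    y = np.asarray(outcomes, dtype=bool)
    if y.all() or (~y).all():
        raise StatisticalError("need at least one of each outcome")
    high = classify(scores, model)
    tp = int((high & y).sum())
    fn = int((~high & y).sum())
    tn = int((~high & ~y).sum())
    fp = int((high & ~y).sum())
    auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return ClassificationMetrics(tp=tp, fn=fn, tn=tn, fp=fp, auc=auc)


@dataclass
class LoocvResult:
    """Held-out probabilities from leave-one-out refits of the logistic model."""

    probabilities: pd.Series
    auc: float
    n_failed: int
    failed_patients: list = field(default_factory=list)


def loocv(profiles: pd.DataFrame, outcomes: pd.Series) -> LoocvResult:
    """Leave-one-out cross-validation of the Escore logistic regression.

    Cluster assignments stay fixed; only the logistic model is refit per
    fold.  Folds that fail to converge are flagged and excluded from the
    held-out AUC (their count is reported).
    """
    cov = escore_covariates(profiles)
    y = pd.Series(outcomes).reindex(cov.index).astype(bool)
    n = len(cov)
    if n < 10:
        raise StatisticalError("LOOCV requires n >= 10 patients")
    probs = {}
    failed = []
    for pid in cov.index:
        rest = cov.index != pid
        try:
            model = fit_escore(profiles.loc[rest], y.loc[rest])
        except EscoreFitError:
            failed.append(pid)
            continue
        probs[pid] = float(model.predict_proba(cov.at[pid, "pct_c56"],
                                               cov.at[pid, "pct_c24"]))
    prob_series = pd.Series(probs, name="loocv_probability")
    held_y = y.loc[prob_series.index]
    if held_y.all() or (~held_y).all():
        raise StatisticalError("LOOCV folds left only one outcome class")
    auc = float(roc_auc_score(held_y, prob_series))
    return LoocvResult(probabilities=prob_series, auc=auc,
                       n_failed=len(failed), failed_patients=failed)


def core_concordance(core_profiles: pd.DataFrame,
                     model: EscoreModel) -> tuple[pd.DataFrame, float]:
    """Risk-class agreement between duplicate tissue cores of a patient.

    ``core_profiles`` is a profile table indexed by (patient_id, core_id)
    or carrying those columns.  Patients with >= 2 cores are scored per
    core and flagged concordant when every core lands on the same side of
    the threshold.  Returns (per-patient table, fraction concordant).
    """
    df = core_profiles
    if not isinstance(df.index, pd.MultiIndex):
        if not {"patient_id", "core_id"}.issubset(df.columns):
            raise DataError("need patient_id/core_id index or columns")
        df = df.set_index(["patient_id", "core_id"])
    scores = escore(df, model)
    high = classify(scores, model)
    calls = pd.DataFrame({"escore": scores, "high_risk": high})
    rows = []
    for pid, grp in calls.groupby(level=0):
        if len(grp) < 2:
            continue
        rows.append({"patient_id": pid, "n_cores": len(grp),
                     "classes": tuple(bool(v) for v in grp["high_risk"]),
                     "concordant": grp["high_risk"].nunique() == 1})
    if not rows:
        raise DataError("no patient has >= 2 cores")
    table = pd.DataFrame(rows).set_index("patient_id")
    return table, float(table["concordant"].mean())
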