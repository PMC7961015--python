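"""Patient-level univariate marker screen.

Per-cell summarised intensities are aggregated to one value per patient and
marker (mean of the per-cell medians), group means are compared with a
Welch two-sample t-test (two-sided), and significance is declared by
Benjamini-Hochberg step-up control of the false discovery rate at q = 0.2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StatisticalError


def aggregate_patients(values: pd.DataFrame, patient_ids: pd.Series) -> pd.DataFrame:
    """Mean of per-cell values per patient; rows = patients, cols = markers."""
    if len(values) == 0:
        raise StatisticalError("no cells to aggregate")
    ids = pd.Series(patient_ids).reindex(values.index)
    return values.groupby(ids.to_numpy()).mean().rename_axis("patient_id")


def bh_select(pvalues, q: float = 0.2) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level ``q``.

    Sort p-values ascending, find the largest i with ``p(i) <= i*q/m`` and
    reject hypotheses 1..i.  Returns a boolean array aligned to the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise StatisticalError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def compare_groups(patient_values: pd.DataFrame, outcomes: pd.Series,
                   q: float = 0.2) -> pd.DataFrame:
    """Welch t-test per marker between BCE and non-BCE patients.

    ``outcomes`` maps patient_id -> bool (True = BCE).  Returns a table with
    group means, t statistic, two-sided p and the BH significance flag.
    """
    outcomes = pd.Series(outcomes).reindex(patient_values.index)
    if outcomes.isna().any():
        raise StatisticalError("outcome missing for some patients")
    grp = outcomes.astype(bool).to_numpy()
    if grp.sum() < 2 or (~grp).sum() < 2:
        raise StatisticalError("each outcome group needs >= 2 patients")
    rows = []
    for marker in patient_values.columns:
        x = patient_values[marker].to_numpy(dtype=float)
        a, b = x[grp], x[~grp]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"marker": marker, "mean_bce": a.mean(),
                     "mean_non_bce": b.mean(), "t": float(t), "p": float(p)})
    result = pd.DataFrame(rows)
    result["significant"] = bh_select(result["p"].to_numpy(), q=q)
    result["q"] = q
    return result
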