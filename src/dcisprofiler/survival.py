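"""Disease-free-interval analysis of the binary Escore groups.

Kaplan-Meier product-limit curves per risk group and the standard
two-group log-rank test (chi-square with 1 df, hypergeometric variance).
The event is any breast cancer event; patients without one are censored at
last follow-up.  Ties between an event and a censoring at the same time
follow the usual convention (the censored patient is still at risk for the
event).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .errors import DataError, StatisticalError


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier step function: columns ``time`` and ``survival``.

    Survival starts at 1 and is non-increasing; censored times reduce the
    risk set only.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DataError("no records for KM estimate")
    if np.any(t <= 0):
        raise DataError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank(times, events, groups) -> LogRankResult:
    """Two-group log-rank test; chi-square statistic with 1 df."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise StatisticalError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    a = g == levels[0]
    if a.sum() == 0 or (~a).sum() == 0:
        raise StatisticalError("each group needs >= 1 record")
    res = _lifelines_logrank(t[a], t[~a], event_observed_A=e[a],
                             event_observed_B=e[~a])
    return LogRankResult(statistic=float(res.test_statistic), df=1,
                         p=float(res.p_value))


def survival_table(patients: pd.DataFrame, high_risk: pd.Series) -> pd.DataFrame:
    """Assemble per-patient survival records with the Escore risk group."""
    hr = pd.Series(high_risk)
    df = patients.set_index("patient_id") if "patient_id" in patients.columns \
        else patients
    out = pd.DataFrame({
        "time": df["followup_years"].astype(float),
        "event": df["bce"].astype(bool),
        "group": np.where(hr.reindex(df.index).astype(bool), "high", "low"),
    })
    if out["time"].le(0).any():
        raise DataError("non-positive follow-up time")
    return out
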