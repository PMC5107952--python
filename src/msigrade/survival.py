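"""Kaplan-Meier estimation, log-rank group comparison, and grader
agreement.

Overall survival (OS) runs from detection of the metastases to last
follow-up; disease-free survival (DFS) from surgery to recurrence or last
follow-up.  Response groups derived from the mTRG are compared with the
log-rank (Mantel-Cox) test; agreement between graders (pathologists or
the automated MSI grade) is a Pearson product-moment correlation of the
1-5 grade vectors (Spearman available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray      # distinct event times (ascending)
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # subjects at risk at each event time
    events: np.ndarray     # events at each event time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival must lie in [0, 1]")

    def survival_at(self, t: float) -> float:
        """Step-function lookup: S(t) with S(0) = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "events": self.events})


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` holds 1 for an observed event and 0 for censoring; subjects
    censored exactly at an event time are counted at risk for that time
    (events processed first, the standard convention followed by
    lifelines).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    ts = event_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0])
                     for t in ts])
    return KMCurve(ts, surv, event_rows["at_risk"].to_numpy(),
                   event_rows["observed"].to_numpy())


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float


def logrank_test(groups) -> LogrankResult:
    """Mantel-Cox log-rank test across two or more groups.

    ``groups`` is a sequence of ``(times, events)`` pairs.  The statistic
    accumulates observed-minus-expected event counts over the pooled event
    times; degrees of freedom are ``len(groups) - 1`` and the p-value
    comes from the chi-square distribution.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError("empty group")
        if np.all(t <= 0):
            raise ValueError("group with all-zero follow-up")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, gi))
    res = multivariate_logrank_test(np.concatenate(times),
                                    np.concatenate(labels),
                                    np.concatenate(events))
    return LogrankResult(float(res.test_statistic),
                         int(res.degrees_of_freedom), float(res.p_value))


def grader_correlation(a, b, method: str = "pearson") -> float:
    """Correlation between two grade vectors (default Pearson r)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("grade vectors must share a length of at least 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant grade vector")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def filter_chemotherapy(records: pd.DataFrame,
                        chemo_column: str = "chemo") -> pd.DataFrame:
    """Restrict a clinical table to chemotherapy-treated lesions."""
    if chemo_column not in records.columns:
        raise ValueError(f"no column {chemo_column!r} in the clinical table")
    return records[records[chemo_column].astype(bool)].reset_index(drop=True)


def km_by_group(records: pd.DataFrame, group_column: str = "group",
                time_column: str = "time", event_column: str = "event"
                ) -> dict[str, KMCurve]:
    """One KM curve per group of a clinical table."""
    out = {}
    for name, sub in records.groupby(group_column, sort=True):
        out[str(name)] = kaplan_meier(sub[time_column], sub[event_column])
    return out


def plot_km(records: pd.DataFrame, ax=None, group_column: str = "group",
            time_column: str = "time", event_column: str = "event"):
    """Kaplan-Meier plot per group (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, sub in records.groupby(group_column, sort=True):
        kmf = KaplanMeierFitter(label=str(name))
        kmf.fit(sub[time_column], sub[event_column])
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    return ax
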