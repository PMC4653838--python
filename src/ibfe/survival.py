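"""Prognostic assessment of discovered patient subtypes.

Each cluster is compared against all remaining patients with a two-group
log-rank test, and Kaplan-Meier survival curves are estimated per
cluster.  The clinical table carries one row per patient: follow-up time
(any consistent unit) and an event indicator (1 = event observed,
0 = censored).  Ties between events and censorings at the same time
follow the standard product-limit convention (censorings occur after
events).  P-values are reported uncorrected; one test is run per cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = ["km_curve", "logrank_vs_rest", "SurvivalResult"]


def _check_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "time", "event"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns: {sorted(missing)}")
    df = clinical.copy()
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in clinical table: {dupes}")
    df["time"] = pd.to_numeric(df["time"])
    if (df["time"] < 0).any():
        raise ValueError("negative follow-up times in clinical table")
    events = pd.to_numeric(df["event"])
    if not events.isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    df["event"] = events.astype(int)
    return df


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a frame with one row per distinct observed time: the survival
    probability just after that time, the number at risk just before it,
    and the numbers of events and censorings at it.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative follow-up times")
    kmf = KaplanMeierFitter().fit(times, events)
    tbl = kmf.event_table
    tbl = tbl[tbl["removed"] > 0]  # drop the synthetic entry row at time 0
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tbl.index.to_numpy(dtype=float),
            "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
            "censored": tbl["censored"].to_numpy(dtype=int),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class SurvivalResult:
    """Per-cluster log-rank tests (cluster vs rest) and KM curves."""

    clusters: dict = field(default_factory=dict)  # cluster -> stats dict
    dropped_ids: list = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "cluster": c.item() if hasattr(c, "item") else c,
                "n": s["n"],
                "n_rest": s["n_rest"],
                "statistic": s["statistic"],
                "p_value": s["p_value"],
            }
            for c, s in self.clusters.items()
        ]


def logrank_vs_rest(labels: pd.Series, clinical: pd.DataFrame) -> SurvivalResult:
    """Log-rank test of each cluster against all remaining patients.

    Parameters
    ----------
    labels : Series
        Cluster assignment indexed by patient id.
    clinical : DataFrame
        Columns ``patient_id``, ``time``, ``event``.

    Patients missing from the clinical table are dropped (and reported in
    ``dropped_ids``); a cluster left empty after the join is skipped with
    a warning.  The test statistic is referenced to a chi-square
    distribution with one degree of freedom.
    """
    clin = _check_clinical(clinical).set_index("patient_id")
    labels = pd.Series(labels)
    present = labels.index.intersection(clin.index)
    dropped = labels.index.difference(clin.index).tolist()
    if len(present) == 0:
        raise ValueError("no labeled patient is present in the clinical table")
    joined = clin.loc[present].assign(cluster=labels.loc[present])
    result = SurvivalResult(dropped_ids=dropped)
    for cluster in sorted(labels.unique()):
        grp = joined[joined["cluster"] == cluster]
        rest = joined[joined["cluster"] != cluster]
        if len(grp) == 0:
            warnings.warn(
                f"cluster {cluster!r} has no patients with clinical data; skipped",
                RuntimeWarning,
            )
            continue
        stats: dict = {
            "n": int(len(grp)),
            "n_rest": int(len(rest)),
            "curve": km_curve(grp["time"], grp["event"]),
        }
        if len(rest) == 0:
            warnings.warn(
                f"cluster {cluster!r} contains every patient; no comparison group",
                RuntimeWarning,
            )
            stats["statistic"] = float("nan")
            stats["p_value"] = float("nan")
        else:
            test = logrank_test(grp["time"], rest["time"], grp["event"], rest["event"])
            stats["statistic"] = float(test.test_statistic)
            stats["p_value"] = float(test.p_value)
        result.clusters[cluster] = stats
    return result
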