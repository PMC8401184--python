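"""Kaplan-Meier estimation and log-rank comparison by methylation status.

Thin, validated wrappers over lifelines: the product-limit estimator and
the two-group log-rank test (chi-square with 1 df), plus stratification
of patients into methylated/unmethylated groups from either a
qualitative MSP call or a quantitative qMSP percentage against the
29.74 % threshold.  When both measures are present the qualitative call
takes precedence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .qmsp import MSP_THRESHOLD, classify_msp

__all__ = ["km_estimate", "logrank", "stratify", "endpoint_columns"]

log = logging.getLogger(__name__)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table (time, survival, at_risk) including the
    S(0) = 1 anchor; censored observations shrink the risk set without
    producing steps.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("need at least one sample")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.to_numpy(dtype=float),
        "at_risk": at_risk.to_numpy(dtype=float),
    }).reset_index(drop=True)


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def stratify(clinical: pd.DataFrame, percents: pd.Series | None = None,
             msp_calls: pd.Series | None = None,
             threshold: float = MSP_THRESHOLD) -> pd.DataFrame:
    """Split patients into methylated/unmethylated groups.

    ``percents`` and ``msp_calls`` are indexed by patient id; the
    qualitative MSP call overrides the quantitative percentage when both
    exist.  Patients with neither measure are dropped (count logged).
    """
    if percents is None and msp_calls is None:
        raise ValueError("provide qMSP percents and/or MSP calls")
    rows = []
    dropped = 0
    for _, r in clinical.iterrows():
        pid = r["patient_id"]
        if msp_calls is not None and pid in msp_calls.index and pd.notna(msp_calls.loc[pid]):
            meth = bool(msp_calls.loc[pid])
        elif percents is not None and pid in percents.index and pd.notna(percents.loc[pid]):
            meth = classify_msp(float(percents.loc[pid]), threshold)
        else:
            dropped += 1
            continue
        rows.append({**r.to_dict(), "group": "methylated" if meth else "unmethylated"})
    if dropped:
        log.info("stratify: dropped %d patients with no methylation measure", dropped)
    if not rows:
        raise ValueError("no patient has a methylation measure")
    return pd.DataFrame(rows)


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    """Clinical-table column pair (time, event) for an endpoint name."""
    try:
        return {"os": ("os_days", "os_event"), "pfs": ("pfs_days", "pfs_event")}[endpoint]
    except KeyError:
        raise ValueError(f"unknown endpoint {endpoint!r}; use 'os' or 'pfs'") from None
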