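"""Quantitative methylation-specific PCR (qMSP) arithmetic.

A dual-probe qMSP reaction reports one Ct for the methylated and one for
the unmethylated detection probe.  Assuming a common amplification
efficiency E (default 2.0, perfect doubling), the starting fractions of
methylated molecules follow directly from the T difference:

    percent_methylated = 100 * E^-CtM / (E^-CtM + E^-CtU)
                       = 100 / (1 + E^(CtM - CtU))

Percent-methylated values above the MSP concordance threshold (29.74 %,
the lowest quantitative value observed to coincide with a positive
qualitative MSP call) classify a sample as methylated.  Fold changes and
the absolute percentage-point drop after epigenetic reactivation
(demethylation) are exact arithmetic on these percentages.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "methylation_percent",
    "classify_msp",
    "fold_change",
    "demethylation_after_rt",
    "summarize_qmsp",
    "MSP_THRESHOLD",
    "NoSignalError",
]

MSP_THRESHOLD = 29.74


class NoSignalError(ValueError):
    """Neither qMSP channel produced a detectable signal."""


def methylation_percent(ct_m: float, ct_u: float, efficiency: float = 2.0) -> float:
    """Percent methylated molecules from the two channel Cts.

    An undetected channel is passed as ``math.inf``: undetected methylated
    probe gives 0 %, undetected unmethylated probe gives 100 %.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    m_inf = math.isinf(ct_m)
    u_inf = math.isinf(ct_u)
    if m_inf and u_inf:
        raise NoSignalError("no signal on either qMSP channel")
    if m_inf:
        return 0.0
    if u_inf:
        return 100.0
    return 100.0 / (1.0 + efficiency ** (ct_m - ct_u))


def classify_msp(percent: float, threshold: float = MSP_THRESHOLD) -> bool:
    """True iff the percent-methylated value lies strictly above the threshold."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must lie in [0, 100]")
    return percent > threshold


def fold_change(percent_a: float, percent_b: float) -> float:
    """Ratio of two percent-methylated values (a over b)."""
    if percent_b <= 0:
        raise ValueError("fold change not estimable: reference percent is zero")
    return percent_a / percent_b


def demethylation_after_rt(percent_r: float, percent_rt: float) -> float:
    """Absolute drop in percentage points after reactivation treatment."""
    for v in (percent_r, percent_rt):
        if not 0 <= v <= 100:
            raise ValueError("percent must lie in [0, 100]")
    return percent_r - percent_rt


def summarize_qmsp(ct_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Replicate-averaged percent methylated per (gene, phenotype).

    ``ct_table`` columns: gene, phenotype, replicate, ct_m, ct_u.  Cts are
    averaged across replicates before the closed-form conversion.
    """
    g = ct_table.groupby(["gene", "phenotype"], as_index=False)[["ct_m", "ct_u"]].mean()
    g["percent_methylated"] = [
        methylation_percent(m, u, efficiency) for m, u in zip(g["ct_m"], g["ct_u"])
    ]
    g["methylated"] = [classify_msp(p) for p in g["percent_methylated"]]
    return g
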