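"""Viability normalization, IC50 interpolation and resistance indices.

Raw viability signals are normalized to the untreated control (dose 0 =
100 % survival).  IC50 is the dose at the first (lowest-dose) 50 %
crossing of the mean curve, obtained by linear interpolation between the
bracketing doses.  The resistance index is IC50(resistant) /
IC50(sensitive); a transfection RI of IC50(R-MOCK)/IC50(R-rescue) on the
same scale quantifies re-sensitization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalize_viability", "ic50", "resistance_index", "UndefinedIC50Error"]


class UndefinedIC50Error(ValueError):
    """The dose-response curve never crosses 50 % viability."""


def normalize_viability(doses, raw, raw_untreated) -> pd.DataFrame:
    """Normalize raw signals to percent of the untreated control.

    ``raw`` is (n_doses,) or (n_doses, n_replicates); ``raw_untreated`` a
    scalar or per-replicate vector averaged before use.  Returns a
    DataFrame with dose, viability (mean %) and viability_sd.
    """
    doses = np.asarray(doses, dtype=float)
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] != len(doses):
        raw = raw.T
    untreated = float(np.mean(raw_untreated))
    if untreated <= 0:
        raise ValueError("untreated control signal must be positive")
    via = 100.0 * raw / untreated
    out = pd.DataFrame({
        "dose": doses,
        "viability": via.mean(axis=1),
        "viability_sd": via.std(axis=1, ddof=1) if raw.shape[1] > 1 else 0.0,
    })
    return out.sort_values("dose").reset_index(drop=True)


def ic50(doses, viability) -> float:
    """Dose at the first 50 % crossing of the viability curve.

    Linear interpolation between the bracketing doses; raises
    :class:`UndefinedIC50Error` when all points sit on one side of 50 %.
    """
    doses = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    order = np.argsort(doses)
    doses, v = doses[order], v[order]
    if not ((v < 50).any() and (v > 50).any()):
        raise UndefinedIC50Error("viability curve does not cross 50%")
    for i in range(len(v) - 1):
        if v[i] == 50:
            return float(doses[i])
        if (v[i] - 50) * (v[i + 1] - 50) < 0:
            frac = (50 - v[i]) / (v[i + 1] - v[i])
            return float(doses[i] + frac * (doses[i + 1] - doses[i]))
    return float(doses[-1])  # last point exactly 50


def resistance_index(ic50_resistant: float, ic50_sensitive: float) -> float:
    """IC50(resistant) / IC50(sensitive); round to 2 decimals for reporting."""
    if ic50_resistant <= 0 or ic50_sensitive <= 0:
        raise ValueError("IC50 values must be positive")
    return float(ic50_resistant / ic50_sensitive)
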