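"""Differential expression, count preprocessing and relative quantification.

Array-style tables (log2 intensities) are tested gene-wise with a Welch
two-sample t-test and Benjamini-Hochberg FDR; count tables go through the
CPM presence filter (discard genes with CPM < 1 in fewer than 6 samples)
and TMM normalization (trimmed mean of M-values, 30 % M-trim / 5 % A-trim,
precision-weighted) before the same two-group test on log2 CPM.
Re-expression after epigenetic reactivation (RT vs R) and the comparative
threshold-cycle method 2^-ddCt round out the module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import bh_adjust

__all__ = [
    "collapse_duplicates",
    "differential_expression",
    "cpm",
    "cpm_filter",
    "tmm_factors",
    "detect_reexpression",
    "ddct",
]


def collapse_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate gene ids, keeping the highest-variance row per gene."""
    if table.index.is_unique:
        return table
    warnings.warn("duplicate gene ids collapsed to the max-variance row", stacklevel=2)
    aux = pd.DataFrame({
        "gene": table.index.to_numpy(),
        "var": table.var(axis=1).to_numpy(),
        "row": np.arange(len(table)),
    })
    keep = aux.sort_values(["var", "row"]).groupby("gene")["row"].last()
    return table.iloc[np.sort(keep.to_numpy())]


def _welch(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t p-values with the zero-variance tie rule:
    identical constant groups give p = 1, constant groups with different
    means give p = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def differential_expression(table: pd.DataFrame, design: dict[str, str],
                            group_a: str, group_b: str,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t on log2 values, group_a vs group_b, with BH FDR.

    Returns gene, logFC (mean_a - mean_b), p, q, direction and the
    boolean ``de`` flag (q <= alpha).  Requires >= 2 samples per group.
    """
    table = collapse_duplicates(table)
    cols_a = [s for s in table.columns if design.get(s) == group_a]
    cols_b = [s for s in table.columns if design.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group for variance estimation "
            f"(got {len(cols_a)} {group_a!r}, {len(cols_b)} {group_b!r}); "
            f"use a paired fixture for single-replicate designs")
    a = table[cols_a].to_numpy(dtype=float)
    b = table[cols_b].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    p = _welch(a, b)
    q = bh_adjust(p)
    return pd.DataFrame({
        "gene": table.index,
        "logFC": logfc,
        "p": p,
        "q": q,
        "direction": np.where(logfc >= 0, "up", "down"),
        "de": q <= alpha,
    }).reset_index(drop=True)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    return counts / lib * 1e6


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0,
               min_samples: int = 6) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in at least min_samples samples."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    return counts[keep]


def tmm_factors(counts: pd.DataFrame, ref: str | None = None,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Standard recipe: the reference sample is the one whose 75th CPM
    percentile is closest to the mean; per sample, gene-wise M (log2
    ratio) and A (log2 abundance) values against the reference are
    doubly trimmed (30 % on M, 5 % on A) and averaged with delta-method
    precision weights; factors are rescaled to geometric mean 1.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with all-zero counts")
    if ref is None:
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(counts.columns).index(ref)

    factors = np.ones(x.shape[1])
    r = x[:, ref_j]
    nr = lib[ref_j]
    for j in range(x.shape[1]):
        o = x[:, j]
        no = lib[j]
        pos = (o > 0) & (r > 0)
        if not pos.any():
            continue
        m = np.log2((o[pos] / no) / (r[pos] / nr))
        a = 0.5 * np.log2((o[pos] / no) * (r[pos] / nr))
        # delta-method asymptotic variance of M; precision weights below
        v = (no - o[pos]) / (no * o[pos]) + (nr - r[pos]) / (nr * r[pos])
        fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
        m, a, v = m[fin], a[fin], v[fin]
        if len(m) == 0 or np.abs(m).max() < 1e-6:
            continue
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any() and np.sum(1.0 / v[keep]) > 0:
            factors[j] = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def detect_reexpression(table: pd.DataFrame, design: dict[str, str],
                        groups: tuple[str, str] = ("R", "RT"),
                        min_fc: float = 2.0, alpha: float = 0.05) -> set[str]:
    """Genes re-expressed after epigenetic reactivation.

    Welch t of RT vs R on log2 values; keep genes with logFC >=
    log2(min_fc) and q <= alpha.
    """
    base, treated = groups
    if not any(design.get(s) == treated for s in table.columns):
        raise ValueError(f"no samples in reactivation group {treated!r}")
    de = differential_expression(table, design, treated, base, alpha=alpha)
    hit = de[(de["logFC"] >= np.log2(min_fc)) & (de["q"] <= alpha)]
    return set(hit["gene"])


def ddct(ct_target_sample: float, ct_ref_sample: float,
         ct_target_cal: float, ct_ref_cal: float) -> float:
    """Relative expression by the comparative threshold-cycle method:
    2^-((Ct_target,sample - Ct_ref,sample) - (Ct_target,cal - Ct_ref,cal))."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_val = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct_val))
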