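"""Beta values, coverage filtering and differential-methylation calling.

Per-CpG methylation is summarized as the beta value meth/(meth+unmeth).
Differential CpGs between a sensitive (S) and a resistant (R) phenotype
are called under named threshold schemes combining beta-value
inequalities with a two-sided Fisher's exact test per CpG and
Benjamini-Hochberg FDR control computed over all shared, covered CpGs.

Shipped schemes
---------------
initial     beta_R > 0.7 and beta_S < 0.3, coverage > 5
readjusted  beta_S < 0.2 and (beta_R - beta_S) > 0.4, coverage > 5
matrix_a    beta_R > 0.4 and beta_S < 0.23, coverage > 10
matrix_b    beta_S < 0.16 and (beta_R - beta_S) >= 0.14, coverage > 10

The coverage filter is strict (">") in every scheme.  Replicates within a
phenotype are pooled by summing counts before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ThresholdScheme",
    "SCHEMES",
    "get_scheme",
    "compute_beta",
    "pool_counts",
    "test_cpg",
    "bh_adjust",
    "call_dm",
    "dm_genes",
    "dm_from_beta_matrix",
]


@dataclass(frozen=True)
class ThresholdScheme:
    """A named set of beta/coverage/FDR cutoffs for DM calling.

    ``min_delta`` is compared strictly (>) when ``delta_strict`` is True,
    otherwise inclusively (>=).  ``min_coverage`` is always strict.
    """

    name: str
    max_beta_S: float
    min_beta_R: float | None = None
    min_delta: float | None = None
    delta_strict: bool = True
    min_coverage: int = 5
    fdr: float = 0.05

    def __post_init__(self):
        for v in (self.max_beta_S, self.min_beta_R, self.min_delta, self.fdr):
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"scheme fraction out of [0,1]: {v}")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be non-negative")


SCHEMES: dict[str, ThresholdScheme] = {
    "initial": ThresholdScheme("initial", max_beta_S=0.3, min_beta_R=0.7, min_coverage=5),
    "readjusted": ThresholdScheme("readjusted", max_beta_S=0.2, min_delta=0.4,
                                  delta_strict=True, min_coverage=5),
    "matrix_a": ThresholdScheme("matrix_a", max_beta_S=0.23, min_beta_R=0.4, min_coverage=10),
    "matrix_b": ThresholdScheme("matrix_b", max_beta_S=0.16, min_delta=0.14,
                                delta_strict=False, min_coverage=10),
}


def get_scheme(name_or_scheme) -> ThresholdScheme:
    if isinstance(name_or_scheme, ThresholdScheme):
        return name_or_scheme
    try:
        return SCHEMES[name_or_scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {name_or_scheme!r}; "
                         f"available: {sorted(SCHEMES)}") from None


def _validate_counts(df: pd.DataFrame):
    for col in ("count_methylated", "count_unmethylated"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        if (df[col].to_numpy() < 0).any():
            raise ValueError(f"negative values in {col!r}")


def compute_beta(profiles: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Filter CpGs to coverage strictly greater than ``min_coverage`` and
    attach coverage and beta columns."""
    _validate_counts(profiles)
    out = profiles.copy()
    out["coverage"] = out["count_methylated"] + out["count_unmethylated"]
    out = out[out["coverage"] > min_coverage].copy()
    out["beta"] = out["count_methylated"] / out["coverage"]
    return out.reset_index(drop=True)


def pool_counts(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum methylated/unmethylated counts across replicate CpG tables
    (outer union of coordinates; absent CpGs contribute zero)."""
    if not profiles:
        raise ValueError("no profiles to pool")
    cat = pd.concat(profiles, ignore_index=True)
    pooled = (cat.groupby(["chrom", "pos"], as_index=False)
              [["count_methylated", "count_unmethylated"]].sum())
    return pooled.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _fisher_two_sided(a, b, c, d):
    """Vectorized two-sided Fisher's exact p for 2x2 tables [[a,b],[c,d]].

    Two-sided by hypergeometric pmf ordering: sum of pmf(k) over the
    support where pmf(k) <= pmf(observed) * (1 + 1e-7).
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    M = a + b + c + d
    n = a + b
    K = a + c
    p = np.ones(len(a), dtype=float)
    ok = (n > 0) & (n < M)  # both margins non-degenerate
    if (~ok).any():
        warnings.warn("empty margin in exact test; returning p = 1", stacklevel=2)
    if not ok.any():
        return p
    # dedupe identical tables: Poisson coverage produces many repeats
    tab = np.stack([a[ok], b[ok], c[ok], d[ok]], axis=1)
    uniq, inv = np.unique(tab, axis=0, return_inverse=True)
    ua, ub, uc, ud = uniq.T
    uM, un, uK = ua + ub + uc + ud, ua + ub, ua + uc
    kmin = np.maximum(0, un + uK - uM)
    kmax = np.minimum(un, uK)
    width = int((kmax - kmin).max()) + 1
    ks = kmin[:, None] + np.arange(width)[None, :]
    valid = ks <= kmax[:, None]
    pmf = hypergeom.pmf(np.where(valid, ks, 0), uM[:, None], uK[:, None], un[:, None])
    pmf = np.where(valid, pmf, 0.0)
    p_obs = hypergeom.pmf(ua, uM, uK, un)
    up = np.where(pmf <= p_obs[:, None] * (1 + 1e-7), pmf, 0.0).sum(axis=1)
    up[up > 1.0 - 1e-12] = 1.0  # full-support sums hit 1 up to rounding
    p[ok] = up[inv]
    return p


def test_cpg(meth_S: int, unmeth_S: int, meth_R: int, unmeth_R: int) -> float:
    """Two-sided exact hypergeometric p-value for one CpG's 2x2 count table.

    An empty margin (no reads in one phenotype, or all reads in one
    methylation state) carries no information: returns 1 with a warning.
    """
    for v in (meth_S, unmeth_S, meth_R, unmeth_R):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return float(_fisher_two_sided([meth_S], [unmeth_S], [meth_R], [unmeth_R])[0])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def call_dm(profiles_S: pd.DataFrame, profiles_R: pd.DataFrame,
            scheme="readjusted") -> pd.DataFrame:
    """Call differentially methylated CpGs between phenotypes S and R.

    Coverage-filters each phenotype, inner-joins on (chrom, pos), computes
    the exact test and BH q over all joined CpGs, and returns exactly the
    rows satisfying every scheme inequality with q < scheme.fdr.
    """
    scheme = get_scheme(scheme)
    s = compute_beta(profiles_S, scheme.min_coverage)
    r = compute_beta(profiles_R, scheme.min_coverage)
    m = s.merge(r, on=["chrom", "pos"], suffixes=("_S", "_R"))
    cols = ["chrom", "pos", "beta_S", "beta_R", "delta", "p", "q", "direction"]
    if m.empty:
        warnings.warn("no shared CpG coordinates between phenotypes", stacklevel=2)
        return pd.DataFrame(columns=cols)
    m["delta"] = m["beta_R"] - m["beta_S"]
    m["p"] = _fisher_two_sided(m["count_methylated_S"], m["count_unmethylated_S"],
                               m["count_methylated_R"], m["count_unmethylated_R"])
    m["q"] = bh_adjust(m["p"].to_numpy())
    keep = (m["beta_S"] < scheme.max_beta_S) & (m["q"] < scheme.fdr)
    if scheme.min_beta_R is not None:
        keep &= m["beta_R"] > scheme.min_beta_R
    if scheme.min_delta is not None:
        keep &= (m["delta"] > scheme.min_delta) if scheme.delta_strict \
            else (m["delta"] >= scheme.min_delta)
    m["direction"] = np.where(m["delta"] >= 0, "hyper", "hypo")
    out = m.loc[keep, cols].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


def dm_genes(dm: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Roll DM CpG calls up to genes via a position annotation.

    ``annotation`` is the classify_positions output aligned row-for-row
    with ``dm`` (zone, gene per CpG).  Returns one row per gene having at
    least one zone-annotated DM CpG: gene, n_dm_cpgs, regions (sorted
    comma-joined zone labels) and max_abs_delta.
    """
    if len(dm) != len(annotation):
        raise ValueError("dm table and annotation must align row-for-row")
    if dm.empty:
        return pd.DataFrame(columns=["gene", "n_dm_cpgs", "regions", "max_abs_delta"])
    j = dm.reset_index(drop=True).join(
        annotation.reset_index(drop=True)[["zone", "gene"]])
    j = j[(j["gene"].notna()) & (j["zone"] != "none")]
    if j.empty:
        return pd.DataFrame(columns=["gene", "n_dm_cpgs", "regions", "max_abs_delta"])
    g = j.groupby("gene").agg(
        n_dm_cpgs=("pos", "size"),
        regions=("zone", lambda z: ",".join(sorted(set(z)))),
        max_abs_delta=("delta", lambda d: float(np.abs(d).max())),
    ).reset_index()
    return g.sort_values("gene").reset_index(drop=True)


def dm_from_beta_matrix(beta: pd.DataFrame, tumor_cols, control_cols,
                        min_delta: float = 0.2, fdr: float = 0.05) -> pd.DataFrame:
    """Array-style DM genes from a per-patient beta matrix.

    Welch t per gene (tumor vs control beta), BH over all genes, and an
    absolute mean-difference cutoff; a stand-in for the 450K differential
    pipeline on desk-scale matrices.
    """
    from scipy import stats

    t = beta[list(tumor_cols)].to_numpy(dtype=float)
    c = beta[list(control_cols)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(t, c, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    delta = t.mean(axis=1) - c.mean(axis=1)
    q = bh_adjust(p)
    out = pd.DataFrame({"gene": beta.index, "delta_beta": delta, "p": p, "q": q})
    out["direction"] = np.where(delta >= 0, "hyper", "hypo")
    return out[(np.abs(out["delta_beta"]) >= min_delta) & (out["q"] < fdr)] \
        .reset_index(drop=True)
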