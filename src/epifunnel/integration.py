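"""Cohort selection, the candidate funnel, contrast matrix and ranking.

The funnel intersects the resistance-associated expression signature with
cohort-level differential expression, re-expression after epigenetic
reactivation, promoter CpG-island presence and WGBS differential
methylation, reporting each stage's size and its percentage of the
previous stage.  The contrast matrix evaluates named set-algebra
combinations of methylation/expression layers (24 shipped specs in three
groups mirroring the combinations of WGBS, expression array, 450K-style
beta matrix and cohort RNA-seq); candidates are ranked by recurrence
across contrasts with DM-CpG count, methylation magnitude and gene id as
deterministic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortCriteria",
    "CRITERIA",
    "select_patients",
    "run_funnel",
    "ContrastSpec",
    "load_contrasts",
    "default_contrasts",
    "evaluate_contrasts",
    "filter_min_positions",
    "rank_candidates",
    "cohort_de_sets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortCriteria:
    """Patient inclusion rules for a cohort-level analysis."""

    name: str = "custom"
    require_platinum: bool = False
    require_expression: bool = False
    require_methylation: bool = False
    max_death_days: float | None = None
    max_relapse_days: float | None = None

    def __post_init__(self):
        if not (self.require_platinum or self.require_expression
                or self.require_methylation or self.max_death_days is not None
                or self.max_relapse_days is not None):
            raise ValueError("criteria must set at least one requirement")


CRITERIA: dict[str, CohortCriteria] = {
    # platinum therapy + expression data + death within 1100 days
    "approach1": CohortCriteria("approach1", require_platinum=True,
                                require_expression=True, max_death_days=1100),
    # platinum + RNA-seq expression + 450K methylation + relapse within 6 months
    "approach2": CohortCriteria("approach2", require_platinum=True,
                                require_expression=True, require_methylation=True,
                                max_relapse_days=183),
}

_CRITERIA_COLUMNS = {
    "require_platinum": ["platinum"],
    "require_expression": ["has_expression"],
    "require_methylation": ["has_methylation"],
    "max_death_days": ["os_days", "os_event"],
    "max_relapse_days": ["relapse_days", "relapse_event"],
}


def get_criteria(name_or_criteria) -> CohortCriteria:
    if isinstance(name_or_criteria, CohortCriteria):
        return name_or_criteria
    try:
        return CRITERIA[name_or_criteria]
    except KeyError:
        raise ValueError(f"unknown criteria preset {name_or_criteria!r}; "
                         f"available: {sorted(CRITERIA)}") from None


def select_patients(clinical: pd.DataFrame, criteria="approach1") -> set[str]:
    """Patients satisfying every active criterion.

    'Death within N days' means the death event occurred and OS <= N;
    'relapse within N days' likewise requires an observed relapse.
    Missing clinical columns raise a schema error naming the column.
    """
    crit = get_criteria(criteria)
    for attr, cols in _CRITERIA_COLUMNS.items():
        if getattr(crit, attr) not in (False, None):
            for col in cols:
                if col not in clinical.columns:
                    raise KeyError(f"clinical table lacks required column {col!r}")
    keep = pd.Series(True, index=clinical.index)
    if crit.require_platinum:
        keep &= clinical["platinum"].astype(bool)
    if crit.require_expression:
        keep &= clinical["has_expression"].astype(bool)
    if crit.require_methylation:
        keep &= clinical["has_methylation"].astype(bool)
    if crit.max_death_days is not None:
        keep &= clinical["os_event"].astype(bool) & (clinical["os_days"] <= crit.max_death_days)
    if crit.max_relapse_days is not None:
        keep &= clinical["relapse_event"].astype(bool) & (
            clinical["relapse_days"] <= crit.max_relapse_days)
    selected = set(clinical.loc[keep, "patient_id"])
    log.info("select_patients[%s]: %d of %d patients", crit.name, len(selected), len(clinical))
    return selected


def _pct(a: int, b: int) -> int | None:
    return int(round(100.0 * a / b)) if b else None


def run_funnel(de_genes: set[str], cohort_de_genes: set[str], reexpressed: set[str],
               promoter_cgi_genes: set[str], dm_genes_table) -> dict:
    """The candidate funnel.

    Successive intersections of the resistance expression signature with
    the cohort signature, the re-expressed set, the promoter-CGI set and
    the WGBS DM gene set; returns stage names/sizes/percentages (nearest
    integer of the previous stage) plus the surviving candidate set.
    Empty upstream sets propagate as empty stages, never exceptions.
    """
    dm_set = (set(dm_genes_table["gene"]) if isinstance(dm_genes_table, pd.DataFrame)
              else set(dm_genes_table))
    stages = [("differential_expression", set(de_genes))]
    for name, layer in [("cohort_concordant", cohort_de_genes),
                        ("reexpressed", reexpressed),
                        ("promoter_cgi", promoter_cgi_genes),
                        ("differentially_methylated", dm_set)]:
        stages.append((name, stages[-1][1] & set(layer)))
    report = {"stages": [], "candidates": sorted(stages[-1][1])}
    prev = None
    for name, s in stages:
        entry = {"stage": name, "n": len(s),
                 "pct_of_previous": _pct(len(s), prev) if prev is not None else None}
        report["stages"].append(entry)
        log.info("funnel %-26s n=%-6d pct_of_previous=%s",
                 name, len(s), entry["pct_of_previous"])
        prev = len(s)
    return report


@dataclass(frozen=True)
class ContrastSpec:
    """One contrast: intersect the referenced layers, after optionally
    filtering direction-annotated layers (e.g. keep only 'hyper' rows)."""

    name: str
    layers: tuple[str, ...]
    directions: dict = field(default_factory=dict)
    group: str = ""

    def __post_init__(self):
        if not self.layers:
            raise ValueError("contrast must reference at least one layer")


def _layer_set(layer, direction: str | None) -> set:
    if isinstance(layer, pd.DataFrame):
        df = layer
        if direction is not None:
            if "direction" not in df.columns:
                raise KeyError("direction filter on a layer without a 'direction' column")
            df = df[df["direction"] == direction]
        return set(df["gene"])
    if direction is not None:
        raise KeyError("direction filter on a plain gene set")
    return set(layer)


def evaluate_contrasts(specs, layers: dict) -> dict[str, set]:
    """Intersection per contrast; direction filters apply before intersecting."""
    out = {}
    for spec in specs:
        acc = None
        for name in spec.layers:
            if name not in layers:
                raise KeyError(f"contrast {spec.name!r} references unknown layer {name!r}")
            s = _layer_set(layers[name], spec.directions.get(name))
            acc = s if acc is None else acc & s
        out[spec.name] = acc or set()
    return out


def load_contrasts(path_or_stream) -> list[ContrastSpec]:
    """Load contrast specs from YAML: a list of {name, layers, directions?, group?}."""
    data = yaml.safe_load(path_or_stream.read_text()
                          if hasattr(path_or_stream, "read_text") else path_or_stream)
    specs = []
    for d in data:
        unknown = set(d) - {"name", "layers", "directions", "group"}
        if unknown:
            raise ValueError(f"unknown contrast keys {sorted(unknown)} in {d.get('name')!r}")
        specs.append(ContrastSpec(d["name"], tuple(d["layers"]),
                                  d.get("directions", {}), d.get("group", "")))
    return specs


def default_contrasts() -> list[ContrastSpec]:
    """The 24 shipped contrasts (groups 1-3)."""
    text = resources.files("epifunnel").joinpath("data/contrasts.yaml").read_text()
    return load_contrasts(text)


def filter_min_positions(candidates: pd.DataFrame, min_positions: int = 10) -> pd.DataFrame:
    """Keep candidates with strictly more than ``min_positions`` DM CpGs."""
    if candidates.empty:
        return candidates
    return candidates[candidates["n_dm_cpgs"] > min_positions].reset_index(drop=True)


def rank_candidates(contrast_sets: dict[str, set], dm_table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by recurrence across contrasts.

    Candidates are the contrast-hit genes with at least one DM CpG; sort
    keys are recurrence desc, n_dm_cpgs desc, max |delta beta| desc, gene
    id asc (a deterministic total order), rank 1-based.
    """
    counts: dict[str, int] = {}
    membership: dict[str, list[str]] = {}
    for cname in sorted(contrast_sets):
        for g in contrast_sets[cname]:
            counts[g] = counts.get(g, 0) + 1
            membership.setdefault(g, []).append(cname)
    dm = dm_table.set_index("gene") if "gene" in dm_table.columns else dm_table
    rows = []
    for g, rec in counts.items():
        if g not in dm.index:
            continue  # CandidateRecord requires >= 1 DM CpG
        rows.append({
            "gene": g,
            "recurrence": rec,
            "n_dm_cpgs": int(dm.at[g, "n_dm_cpgs"]),
            "regions": dm.at[g, "regions"],
            "max_abs_delta": float(dm.at[g, "max_abs_delta"]),
            "contrasts": ",".join(membership[g]),
        })
    if not rows:
        return pd.DataFrame(columns=["gene", "recurrence", "n_dm_cpgs", "regions",
                                     "max_abs_delta", "contrasts", "rank"])
    df = pd.DataFrame(rows)
    df = df.sort_values(["recurrence", "n_dm_cpgs", "max_abs_delta", "gene"],
                        ascending=[False, False, False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def cohort_de_sets(counts: pd.DataFrame, design: dict[str, str], selected: set[str],
                   alpha: float = 0.05, min_cpm: float = 1.0, min_samples: int = 6,
                   present_fraction: float = 1.0) -> tuple[set[str], set[str]]:
    """Down- and up-regulated gene sets, tumors of selected patients vs controls.

    Counts go through the CPM presence filter and TMM normalization, the
    two-group test runs on log2 normalized CPM, and a DE gene is kept only
    if its direction is consistent in at least ``present_fraction`` of the
    selected patients (each patient's value on the DE side of the control
    mean) - the per-patient concordance rule.
    """
    from .expression import cpm_filter, differential_expression, tmm_factors

    tumor = [c for c in counts.columns if design.get(c) == "tumor" and c in selected]
    control = [c for c in counts.columns if design.get(c) == "control"]
    if len(tumor) < 2 or len(control) < 2:
        log.info("cohort_de_sets: too few samples (tumor=%d control=%d)",
                 len(tumor), len(control))
        return set(), set()
    sub = counts[tumor + control]
    sub = cpm_filter(sub, min_cpm=min_cpm, min_samples=min(min_samples, sub.shape[1]))
    if sub.empty:
        return set(), set()
    factors = tmm_factors(sub)
    eff_lib = sub.sum(axis=0) * factors
    logcpm = pd.DataFrame(
        np.log2(sub.to_numpy() / eff_lib.to_numpy()[None, :] * 1e6 + 0.5),
        index=sub.index, columns=sub.columns)
    de = differential_expression(logcpm, {**{t: "tumor" for t in tumor},
                                          **{c: "control" for c in control}},
                                 "tumor", "control", alpha=alpha)
    de = de[de["de"]]
    ctrl_mean = logcpm[control].mean(axis=1)
    down, up = set(), set()
    for _, row in de.iterrows():
        vals = logcpm.loc[row["gene"], tumor]
        if row["logFC"] < 0:
            frac = float((vals < ctrl_mean[row["gene"]]).mean())
            if frac >= present_fraction:
                down.add(row["gene"])
        else:
            frac = float((vals > ctrl_mean[row["gene"]]).mean())
            if frac >= present_fraction:
                up.add(row["gene"])
    return down, up
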