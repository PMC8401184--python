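"""Synthetic study generator: genome, bisulfite counts, expression, cohort.

Emulates the experimental design the pipeline was built for: paired
cisplatin-sensitive (S) and cisplatin-resistant (R) phenotypes plus an
epigenetic-reactivation phenotype (RT, the 5-Aza-dC + TSA treated
resistant line), with a configurable number of planted genes that are
hypermethylated and silenced in R and partially demethylated/re-expressed
in RT, and a platinum-treated patient cohort whose methylated patients
carry an elevated death hazard.

Planted genes rotate through the three genomic zones used downstream:
alpha (promoter CpG island), beta (CpG-island shore, via a distal
gene-body island whose upstream shore carries the methylation) and gamma
(gene body).  Every planted gene keeps a promoter island so the candidate
funnel's promoter-CGI stage is informative about methylation, not island
presence.  Background sequence is GC-poor and CpG-depleted; a few
soft-masked (lowercase) CpG-rich decoys emulate repeat elements that the
island scanner must skip.

Distribution choices (Poisson coverage, binomial methylated counts,
Gaussian log2 intensities, negative-binomial RNA-seq counts, exponential
survival with administrative censoring) are the minimal standard models
for each data type.  One integer seed reproduces every artifact
byte-for-byte; independent sub-streams per artifact keep the outputs of
one generator invariant to whether the others were called.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_genome",
    "generate_wgbs",
    "generate_expression",
    "generate_cohort",
    "generate_qmsp",
    "generate_viability",
    "simulate_all",
]

_ACGT = np.frombuffer(b"ACGT", dtype="S1")
_SLOT = 7000          # bp reserved per gene (keeps shore/shelf zones of one
                      # gene's islands clear of the neighbouring gene's body)
_LEAD = 1000          # bp margin at the chromosome start
_TAIL = 8000          # bp reserved for masked repeat decoys
_ISLAND_LEN = 800
_SEGMENT_LEN = 500    # CpG-enriched (sub-island) planted segment

PHENOTYPES = ("S", "R", "RT")
_PHENO_STREAM = {"S": 11, "R": 12, "RT": 13}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the defaults that define it."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 800_000
    n_genes: int = 200
    n_planted: int = 10
    depth_mean: float = 30.0
    beta_S: float = 0.05
    beta_R_planted: float = 0.8
    beta_RT_planted: float | None = None   # default 0.65 * beta_R_planted
    expr_effect: float = 2.0               # log2 silencing in R vs S
    reexpr_effect: float = 2.0             # log2 recovery in RT vs R
    expr_sd: float = 0.25                  # log2 replicate noise
    n_reps: int = 4                        # cell-line replicates per phenotype
    n_patients: int = 200
    n_controls: int = 10
    frac_resistant: float = 0.5
    frac_meth_resistant: float = 0.7       # P(methylated | resistant)
    frac_meth_sensitive: float = 0.1
    hazard_ratio_meth: float = 3.0
    baseline_median_os: float = 600.0      # days
    admin_censor_days: float = 1825.0
    frac_promoter_cgi: float = 0.6         # background genes with promoter CGI
    ic50_sensitive: float = 1.0            # ug/mL, viability simulation
    ri_true: float = 2.3

    def __post_init__(self):
        fracs = {"beta_S": self.beta_S, "beta_R_planted": self.beta_R_planted,
                 "frac_resistant": self.frac_resistant,
                 "frac_meth_resistant": self.frac_meth_resistant,
                 "frac_meth_sensitive": self.frac_meth_sensitive,
                 "frac_promoter_cgi": self.frac_promoter_cgi}
        if self.beta_RT_planted is not None:
            fracs["beta_RT_planted"] = self.beta_RT_planted
        for k, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{k} must lie in [0, 1], got {v}")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_chrom < 1 or self.chrom_len < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.hazard_ratio_meth <= 0:
            raise ValueError("hazard_ratio_meth must be positive")

    @property
    def beta_rt(self) -> float:
        return (self.beta_RT_planted if self.beta_RT_planted is not None
                else 0.65 * self.beta_R_planted)

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]

    def patient_ids(self) -> list[str]:
        return [f"p{i + 1:04d}" for i in range(self.n_patients)]


@dataclass
class GroundTruth:
    """Planted effects: which genes, where, and which patients are methylated."""

    planted_genes: tuple[str, ...]
    planted_zone: dict[str, str]                       # gene -> alpha|beta|gamma
    planted_interval: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    patient_methylated: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_genes": list(self.planted_genes),
            "planted_zone": dict(self.planted_zone),
            "planted_interval": {g: list(v) for g, v in self.planted_interval.items()},
            "patient_methylated": dict(self.patient_methylated),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(tuple(d["planted_genes"]), dict(d["planted_zone"]),
                   {g: tuple(v) for g, v in d["planted_interval"].items()},
                   dict(d.get("patient_methylated", {})))


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), int(stream)])


def _background(rng, length: int) -> np.ndarray:
    """GC-poor, CpG-depleted sequence (85 % of CG dinucleotides broken)."""
    arr = rng.choice(_ACGT, size=length, p=[0.30, 0.20, 0.20, 0.30])
    cg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
    broken = cg[rng.random(len(cg)) < 0.85]
    arr[broken + 1] = b"T"
    return arr


def _island(rng, length: int = _ISLAND_LEN) -> np.ndarray:
    """Island-grade sequence: GC ~70 %, CpG injected every 8 bp."""
    arr = rng.choice(_ACGT, size=length, p=[0.15, 0.35, 0.35, 0.15])
    for i in range(0, length - 1, 8):
        arr[i] = b"C"
        arr[i + 1] = b"G"
    return arr


def _cpg_segment(rng, length: int = _SEGMENT_LEN) -> np.ndarray:
    """CpG-enriched but sub-island sequence (GC ~47 %): carries planted
    methylation in shores and gene bodies without triggering the scanner."""
    arr = rng.choice(_ACGT, size=length, p=[0.29, 0.21, 0.21, 0.29])
    for i in range(0, length - 1, 25):
        arr[i] = b"C"
        arr[i + 1] = b"G"
    return arr


def generate_genome(cfg: SimConfig):
    """Build the miniature genome.

    Returns (genome, genes, true_cgis, truth): a {chrom: sequence} dict, a
    gene-model table (gene, chrom, strand, tss, start, end; 0-based
    half-open), the engineered island intervals, and the ground truth of
    planted methylation.
    """
    per_chrom = (cfg.chrom_len - _LEAD - _TAIL) // _SLOT
    if per_chrom < 1 or per_chrom * cfg.n_chrom < cfg.n_genes:
        raise ValueError(
            f"chrom_len {cfg.chrom_len} too small for {cfg.n_genes} genes "
            f"on {cfg.n_chrom} chromosomes ({_SLOT} bp per gene plus margins)")
    rng = _rng(cfg, 1)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    seqs = {c: _background(rng, cfg.chrom_len) for c in chrom_names}

    ids = cfg.gene_ids()
    planted_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_planted, replace=False))
    zones = {int(gi): ("alpha", "beta", "gamma")[k % 3]
             for k, gi in enumerate(planted_idx)}

    gene_rows, cgi_rows = [], []
    planted_zone, planted_interval = {}, {}
    for i, gid in enumerate(ids):
        chrom = chrom_names[i // per_chrom]
        seq = seqs[chrom]
        s = _LEAD + (i % per_chrom) * _SLOT
        strand = "+" if rng.random() < 0.5 else "-"
        planted = i in zones
        zone = zones.get(i)
        if strand == "+":
            tss = s + 2600
            start, end = tss, tss + 2000
            prom_isl = (tss - 400, tss + 400)
            body_isl = (tss + 1200, tss + 2000)
            shore_seg = (tss + 600, tss + 600 + _SEGMENT_LEN)   # upstream of body island
            gamma_seg = (tss + 800, tss + 800 + _SEGMENT_LEN)
        else:
            tss = s + 2399
            start, end = s + 400, s + 2400
            prom_isl = (tss - 400, tss + 400)
            body_isl = (s + 400, s + 1200)
            shore_seg = (s + 1300, s + 1300 + _SEGMENT_LEN)     # 5' upstream = right of island
            gamma_seg = (s + 799, s + 799 + _SEGMENT_LEN)
        has_prom_cgi = planted or (rng.random() < cfg.frac_promoter_cgi)
        if has_prom_cgi:
            seq[prom_isl[0]:prom_isl[1]] = _island(rng)
            cgi_rows.append((chrom, *prom_isl, gid, "promoter"))
        if planted:
            if zone == "alpha":
                planted_interval[gid] = (chrom, *prom_isl)
            elif zone == "beta":
                seq[body_isl[0]:body_isl[1]] = _island(rng)
                cgi_rows.append((chrom, *body_isl, gid, "gene_body"))
                seq[shore_seg[0]:shore_seg[1]] = _cpg_segment(rng)
                planted_interval[gid] = (chrom, *shore_seg)
            else:  # gamma
                seq[gamma_seg[0]:gamma_seg[1]] = _cpg_segment(rng)
                planted_interval[gid] = (chrom, *gamma_seg)
            planted_zone[gid] = zone
        gene_rows.append((gid, chrom, strand, tss, start, end))

    # soft-masked CpG-rich decoys (repeat stand-ins) in the reserved tail
    for c in chrom_names:
        for k in range(2):
            a = cfg.chrom_len - _TAIL + 1000 + k * 3000
            decoy = np.char.lower(_island(rng))
            seqs[c][a:a + _ISLAND_LEN] = decoy

    genome = {c: seqs[c].tobytes().decode("ascii") for c in chrom_names}
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "strand", "tss", "start", "end"])
    true_cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "gene", "kind"])
    truth = GroundTruth(tuple(ids[int(i)] for i in planted_idx), planted_zone, planted_interval)
    assert set(truth.planted_genes) <= set(ids)
    return genome, genes, true_cgis, truth


def _cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every CpG (destranded, case-blind)."""
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))


def generate_wgbs(cfg: SimConfig, genome: dict[str, str], truth: GroundTruth,
                  phenotype: str) -> pd.DataFrame:
    """Per-CpG bisulfite count table for one phenotype.

    Coverage ~ Poisson(depth_mean); methylated counts ~ Binomial(coverage,
    p) with p = beta_S everywhere except planted intervals, which use
    beta_R_planted in R and beta_RT_planted in RT.  Counts from both
    strands are pooled at the forward-strand C (1-based positions).
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    rng = _rng(cfg, _PHENO_STREAM[phenotype])
    frames = []
    for chrom in sorted(genome):
        pos0 = _cpg_positions(genome[chrom])
        p = np.full(len(pos0), cfg.beta_S)
        if phenotype in ("R", "RT"):
            level = cfg.beta_R_planted if phenotype == "R" else cfg.beta_rt
            for _, (c, a, b) in truth.planted_interval.items():
                if c == chrom:
                    p[(pos0 >= a) & (pos0 < b)] = level
        cov = rng.poisson(cfg.depth_mean, len(pos0))
        meth = rng.binomial(cov, p)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos0 + 1,
            "strand": "+",
            "count_methylated": meth,
            "count_unmethylated": cov - meth,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_expression(cfg: SimConfig, genes: pd.DataFrame, truth: GroundTruth,
                        design: str = "cell-line"):
    """Expression matrix plus sample->group design map.

    'cell-line': log2 intensities for S/R/RT replicates; planted genes are
    down by expr_effect in R and recover by reexpr_effect in RT.
    'cohort': negative-binomial RNA-seq counts for tumor (per patient) and
    control samples; planted genes are down by expr_effect in tumors.
    """
    ids = list(genes["gene"])
    planted = np.isin(ids, list(truth.planted_genes))
    if design == "cell-line":
        rng = _rng(cfg, 21)
        base = rng.normal(8.0, 1.5, len(ids))
        cols, offsets = [], []
        for pheno in PHENOTYPES:
            eff = np.zeros(len(ids))
            if pheno == "R":
                eff[planted] = -cfg.expr_effect
            elif pheno == "RT":
                eff[planted] = -cfg.expr_effect + cfg.reexpr_effect
            for r in range(cfg.n_reps):
                cols.append(f"{pheno}_{r + 1}")
                offsets.append(eff)
        mat = (base[:, None] + np.stack(offsets, axis=1)
               + rng.normal(0.0, cfg.expr_sd, (len(ids), len(cols))))
        table = pd.DataFrame(mat, index=pd.Index(ids, name="gene"), columns=cols)
        dmap = {c: c.split("_")[0] for c in cols}
        return table, dmap
    if design == "cohort":
        rng = _rng(cfg, 22)
        mu = rng.lognormal(math.log(200.0), 1.0, len(ids))
        tum_mu = mu.copy()
        tum_mu[planted] = mu[planted] / 2.0 ** cfg.expr_effect
        r_disp = 10.0  # NB size; squared CV ~ 1/mu + 0.1
        cols, groups, data = [], {}, []
        for pid in cfg.patient_ids():
            cols.append(pid)
            groups[pid] = "tumor"
            data.append(rng.negative_binomial(r_disp, r_disp / (r_disp + tum_mu)))
        for k in range(cfg.n_controls):
            name = f"CTRL_{k + 1:02d}"
            cols.append(name)
            groups[name] = "control"
            data.append(rng.negative_binomial(r_disp, r_disp / (r_disp + mu)))
        table = pd.DataFrame(np.stack(data, axis=1),
                             index=pd.Index(ids, name="gene"), columns=cols)
        return table, groups
    raise ValueError(f"unknown design {design!r}; expected 'cell-line' or 'cohort'")


def generate_cohort(cfg: SimConfig, truth: GroundTruth):
    """Platinum-treated patient cohort with survival and methylation.

    Returns (clinical, beta_matrix, (expr_counts, expr_design)).  Survival
    times are exponential with the death hazard multiplied by
    hazard_ratio_meth for methylated patients, censored administratively;
    relapse is a second exponential clock that runs faster in resistant
    patients.  Fills ``truth.patient_methylated`` in place.
    """
    if cfg.n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = _rng(cfg, 31)
    pids = cfg.patient_ids()
    n = cfg.n_patients
    resistant = rng.random(n) < cfg.frac_resistant
    p_meth = np.where(resistant, cfg.frac_meth_resistant, cfg.frac_meth_sensitive)
    methylated = rng.random(n) < p_meth
    truth.patient_methylated.update({p: bool(m) for p, m in zip(pids, methylated)})

    qmsp_percent = np.where(
        methylated,
        np.clip(rng.normal(60.0, 12.0, n), 35.0, 98.0),
        np.clip(rng.normal(10.0, 6.0, n), 0.5, 25.0),
    )
    msp_methylated = qmsp_percent > 29.74

    lam0 = math.log(2.0) / cfg.baseline_median_os
    rate = lam0 * np.where(methylated, cfg.hazard_ratio_meth, 1.0)
    t_death = rng.exponential(1.0 / rate)
    os_event = t_death <= cfg.admin_censor_days
    os_days = np.minimum(t_death, cfg.admin_censor_days)

    rel_median = np.where(resistant, 240.0, 900.0)
    t_rel = rng.exponential(rel_median / math.log(2.0))
    relapse_event = t_rel <= os_days
    relapse_days = np.minimum(t_rel, os_days)
    pfs_days = relapse_days
    pfs_event = relapse_event | os_event

    clinical = pd.DataFrame({
        "patient_id": pids,
        "platinum": rng.random(n) < 0.9,
        "resistant": resistant,
        "has_expression": rng.random(n) < 0.92,
        "has_methylation": rng.random(n) < 0.92,
        "qmsp_percent": np.round(qmsp_percent, 2),
        "msp_methylated": msp_methylated,
        "os_days": np.round(os_days, 1),
        "os_event": os_event,
        "relapse_days": np.round(relapse_days, 1),
        "relapse_event": relapse_event,
        "pfs_days": np.round(pfs_days, 1),
        "pfs_event": pfs_event,
    })

    ids = cfg.gene_ids()
    planted = np.isin(ids, list(truth.planted_genes))
    beta_rng = _rng(cfg, 32)
    cols = {}
    for pid, m in zip(pids, methylated):
        b = np.clip(beta_rng.normal(0.10, 0.05, len(ids)), 0.01, 0.99)
        if m:
            b[planted] = np.clip(beta_rng.normal(0.70, 0.10, planted.sum()), 0.3, 0.99)
        cols[pid] = np.round(b, 4)
    for k in range(cfg.n_controls):
        cols[f"CTRL_{k + 1:02d}"] = np.round(
            np.clip(beta_rng.normal(0.10, 0.05, len(ids)), 0.01, 0.99), 4)
    beta_matrix = pd.DataFrame(cols, index=pd.Index(ids, name="gene"))

    genes_stub = pd.DataFrame({"gene": ids})
    expr = generate_expression(cfg, genes_stub, truth, design="cohort")
    return clinical, beta_matrix, expr


def generate_qmsp(cfg: SimConfig, truth: GroundTruth, n_replicates: int = 3,
                  ct_floor: float = 24.0, ct_sd: float = 0.15) -> pd.DataFrame:
    """Dual-probe qMSP Ct table for every planted gene across S/R/RT.

    Target percent methylated follows the configured beta levels; Cts are
    back-computed from the two-channel closed form and jittered.
    """
    rng = _rng(cfg, 41)
    levels = {"S": cfg.beta_S, "R": cfg.beta_R_planted, "RT": cfg.beta_rt}
    rows = []
    for gid in truth.planted_genes:
        for pheno, frac in levels.items():
            frac = min(max(frac, 1e-4), 1 - 1e-4)
            ct_m = ct_floor - math.log2(frac)
            ct_u = ct_floor - math.log2(1.0 - frac)
            for r in range(n_replicates):
                rows.append((gid, pheno, r + 1,
                             ct_m + rng.normal(0.0, ct_sd),
                             ct_u + rng.normal(0.0, ct_sd)))
    return pd.DataFrame(rows, columns=["gene", "phenotype", "replicate", "ct_m", "ct_u"])


def generate_viability(cfg: SimConfig, doses=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
                       n_replicates: int = 4, hill: float = 2.0,
                       signal_untreated: float = 1000.0,
                       noise_sd: float = 15.0) -> pd.DataFrame:
    """Raw dose-response signals for the S and R phenotypes.

    Log-logistic viability with IC50 = ic50_sensitive (S) and
    ic50_sensitive * ri_true (R); dose 0 is the untreated control.
    """
    rng = _rng(cfg, 42)
    ic50s = {"S": cfg.ic50_sensitive, "R": cfg.ic50_sensitive * cfg.ri_true}
    rows = []
    for pheno, ic in ic50s.items():
        for d in doses:
            frac = 1.0 if d == 0 else 1.0 / (1.0 + (d / ic) ** hill)
            for r in range(n_replicates):
                sig = max(frac * signal_untreated + rng.normal(0.0, noise_sd), 1.0)
                rows.append((pheno, d, r + 1, sig))
    return pd.DataFrame(rows, columns=["phenotype", "dose", "replicate", "signal"])


def simulate_all(cfg: SimConfig) -> dict:
    """Run every generator with one seed; returns all artifacts keyed by name."""
    genome, genes, true_cgis, truth = generate_genome(cfg)
    wgbs = {p: generate_wgbs(cfg, genome, truth, p) for p in PHENOTYPES}
    expr_cell, design_cell = generate_expression(cfg, genes, truth, "cell-line")
    clinical, beta_matrix, (expr_cohort, design_cohort) = generate_cohort(cfg, truth)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "true_cgis": true_cgis,
        "truth": truth,
        "wgbs": wgbs,
        "expr_cell": expr_cell,
        "design_cell": design_cell,
        "clinical": clinical,
        "beta_matrix": beta_matrix,
        "expr_cohort": expr_cohort,
        "design_cohort": design_cohort,
        "qmsp_cts": generate_qmsp(cfg, truth),
        "viability": generate_viability(cfg),
    }
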