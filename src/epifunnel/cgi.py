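"""CpG-island detection and promoter/shore-shelf/gene-body annotation.

Islands are detected with the Takai-Jones criteria (GC >= 55 %,
observed/expected CpG >= 0.65, length >= 500 bp) by sliding a 200-bp
window at 1-bp steps, unioning qualifying windows and trimming each merged
run to the longest sub-interval whose full span still meets all three
criteria.  Soft-masked (lowercase) bases stand in for RepeatMasker output:
any window touching a masked base is ineligible, which keeps ALU-like
repeats out of the island set.

Positions are then classified into the zones used for candidate
prioritization: alpha (promoter, TSS-2000..TSS+500 in gene orientation),
beta (CpG-island shores at 0-2 kb and shelves at 2-4 kb 5' upstream of the
island start) and gamma (gene body), with precedence alpha > beta > gamma.
Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "obs_exp_cpg",
    "gc_percent",
    "find_cgis",
    "find_cgis_genome",
    "assign_islands_to_genes",
    "classify_positions",
    "classify_position",
    "promoter_has_cgi",
    "promoter_cgi_flags",
]

_IUPAC = set("ACGTRYSWKMBDHVN")

ZONES = ("alpha", "beta_shore", "beta_shelf", "gamma", "none")


def _validate_sequence(seq: str) -> str:
    if len(seq) == 0:
        raise ValueError("empty sequence")
    upper = seq.upper()
    bad = set(upper) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return upper


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG ratio: (N_CpG * L) / (N_C * N_G).

    Returns 0.0 when the sequence contains no C or no G.  Case-insensitive
    (masking is handled by the scanner, not here).
    """
    upper = _validate_sequence(seq)
    n_c = upper.count("C")
    n_g = upper.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = upper.count("CG")
    return n_cpg * len(upper) / (n_c * n_g)


def gc_percent(seq: str) -> float:
    """G+C content in percent, case-insensitive."""
    upper = _validate_sequence(seq)
    return 100.0 * (upper.count("C") + upper.count("G")) / len(upper)


def _seq_arrays(seq: str):
    """Cumulative C, G, CpG and masked-base counts (length L+1 each)."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (b == ord("C")) | (b == ord("c"))
    is_g = (b == ord("G")) | (b == ord("g"))
    is_mask = (b >= ord("a"))  # lowercase ASCII letters
    is_cpg = np.zeros(len(b), dtype=bool)
    if len(b) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    return cum(is_c), cum(is_g), cum(is_cpg), cum(is_mask)


def _span_stats(cc, cg, ccpg, starts, ends):
    """GC% and obs/exp for [start, end) spans, from cumulative counts.

    CpG dinucleotides straddling the right boundary are not counted, so a
    span is scored exactly as its extracted sequence would be.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    length = ends - starts
    n_c = cc[ends] - cc[starts]
    n_g = cg[ends] - cg[starts]
    n_cpg = ccpg[np.maximum(ends - 1, starts)] - ccpg[starts]
    gc = 100.0 * (n_c + n_g) / length
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cpg * length / np.where(denom > 0, denom, 1), 0.0)
    return gc, oe


def _trim_run(cc, cg, ccpg, a, b, min_gc, min_oe, min_len):
    """Longest sub-interval of [a, b) meeting all three criteria, or None.

    Ties at equal length break to the leftmost start.
    """
    for length in range(b - a, min_len - 1, -1):
        starts = np.arange(a, b - length + 1)
        gc, oe = _span_stats(cc, cg, ccpg, starts, starts + length)
        ok = (gc >= min_gc) & (oe >= min_oe)
        if ok.any():
            s = int(starts[np.argmax(ok)])
            return s, s + length
    return None


def find_cgis(
    seq: str,
    chrom: str = "chr1",
    min_gc: float = 55.0,
    min_oe: float = 0.65,
    min_len: int = 500,
    window: int = 200,
    step: int = 1,
) -> pd.DataFrame:
    """Scan one sequence for CpG islands.

    Returns a DataFrame with columns chrom, start, end, name, length,
    gc_percent, obs_exp (0-based half-open, sorted, non-overlapping).
    Every reported interval re-satisfies all three criteria on its own
    extracted sequence.
    """
    _validate_sequence(seq)
    cols = ["chrom", "start", "end", "name", "length", "gc_percent", "obs_exp"]
    empty = pd.DataFrame(columns=cols)
    if window > len(seq):
        return empty
    cc, cg, ccpg, cmask = _seq_arrays(seq)
    starts = np.arange(0, len(seq) - window + 1, step)
    ends = starts + window
    gc, oe = _span_stats(cc, cg, ccpg, starts, ends)
    masked = (cmask[ends] - cmask[starts]) > 0
    ok = (gc >= min_gc) & (oe >= min_oe) & ~masked
    if not ok.any():
        return empty

    # union of qualifying windows -> merged runs
    covered = np.zeros(len(seq) + 1, dtype=np.int32)
    np.add.at(covered, starts[ok], 1)
    np.add.at(covered, ends[ok], -1)
    depth = np.cumsum(covered[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], depth.view(np.int8), [0]])))
    runs = edges.reshape(-1, 2)

    records = []
    for a, b in runs:
        if b - a < min_len:
            continue
        trimmed = _trim_run(cc, cg, ccpg, int(a), int(b), min_gc, min_oe, min_len)
        if trimmed is None:
            continue
        s, e = trimmed
        gcs, oes = _span_stats(cc, cg, ccpg, [s], [e])
        records.append((chrom, s, e, e - s, float(gcs[0]), float(oes[0])))
    if not records:
        return empty
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "length", "gc_percent", "obs_exp"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df.insert(3, "name", [f"CGI_{i + 1}" for i in range(len(df))])
    return df[cols]


def find_cgis_genome(genome: dict[str, str], **kwargs) -> pd.DataFrame:
    """Scan every chromosome of a {name: sequence} genome; island names are
    numbered consecutively genome-wide."""
    parts = [find_cgis(seq, chrom=c, **kwargs) for c, seq in sorted(genome.items())]
    parts = [p for p in parts if len(p)]
    if not parts:
        return find_cgis("A" * 1, chrom="x").iloc[0:0]
    df = pd.concat(parts, ignore_index=True)
    df["name"] = [f"CGI_{i + 1}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------------------
# zone classification
# ---------------------------------------------------------------------------

def _alpha_window(tss: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Genomic half-open span of [TSS-up, TSS+down] in gene orientation."""
    if strand == "+":
        return tss - up, tss + down + 1
    return tss - down, tss + up + 1


def assign_islands_to_genes(
    islands: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> pd.DataFrame:
    """Attach a gene and strand to each island.

    An island belongs to the gene whose promoter window or body it
    overlaps; when several genes overlap, the one whose TSS is nearest to
    the island midpoint wins.  Unassigned islands keep gene=None and the
    '+' strand convention for shore/shelf layout.
    """
    out = islands.copy()
    out["gene"] = None
    out["strand"] = "+"
    for i, isl in out.iterrows():
        g = genes[genes["chrom"] == isl["chrom"]]
        if g.empty:
            continue
        win = np.array([
            _alpha_window(t, s, promoter_up, promoter_down)
            for t, s in zip(g["tss"], g["strand"])
        ])
        lo = np.minimum(win[:, 0], g["start"].to_numpy())
        hi = np.maximum(win[:, 1], g["end"].to_numpy())
        hits = (isl["start"] < hi) & (isl["end"] > lo)
        if hits.any():
            cand = g[hits]
            mid = 0.5 * (isl["start"] + isl["end"])
            best = (cand["tss"] - mid).abs().idxmin()
            out.at[i, "gene"] = cand.at[best, "gene"]
            out.at[i, "strand"] = cand.at[best, "strand"]
    return out


def _beta_zones(islands: pd.DataFrame, shore_bp: int = 2000, shelf_bp: int = 4000,
                symmetric: bool = False):
    """Shore/shelf spans per island, 5' upstream of the island start on the
    annotated gene's strand (both sides when symmetric=True)."""
    zones = []  # (chrom, start, end, zone, gene, island)
    for _, isl in islands.iterrows():
        strand = isl.get("strand", "+")
        if strand == "+":
            shore = (isl["start"] - shore_bp, isl["start"])
            shelf = (isl["start"] - shelf_bp, isl["start"] - shore_bp)
            extra = [(isl["end"], isl["end"] + shore_bp),
                     (isl["end"] + shore_bp, isl["end"] + shelf_bp)] if symmetric else []
        else:
            shore = (isl["end"], isl["end"] + shore_bp)
            shelf = (isl["end"] + shore_bp, isl["end"] + shelf_bp)
            extra = [(isl["start"] - shore_bp, isl["start"]),
                     (isl["start"] - shelf_bp, isl["start"] - shore_bp)] if symmetric else []
        zones.append((isl["chrom"], max(shore[0], 0), max(shore[1], 0), "beta_shore",
                      isl.get("gene"), isl["name"]))
        zones.append((isl["chrom"], max(shelf[0], 0), max(shelf[1], 0), "beta_shelf",
                      isl.get("gene"), isl["name"]))
        for k, (a, b) in enumerate(extra):
            zone = "beta_shore" if k == 0 else "beta_shelf"
            zones.append((isl["chrom"], max(a, 0), max(b, 0), zone,
                          isl.get("gene"), isl["name"]))
    return zones


def classify_positions(
    chroms,
    positions,
    genes: pd.DataFrame,
    islands: pd.DataFrame,
    promoter_up: int = 2000,
    promoter_down: int = 500,
    symmetric_shores: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Classify 0-based genomic positions into alpha/beta/gamma/none zones.

    Vectorized over positions; precedence alpha > beta_shore > beta_shelf >
    gamma > none, ties within a precedence level resolved by nearest TSS
    (alpha/gamma) or leftmost island (beta).
    """
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    if chrom_sizes is not None:
        for c, p in zip(chroms, positions):
            if c not in chrom_sizes:
                raise ValueError(f"position on undeclared chromosome {c!r}")
            if not (0 <= p < chrom_sizes[c]):
                raise ValueError(f"position {p} outside chromosome {c!r}")

    if "gene" not in islands.columns:
        islands = assign_islands_to_genes(islands, genes, promoter_up, promoter_down)

    zone = np.full(len(positions), "none", dtype=object)
    gene = np.full(len(positions), None, dtype=object)
    island = np.full(len(positions), None, dtype=object)

    beta = _beta_zones(islands, symmetric=symmetric_shores)
    for c in pd.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        pos = positions[sel]
        g = genes[genes["chrom"] == c]
        # gamma first, then beta, then alpha: later assignments override.
        if len(g):
            body = (pos[:, None] >= g["start"].to_numpy()[None, :]) & (
                pos[:, None] < g["end"].to_numpy()[None, :]
            )
            dist = np.abs(pos[:, None] - g["tss"].to_numpy()[None, :]).astype(float)
            dist[~body] = np.inf
            hit = body.any(axis=1)
            j = np.argmin(dist, axis=1)
            zone[sel[hit]] = "gamma"
            gene[sel[hit]] = g["gene"].to_numpy()[j[hit]]
        for shelf_first in ("beta_shelf", "beta_shore"):
            zb = [z for z in beta if z[0] == c and z[3] == shelf_first]
            for _, a, b, zn, zg, zi in zb:
                hit = sel[(pos >= a) & (pos < b)]
                zone[hit] = zn
                gene[hit] = zg
                island[hit] = zi
        if len(g):
            win = np.array([
                _alpha_window(t, s, promoter_up, promoter_down)
                for t, s in zip(g["tss"], g["strand"])
            ])
            inwin = (pos[:, None] >= win[None, :, 0]) & (pos[:, None] < win[None, :, 1])
            dist = np.abs(pos[:, None] - g["tss"].to_numpy()[None, :]).astype(float)
            dist[~inwin] = np.inf
            hit = inwin.any(axis=1)
            j = np.argmin(dist, axis=1)
            zone[sel[hit]] = "alpha"
            gene[sel[hit]] = g["gene"].to_numpy()[j[hit]]
            island[sel[hit]] = None
    return pd.DataFrame({"chrom": chroms, "pos": positions, "zone": zone,
                         "gene": gene, "island": island})


def classify_position(chrom, pos, genes, islands, promoter_up=2000,
                      promoter_down=500, chrom_sizes=None, **kwargs):
    """Single-position convenience wrapper around :func:`classify_positions`."""
    row = classify_positions([chrom], [pos], genes, islands, promoter_up,
                             promoter_down, chrom_sizes=chrom_sizes, **kwargs).iloc[0]
    return row["zone"], row["gene"], row["island"]


def promoter_has_cgi(gene_row, islands: pd.DataFrame, promoter_up: int = 2000,
                     promoter_down: int = 500) -> bool:
    """True iff any island overlaps the gene's promoter (alpha) window by >= 1 bp."""
    a, b = _alpha_window(int(gene_row["tss"]), gene_row["strand"], promoter_up, promoter_down)
    isl = islands[islands["chrom"] == gene_row["chrom"]]
    return bool(((isl["start"] < b) & (isl["end"] > a)).any())


def promoter_cgi_flags(genes: pd.DataFrame, islands: pd.DataFrame,
                       promoter_up: int = 2000, promoter_down: int = 500) -> pd.Series:
    """Per-gene boolean Series of promoter-CGI presence."""
    return pd.Series(
        [promoter_has_cgi(r, islands, promoter_up, promoter_down) for _, r in genes.iterrows()],
        index=genes["gene"].to_numpy(),
        name="promoter_cgi",
    )
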