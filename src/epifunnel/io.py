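"""Readers and writers for the pipeline's text formats.

Conventions: CpG reports are 1-based TSV (chrom, pos, strand,
count_methylated, count_unmethylated; the strand column may be absent, in
which case counts are taken as already pooled); BED output is 0-based
half-open; matrices are TSV with a header row of sample ids and gene ids
in the first column; every writer emits a comment header carrying the
package version, seed and config hash so reruns are byte-comparable, and
every reader skips '#' lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

__all__ = [
    "header_line",
    "config_hash",
    "read_cpg_report",
    "write_cpg_report",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "write_json",
    "validate_chrom_names",
]


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:8]


def header_line(seed=None, cfg_hash=None) -> str:
    parts = [f"# epifunnel v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts)


def _write_with_header(df: pd.DataFrame, path, seed, cfg_hash, index=False):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header_line(seed, cfg_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_cpg_report(path) -> pd.DataFrame:
    """Parse a per-CpG count report; malformed rows raise with line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # column header row
                continue
            if len(fields) == 5:
                chrom, pos, strand, m, u = fields
            elif len(fields) == 4:
                chrom, pos, m, u = fields
                strand = "+"
            else:
                raise ValueError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(fields)}")
            try:
                pos_i, m_i, u_i = int(pos), int(m), int(u)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position or count") from None
            if pos_i < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            if m_i < 0 or u_i < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos_i, strand, m_i, u_i))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                     "count_methylated", "count_unmethylated"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_cpg_report(df: pd.DataFrame, path, seed=None, cfg_hash=None):
    out = df[["chrom", "pos", "strand", "count_methylated", "count_unmethylated"]]
    out = out.sort_values(["chrom", "pos"])
    _write_with_header(out, path, seed, cfg_hash)


def read_fasta(path) -> dict[str, str]:
    """FASTA to {name: sequence}; soft-masking (case) is preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path):
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


def write_bed(df: pd.DataFrame, path, seed=None, cfg_hash=None):
    """BED (0-based half-open): chrom, start, end, name and any extra of
    score/strand present in the frame, without a column header."""
    cols = ["chrom", "start", "end", "name"]
    for extra in ("score", "strand"):
        if extra in df.columns:
            cols.append(extra)
    out = df[cols].sort_values(["chrom", "start"])
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header_line(seed, cfg_hash) + "\n")
        out.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return df


def write_matrix(df: pd.DataFrame, path, seed=None, cfg_hash=None):
    _write_with_header(df, path, seed, cfg_hash, index=True)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene"
    return df


def write_clinical(df: pd.DataFrame, path, seed=None, cfg_hash=None):
    _write_with_header(df, path, seed, cfg_hash)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj, path, seed=None, cfg_hash=None):
    payload = {"_meta": {"version": __version__, "seed": seed, "config": cfg_hash}, **obj}
    Path(path).write_text(json.dumps(_plain(payload), indent=2, sort_keys=True) + "\n")


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_plain(v) for v in sorted(obj)] if isinstance(obj, set) else [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj]
    return obj


def validate_chrom_names(names, genome: dict[str, str]):
    """Cross-file consistency: every referenced chromosome must exist."""
    missing = sorted(set(names) - set(genome))
    if missing:
        raise ValueError(f"chromosome names not in genome: {missing}")
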