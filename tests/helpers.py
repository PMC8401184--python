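"""Independent oracles shared between unit and acceptance tests.

Each helper deliberately re-derives a result along a different route from
the library implementation (naive counting, row-wise exact tests, explicit
set algebra), so agreement is evidence and not tautology.
"""

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from epifunnel.methylome import bh_adjust, get_scheme


def brute_force_call_dm(profiles_S, profiles_R, scheme):
    """Row-by-row DM calling: per-row scipy fisher_exact, pandas merge,
    explicit inequality checks."""
    scheme = get_scheme(scheme)
    frames = []
    for tag, prof in (("S", profiles_S), ("R", profiles_R)):
        df = prof.copy()
        df["cov"] = df["count_methylated"] + df["count_unmethylated"]
        df = df[df["cov"] > scheme.min_coverage]
        df[f"beta_{tag}"] = df["count_methylated"] / df["cov"]
        frames.append(df.rename(columns={
            "count_methylated": f"m_{tag}", "count_unmethylated": f"u_{tag}"}))
    m = frames[0].merge(frames[1], on=["chrom", "pos"])
    pvals = [fisher_exact([[r.m_S, r.u_S], [r.m_R, r.u_R]])[1] for r in m.itertuples()]
    m["p"] = pvals
    m["q"] = bh_adjust(pvals)
    called = []
    for r in m.itertuples():
        ok = r.beta_S < scheme.max_beta_S and r.q < scheme.fdr
        if scheme.min_beta_R is not None:
            ok = ok and r.beta_R > scheme.min_beta_R
        if scheme.min_delta is not None:
            d = r.beta_R - r.beta_S
            ok = ok and (d > scheme.min_delta if scheme.delta_strict else d >= scheme.min_delta)
        if ok:
            called.append((r.chrom, r.pos))
    return set(called)


def naive_gc_oe(seq):
    """Direct character counting of GC% and obs/exp, no cumulative sums."""
    up = seq.upper()
    n_c = sum(ch == "C" for ch in up)
    n_g = sum(ch == "G" for ch in up)
    n_cpg = sum(up[i] == "C" and up[i + 1] == "G" for i in range(len(up) - 1))
    gc = 100.0 * (n_c + n_g) / len(up)
    oe = 0.0 if n_c == 0 or n_g == 0 else n_cpg * len(up) / (n_c * n_g)
    return gc, oe


def exhaustive_find_cgis(seq, min_gc=55.0, min_oe=0.65, min_len=500, window=200):
    """Exhaustive enumeration of qualifying 200-bp windows (naive scoring),
    union-merge, then exhaustive longest-qualifying-subinterval trim."""
    if window > len(seq):
        return []
    qual = []
    for s in range(0, len(seq) - window + 1):
        w = seq[s:s + window]
        if any(c.islower() for c in w):
            continue
        gc, oe = naive_gc_oe(w)
        if gc >= min_gc and oe >= min_oe:
            qual.append((s, s + window))
    if not qual:
        return []
    merged = []
    cur = list(qual[0])
    for a, b in qual[1:]:
        if a <= cur[1]:
            cur[1] = max(cur[1], b)
        else:
            merged.append(tuple(cur))
            cur = [a, b]
    merged.append(tuple(cur))
    islands = []
    for a, b in merged:
        found = None
        for length in range(b - a, min_len - 1, -1):
            for s in range(a, b - length + 1):
                gc, oe = naive_gc_oe(seq[s:s + length])
                if gc >= min_gc and oe >= min_oe:
                    found = (s, s + length)
                    break
            if found:
                break
        if found:
            islands.append(found)
    return islands


def brute_force_contrasts(specs, layers):
    """Explicit set algebra with loops and python sets."""
    out = {}
    for spec in specs:
        genes = None
        for layer_name in spec.layers:
            layer = layers[layer_name]
            if isinstance(layer, pd.DataFrame):
                want = spec.directions.get(layer_name)
                s = {g for g, d in zip(layer["gene"], layer["direction"])
                     if want is None or d == want}
            else:
                s = set(layer)
            genes = s if genes is None else {g for g in genes if g in s}
        out[spec.name] = genes or set()
    return out


def manual_logrank(times, events, groups):
    """Hand-rolled two-group log-rank O-E/V statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var
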