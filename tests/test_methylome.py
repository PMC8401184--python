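"""Beta computation, the exact test, BH adjustment and DM calling, each
checked against an independent route (scipy row-wise tests, hand formulas,
brute-force filtering)."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from epifunnel.methylome import (SCHEMES, ThresholdScheme, bh_adjust, call_dm,
                                 compute_beta, dm_genes, pool_counts)
from epifunnel.methylome import test_cpg as exact_cpg_p
from helpers import brute_force_call_dm


def _profile(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "count_methylated",
                                       "count_unmethylated"])


class TestComputeBeta:
    def test_retained_and_removed_at_boundary(self):
        df = _profile([("chr1", 10, 5, 5), ("chr1", 20, 3, 2), ("chr1", 30, 0, 8)])
        out = compute_beta(df, min_coverage=5)
        assert list(out["pos"]) == [10, 30]          # coverage 5 is not > 5
        assert out.loc[out["pos"] == 10, "beta"].item() == 0.5
        assert out.loc[out["pos"] == 30, "beta"].item() == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_beta(_profile([("chr1", 1, -1, 5)]))


class TestExactTest:
    def test_strong_association(self):
        # frozen from exact hypergeometric enumeration of the 2x2 table
        assert exact_cpg_p(9, 1, 1, 9) == pytest.approx(1.0933e-3, rel=1e-3)

    def test_no_association(self):
        assert exact_cpg_p(5, 5, 5, 5) == 1.0

    def test_two_by_two_minimal(self):
        assert exact_cpg_p(1, 0, 0, 1) == 1.0

    def test_empty_margin_warns(self):
        with pytest.warns(UserWarning, match="margin"):
            assert exact_cpg_p(0, 0, 3, 4) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            exact_cpg_p(-1, 2, 3, 4)

    def test_matches_scipy_on_random_tables(self, rng):
        tables = rng.integers(0, 40, size=(200, 4))
        for a, b, c, d in tables:
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            expected = fisher_exact([[a, b], [c, d]])[1]
            assert exact_cpg_p(a, b, c, d) == pytest.approx(expected, rel=1e-9)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        # q_i = min over j>=i of p_(j) * m / j -> all 0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_adjust([]).size == 0

    def test_dominates_p_and_monotone(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_range_validation(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _big_pair(beta_s, beta_r, n=100):
    """One CpG with large counts at the given betas, plus null companions
    so BH has context."""
    rows_s = [("chr1", 1, int(beta_s * n), n - int(beta_s * n))]
    rows_r = [("chr1", 1, int(beta_r * n), n - int(beta_r * n))]
    for i in range(2, 8):
        rows_s.append(("chr1", i, 5, 95))
        rows_r.append(("chr1", i, 5, 95))
    return _profile(rows_s), _profile(rows_r)


class TestCallDm:
    def test_readjusted_inequalities(self):
        s, r = _big_pair(0.1, 0.8)
        out = call_dm(s, r, "readjusted")
        assert 1 in set(out["pos"])                  # 0.1<0.2 and delta 0.7>0.4
        assert out.loc[out["pos"] == 1, "direction"].item() == "hyper"
        s, r = _big_pair(0.25, 0.9)
        assert 1 not in set(call_dm(s, r, "readjusted")["pos"])  # beta_S fails

    def test_disjoint_coordinates_warns_empty(self):
        s = _profile([("chr1", 1, 5, 10)])
        r = _profile([("chr2", 1, 5, 10)])
        with pytest.warns(UserWarning, match="shared"):
            assert call_dm(s, r, "readjusted").empty

    @pytest.mark.parametrize("scheme", ["initial", "readjusted", "matrix_a", "matrix_b"])
    def test_brute_force_oracle_500_cpgs(self, scheme, rng):
        n = 500
        pos = np.arange(1, n + 1)
        cov_s, cov_r = rng.poisson(20, n), rng.poisson(20, n)
        p_r = np.where(rng.random(n) < 0.3, 0.8, 0.05)
        s = _profile(list(zip(["chr1"] * n, pos, rng.binomial(cov_s, 0.05),
                              cov_s - rng.binomial(cov_s, 0.05))))
        s["count_unmethylated"] = cov_s - s["count_methylated"]
        meth_r = rng.binomial(cov_r, p_r)
        r = _profile(list(zip(["chr1"] * n, pos, meth_r, cov_r - meth_r)))
        got = set(zip(call_dm(s, r, scheme)["chrom"], call_dm(s, r, scheme)["pos"]))
        assert got == brute_force_call_dm(s, r, scheme)

    def test_tightening_is_monotone(self, rng):
        n = 300
        pos = np.arange(1, n + 1)
        cov = rng.poisson(25, n)
        p_r = np.where(rng.random(n) < 0.4, rng.uniform(0.3, 0.9, n), 0.05)
        meth_s = rng.binomial(cov, 0.08)
        meth_r = rng.binomial(cov, p_r)
        s = _profile(list(zip(["chr1"] * n, pos, meth_s, cov - meth_s)))
        r = _profile(list(zip(["chr1"] * n, pos, meth_r, cov - meth_r)))
        loose = ThresholdScheme("loose", max_beta_S=0.3, min_delta=0.2)
        for tight in (
            ThresholdScheme("t1", max_beta_S=0.2, min_delta=0.2),
            ThresholdScheme("t2", max_beta_S=0.3, min_delta=0.5),
            ThresholdScheme("t3", max_beta_S=0.3, min_delta=0.2, min_coverage=15),
            ThresholdScheme("t4", max_beta_S=0.3, min_delta=0.2, fdr=0.01),
        ):
            a = set(call_dm(s, r, loose)["pos"])
            b = set(call_dm(s, r, tight)["pos"])
            assert b <= a

    def test_pool_counts_sums_replicates(self):
        a = _profile([("chr1", 1, 3, 4), ("chr1", 2, 1, 1)])
        b = _profile([("chr1", 1, 2, 2)])
        pooled = pool_counts([a, b])
        assert pooled.loc[pooled["pos"] == 1, "count_methylated"].item() == 5
        assert pooled.loc[pooled["pos"] == 2, "count_unmethylated"].item() == 1


class TestDmGenes:
    def _dm(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "delta"])

    def test_promoter_rollup(self):
        dm = self._dm([("chr1", 10, 0.5), ("chr1", 11, 0.6), ("chr1", 12, 0.7),
                       ("chr1", 99, 0.9)])
        ann = pd.DataFrame({"zone": ["alpha", "alpha", "alpha", "none"],
                            "gene": ["gA", "gA", "gA", None]})
        out = dm_genes(dm, ann)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["gene"], row["n_dm_cpgs"], row["regions"]) == ("gA", 3, "alpha")
        assert row["max_abs_delta"] == pytest.approx(0.7)

    def test_gene_without_dm_absent(self):
        dm = self._dm([("chr1", 10, 0.5)])
        ann = pd.DataFrame({"zone": ["none"], "gene": [None]})
        assert dm_genes(dm, ann).empty

    def test_groupby_oracle(self, rng):
        n = 200
        genes = [f"g{k}" for k in rng.integers(0, 12, n)]
        zones = rng.choice(["alpha", "beta_shore", "gamma", "none"], n)
        dm = self._dm([("chr1", i + 1, d) for i, d in enumerate(rng.uniform(-1, 1, n))])
        ann = pd.DataFrame({"zone": zones, "gene": genes})
        out = dm_genes(dm, ann).set_index("gene")
        # independent tally
        expected = {}
        for g, z, d in zip(genes, zones, dm["delta"]):
            if z == "none":
                continue
            e = expected.setdefault(g, [0, set(), 0.0])
            e[0] += 1
            e[1].add(z)
            e[2] = max(e[2], abs(d))
        assert set(out.index) == set(expected)
        for g, (cnt, zs, mx) in expected.items():
            assert out.at[g, "n_dm_cpgs"] == cnt
            assert out.at[g, "regions"] == ",".join(sorted(zs))
            assert out.at[g, "max_abs_delta"] == pytest.approx(mx)
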