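"""Island detection against exhaustive enumeration, and the zone
classification contract (alpha > beta > gamma precedence)."""

import numpy as np
import pandas as pd
import pytest

from epifunnel.cgi import (assign_islands_to_genes, classify_position,
                           classify_positions, find_cgis, gc_percent,
                           obs_exp_cpg, promoter_cgi_flags, promoter_has_cgi)
from helpers import exhaustive_find_cgis, naive_gc_oe


def _island_seq(rng, length=800):
    arr = rng.choice(list("ACGT"), size=length, p=[0.15, 0.35, 0.35, 0.15])
    for i in range(0, length - 1, 8):
        arr[i], arr[i + 1] = "C", "G"
    return "".join(arr)


def _at_rich(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length, p=[0.4, 0.1, 0.1, 0.4]))


class TestObsExp:
    def test_cg_repeat_closed_form(self):
        assert obs_exp_cpg("CG" * 250) == pytest.approx(2.0)

    def test_no_cg(self):
        assert obs_exp_cpg("AT" * 250) == 0.0

    def test_matches_naive_recount(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        gc_naive, oe_naive = naive_gc_oe(seq)
        assert obs_exp_cpg(seq) == pytest.approx(oe_naive)
        assert gc_percent(seq) == pytest.approx(gc_naive)

    def test_validation(self):
        with pytest.raises(ValueError):
            obs_exp_cpg("")
        with pytest.raises(ValueError):
            obs_exp_cpg("ACGX")


class TestFindCgis:
    def test_engineered_island_recovered(self, rng):
        isl = _island_seq(rng, 600)
        seq = _at_rich(rng, 2000) + isl + _at_rich(rng, 2000)
        out = find_cgis(seq)
        assert len(out) == 1
        r = out.iloc[0]
        assert abs(r["start"] - 2000) < 150 and abs(r["end"] - 2600) < 150
        assert r["gc_percent"] >= 55 and r["obs_exp"] >= 0.65 and r["length"] >= 500

    def test_masked_island_skipped(self, rng):
        isl = _island_seq(rng, 600).lower()
        seq = _at_rich(rng, 1000) + isl + _at_rich(rng, 1000)
        assert find_cgis(seq).empty

    def test_window_longer_than_sequence(self):
        assert find_cgis("ACGT" * 10).empty

    @pytest.mark.parametrize("layout", ["single", "two_islands", "masked_middle", "edge"])
    def test_exhaustive_oracle_under_5kb(self, layout, rng):
        if layout == "single":
            seq = _at_rich(rng, 1500) + _island_seq(rng, 700) + _at_rich(rng, 1500)
        elif layout == "two_islands":
            seq = (_at_rich(rng, 800) + _island_seq(rng, 600) + _at_rich(rng, 1200)
                   + _island_seq(rng, 550) + _at_rich(rng, 800))
        elif layout == "masked_middle":
            isl = _island_seq(rng, 900)
            seq = _at_rich(rng, 1000) + isl[:400] + isl[400:500].lower() + isl[500:] \
                + _at_rich(rng, 1000)
        else:
            seq = _island_seq(rng, 700) + _at_rich(rng, 1000)
        got = list(zip(find_cgis(seq)["start"], find_cgis(seq)["end"]))
        assert got == exhaustive_find_cgis(seq)

    def test_idempotent_on_own_output(self, small_genome):
        genome, *_ = small_genome
        islands = find_cgis(genome["chr1"], chrom="chr1")
        assert len(islands) > 0
        for _, r in islands.iterrows():
            again = find_cgis(genome["chr1"][r["start"]:r["end"]])
            assert len(again) == 1
            assert again.iloc[0]["start"] == 0
            assert again.iloc[0]["end"] == r["end"] - r["start"]

    def test_reported_islands_satisfy_criteria_on_extract(self, small_genome):
        genome, *_ = small_genome
        islands = find_cgis(genome["chr2"], chrom="chr2")
        for _, r in islands.iterrows():
            sub = genome["chr2"][r["start"]:r["end"]]
            gc, oe = naive_gc_oe(sub)
            assert gc >= 55 and oe >= 0.65 and len(sub) >= 500


def _toy_models():
    genes = pd.DataFrame([
        ("gPlus", "chr1", "+", 10_000, 10_000, 13_000),
        ("gMinus", "chr1", "-", 29_999, 27_000, 30_000),
    ], columns=["gene", "chrom", "strand", "tss", "start", "end"])
    islands = pd.DataFrame([
        ("chr1", 20_000, 20_800, "CGI_1"),
    ], columns=["chrom", "start", "end", "name"])
    islands["gene"] = [None]
    islands["strand"] = ["+"]
    return genes, islands


class TestClassifyPosition:
    def test_tss_is_alpha_both_strands(self):
        genes, islands = _toy_models()
        assert classify_position("chr1", 10_000, genes, islands)[0] == "alpha"
        assert classify_position("chr1", 29_999, genes, islands)[0] == "alpha"

    def test_shore_and_shelf_upstream_of_island(self):
        genes, islands = _toy_models()
        zone, _, isl = classify_position("chr1", 20_000 - 1000, genes, islands)
        assert (zone, isl) == ("beta_shore", "CGI_1")
        zone, _, _ = classify_position("chr1", 20_000 - 3000, genes, islands)
        assert zone == "beta_shelf"

    def test_minus_strand_shore_is_genomic_right(self):
        genes, islands = _toy_models()
        islands = islands.assign(strand=["-"])
        assert classify_position("chr1", 20_800 + 500, genes, islands)[0] == "beta_shore"
        assert classify_position("chr1", 20_800 + 2500, genes, islands)[0] == "beta_shelf"
        assert classify_position("chr1", 20_000 - 1000, genes, islands)[0] == "none"

    def test_gene_body_gamma_and_intergenic_none(self):
        genes, islands = _toy_models()
        zone, gene, _ = classify_position("chr1", 12_700, genes, islands)
        assert (zone, gene) == ("gamma", "gPlus")
        assert classify_position("chr1", 26_000, genes, islands)[0] == "none"

    def test_alpha_precedence_over_beta_and_gamma(self):
        genes, islands = _toy_models()
        islands.loc[0, ["start", "end"]] = [10_500, 11_200]  # island inside promoter
        # TSS+100 is in the promoter window AND in the gene body AND in the
        # island's upstream shore -> alpha wins
        assert classify_position("chr1", 10_100, genes, islands)[0] == "alpha"

    def test_partition_single_zone_per_position(self, rng):
        genes, islands = _toy_models()
        pos = rng.integers(0, 40_000, 500)
        out = classify_positions(["chr1"] * 500, pos, genes, islands)
        assert out["zone"].isin(["alpha", "beta_shore", "beta_shelf", "gamma", "none"]).all()
        assert len(out) == 500

    def test_off_chromosome_errors(self):
        genes, islands = _toy_models()
        with pytest.raises(ValueError, match="chromosome"):
            classify_position("chr9", 100, genes, islands, chrom_sizes={"chr1": 40_000})
        with pytest.raises(ValueError, match="outside"):
            classify_position("chr1", 99_999_999, genes, islands,
                              chrom_sizes={"chr1": 40_000})


class TestPromoterCgi:
    def test_island_spanning_tss(self):
        genes, islands = _toy_models()
        islands.loc[0, ["start", "end"]] = [9_800, 10_600]
        assert promoter_has_cgi(genes.iloc[0], islands)

    def test_distant_island(self):
        genes, islands = _toy_models()
        assert not promoter_has_cgi(genes.iloc[0], islands)  # 10 kb away

    def test_flags_match_interval_overlap_oracle(self, small_genome):
        genome, genes, cgis, _ = small_genome
        islands = cgis.rename(columns={"kind": "name"}).copy()
        islands["name"] = [f"CGI_{i}" for i in range(len(islands))]
        flags = promoter_cgi_flags(genes, islands)
        for _, g in genes.iterrows():
            if g["strand"] == "+":
                a, b = g["tss"] - 2000, g["tss"] + 501
            else:
                a, b = g["tss"] - 500, g["tss"] + 2001
            expect = any((isl["chrom"] == g["chrom"]) and (isl["start"] < b)
                         and (isl["end"] > a) for _, isl in islands.iterrows())
            assert flags[g["gene"]] == expect
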