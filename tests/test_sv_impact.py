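"""Impact rule table, interval index and the per-base sweep oracle."""

import itertools

import numpy as np
import pytest

from ganopan.io_formats import GeneModel, SvRecord, Transcript
from ganopan.sv_impact import (
    IMPACTS, REGIONS, GeneIndex, ImpactConfig, annotate, classify_impact,
    impact_rule, summarize_impacts,
)
from conftest import make_gene
from _oracles import sv_impact_oracle

CFG = ImpactConfig(promoter_len=120, downstream_len=60)


class TestRuleTable:
    def test_totality_over_full_cross_product(self):
        """Every (svtype, region, frame-feature) combination maps to exactly
        one impact class."""
        for svtype, region, fs, ss, bk in itertools.product(
                ("INS", "DEL", "DUP", "INV", "TRA"), REGIONS,
                (False, True), (False, True), (False, True)):
            impact, why = impact_rule(svtype, region, fs, ss, bk)
            assert impact in IMPACTS and why

    def test_promoter_insertion_is_modifier(self, two_exon_gene):
        """A 440 bp insertion anchored in the promoter window annotates as a
        modifier regulatory variant."""
        prom = two_exon_gene.promoter(CFG.promoter_len)
        sv = SvRecord("ins440", "chr1", "INS", prom[0] + 10, prom[0] + 10, 440)
        ann = classify_impact(sv, two_exon_gene, CFG)
        assert (ann.region, ann.impact) == ("promoter_upstream", "modifier")

    def test_inframe_cds_deletion_is_moderate(self, two_exon_gene):
        cs = two_exon_gene.transcripts[0].cds[0][0]
        sv = SvRecord("d3", "chr1", "DEL", cs + 6, cs + 9, 3)
        ann = classify_impact(sv, two_exon_gene, CFG)
        assert (ann.region, ann.impact) == ("cds", "moderate")

    def test_frameshift_insertion_is_high(self, two_exon_gene):
        cs = two_exon_gene.transcripts[0].cds[0][0]
        sv = SvRecord("i1", "chr1", "INS", cs + 10, cs + 10, 7)
        assert classify_impact(sv, two_exon_gene, CFG).impact == "high"

    def test_inversion_containing_gene_is_moderate(self, two_exon_gene):
        g = two_exon_gene
        sv = SvRecord("v1", "chr1", "INV", g.start - 5, g.end + 5,
                      g.end - g.start + 10)
        assert classify_impact(sv, g, CFG).impact == "moderate"

    def test_inversion_breakpoint_in_cds_is_high(self, two_exon_gene):
        cs, ce = two_exon_gene.transcripts[0].cds[0]
        sv = SvRecord("v2", "chr1", "INV", cs + 5, ce + 1000, ce + 995 - cs)
        assert classify_impact(sv, two_exon_gene, CFG).impact == "high"

    def test_no_intersection_is_an_error(self, two_exon_gene):
        sv = SvRecord("far", "chr1", "DEL", 1, 5, 4)
        with pytest.raises(ValueError, match="does not intersect"):
            classify_impact(sv, two_exon_gene, CFG)


class TestSweepOracle:
    """Exhaustive DEL/INS sweep over a two-exon gene vs the per-base oracle."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_deletion_sweep_matches_oracle(self, strand):
        gene = make_gene(strand=strand, start=400)
        lo = gene.start - CFG.promoter_len - 20
        hi = gene.end + CFG.promoter_len + 20
        checked = 0
        for s in range(lo, hi, 1):
            for ln in range(1, 51, 7):
                expected = sv_impact_oracle("DEL", s, s + ln, ln, gene,
                                            CFG.promoter_len, CFG.downstream_len)
                sv = SvRecord("d", "chr1", "DEL", s, s + ln, ln)
                if expected is None:
                    with pytest.raises(ValueError):
                        classify_impact(sv, gene, CFG)
                    continue
                ann = classify_impact(sv, gene, CFG)
                assert (ann.region, ann.impact) == expected, (s, ln)
                checked += 1
        assert checked > 1000

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_insertion_sweep_matches_oracle(self, strand):
        gene = make_gene(strand=strand, start=400)
        lo = gene.start - CFG.promoter_len - 20
        hi = gene.end + CFG.promoter_len + 20
        for p in range(lo, hi):
            for ln in (1, 2, 3, 6, 440):
                expected = sv_impact_oracle("INS", p, p, ln, gene,
                                            CFG.promoter_len, CFG.downstream_len)
                sv = SvRecord("i", "chr1", "INS", p, p, ln)
                if expected is None:
                    with pytest.raises(ValueError):
                        classify_impact(sv, gene, CFG)
                    continue
                ann = classify_impact(sv, gene, CFG)
                assert (ann.region, ann.impact) == expected, (p, ln)

    def test_inv_dup_tra_spot_checks_match_oracle(self):
        gene = make_gene(start=400)
        rng = np.random.default_rng(2)
        for svtype in ("INV", "DUP", "TRA"):
            for _ in range(300):
                s = int(rng.integers(gene.start - 150, gene.end + 150))
                if svtype == "TRA":
                    sv_args = (s, s, 1)
                else:
                    ln = int(rng.integers(1, 120))
                    sv_args = (s, s + ln, ln)
                expected = sv_impact_oracle(svtype, sv_args[0], sv_args[1],
                                            sv_args[2], gene,
                                            CFG.promoter_len, CFG.downstream_len)
                sv = SvRecord("x", "chr1", svtype, *sv_args)
                if expected is None:
                    with pytest.raises(ValueError):
                        classify_impact(sv, gene, CFG)
                    continue
                ann = classify_impact(sv, gene, CFG)
                assert (ann.region, ann.impact) == expected


class TestStrandSymmetry:
    def test_mirrored_gene_gives_same_impacts(self):
        """Reflecting gene and variant coordinates and flipping strand must
        not change any impact class."""
        L = 10_000
        fwd = make_gene(strand="+", start=2000)

        def mirror_ivals(ivals):
            return sorted((L - e, L - s) for s, e in ivals)

        tr = fwd.transcripts[0]
        rev = GeneModel(fwd.gene_id, fwd.chrom, "-", L - fwd.end, L - fwd.start,
                        [Transcript(tr.transcript_id, mirror_ivals(tr.exons),
                                    mirror_ivals(tr.cds))])
        rng = np.random.default_rng(5)
        for _ in range(400):
            s = int(rng.integers(fwd.start - CFG.promoter_len,
                                 fwd.end + CFG.promoter_len))
            ln = int(rng.integers(1, 60))
            for svtype in ("DEL", "DUP", "INV"):
                sv_f = SvRecord("f", "chr1", svtype, s, s + ln, ln)
                sv_r = SvRecord("r", "chr1", svtype, L - (s + ln), L - s, ln)
                try:
                    a = classify_impact(sv_f, fwd, CFG)
                except ValueError:
                    with pytest.raises(ValueError):
                        classify_impact(sv_r, rev, CFG)
                    continue
                b = classify_impact(sv_r, rev, CFG)
                assert (a.region, a.impact) == (b.region, b.impact)


class TestIndex:
    def test_linear_scan_equivalence(self):
        rng = np.random.default_rng(9)
        genes = []
        pos = 500
        for i in range(1000):
            pos += int(rng.integers(300, 2500))
            g = make_gene(f"g{i:04d}", chrom=f"chr{i % 4}", start=pos,
                          strand="+" if rng.random() < 0.5 else "-")
            genes.append(g)
            pos = g.end
        idx = GeneIndex(genes, CFG)

        def linear(chrom, s, e):
            out = []
            for g in genes:
                if g.chrom != chrom:
                    continue
                for a, b in (g.span, g.promoter(CFG.promoter_len),
                             g.downstream(CFG.downstream_len)):
                    if (s == e and a <= s < b) or (s < e and s < b and a < e):
                        out.append(g.gene_id)
                        break
            return sorted(out)

        for _ in range(500):
            chrom = f"chr{int(rng.integers(0, 4))}"
            s = int(rng.integers(0, pos))
            e = s + int(rng.integers(0, 800))
            assert sorted(g.gene_id for g in idx.query(chrom, s, e)) == \
                   linear(chrom, s, e)

    def test_duplicate_gene_id_rejected(self):
        g = make_gene("dup")
        with pytest.raises(ValueError, match="duplicate"):
            GeneIndex([g, make_gene("dup", start=9000)], CFG)

    def test_query_between_genes_is_empty(self):
        g1 = make_gene("a", start=1000)
        g2 = make_gene("b", start=g1.end + 5000)
        idx = GeneIndex([g1, g2], CFG)
        mid = g1.end + 2000
        assert idx.query("chr1", mid, mid + 10) == []


class TestSummaries:
    def test_max_rule_per_sv_and_gene(self):
        from ganopan.sv_impact import ImpactAnnotation
        anns = [ImpactAnnotation("sv1", "gA", "cds", "high", "x"),
                ImpactAnnotation("sv1", "gB", "promoter_upstream", "modifier", "x")]
        sv_counts, gene_counts = summarize_impacts(anns)
        assert sv_counts == {"high": 1, "moderate": 0, "low": 0, "modifier": 0}
        assert gene_counts == {"high": 1, "moderate": 0, "low": 0, "modifier": 1}

    def test_empty_annotations(self):
        sv_counts, gene_counts = summarize_impacts([])
        assert set(sv_counts.values()) == {0} and set(gene_counts.values()) == {0}

    def test_annotate_determinism(self):
        genes = [make_gene("a", start=1000), make_gene("b", start=8000)]
        svs = [SvRecord("s1", "chr1", "DEL", 1035, 1060, 25),
               SvRecord("s2", "chr1", "INS", 7950, 7950, 440)]
        a = annotate(genes, svs, CFG)
        b = annotate(genes, svs, CFG)
        assert a == b and len(a) >= 2
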