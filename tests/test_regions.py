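"""Region classification and gene-model loading tests."""

import logging

import numpy as np
import pytest

from caddregions.io import write_gtf
from caddregions.regions import (
    GeneModel,
    RegionCategory,
    TranscriptModel,
    Variant,
    annotate_variants,
    classify_variant,
    load_gene_model,
)


def make_coding_plus():
    return TranscriptModel(
        transcript_id="tc",
        gene_id="gc",
        chrom="chr1",
        strand="+",
        tx_start=10000,
        tx_end=12000,
        exons=[(10000, 10400), (11000, 11400), (11800, 12000)],
        cds_start=10100,
        cds_end=11900,
    )


def make_noncoding():
    return TranscriptModel(
        transcript_id="tn",
        gene_id="gn",
        chrom="chr1",
        strand="+",
        tx_start=50000,
        tx_end=51000,
        exons=[(50000, 50200), (50800, 51000)],
    )


def v(chrom, pos):
    return Variant(chrom=chrom, pos=pos, ref="A", alt="T", score=1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10402, RegionCategory.SPLICING),  # 2 bp past an exon 3' boundary
            (10403, RegionCategory.INTRONIC),  # 3 bp: intron proper
            (10999, RegionCategory.SPLICING),  # 1 bp before the next exon
            (10500, RegionCategory.INTRONIC),
            (9500, RegionCategory.UPSTREAM),  # 500 bp 5' of the TSS
            (9000, RegionCategory.UPSTREAM),  # exactly 1000 bp away
            (8999, RegionCategory.INTERGENIC),  # 1001 bp away
            (12500, RegionCategory.DOWNSTREAM),
            (13000, RegionCategory.DOWNSTREAM),
            (13001, RegionCategory.INTERGENIC),
            (10050, RegionCategory.UTR5),
            (10100, RegionCategory.EXONIC),  # CDS start inclusive
            (11950, RegionCategory.UTR3),
            (30000, RegionCategory.INTERGENIC),  # far from every window
        ],
    )
    def test_coding_plus_strand(self, pos, expected):
        assert classify_variant(v("chr1", pos), [make_coding_plus()]) == expected

    def test_noncoding_transcript_labels(self):
        t = make_noncoding()
        assert classify_variant(v("chr1", 50100), [t]) == RegionCategory.NCRNA_EXONIC
        assert classify_variant(v("chr1", 50500), [t]) == RegionCategory.NCRNA_INTRONIC
        # noncoding transcripts get no splicing category
        assert classify_variant(v("chr1", 50201), [t]) == RegionCategory.NCRNA_INTRONIC

    def test_minus_strand_windows(self):
        t = make_coding_plus()
        t.strand = "-"
        # 500 bp beyond tx_end (higher coordinate) is upstream on '-'
        assert classify_variant(v("chr1", 12500), [t]) == RegionCategory.UPSTREAM
        assert classify_variant(v("chr1", 9500), [t]) == RegionCategory.DOWNSTREAM
        # UTR identities flip with strand
        assert classify_variant(v("chr1", 10050), [t]) == RegionCategory.UTR3
        assert classify_variant(v("chr1", 11950), [t]) == RegionCategory.UTR5

    def test_absent_chromosome_is_intergenic(self, caplog):
        with caplog.at_level(logging.WARNING):
            cat = classify_variant(v("chrX", 100), [make_coding_plus()])
        assert cat == RegionCategory.INTERGENIC

    def test_precedence_splicing_beats_ncrna_exon(self):
        coding = make_coding_plus()
        nc = TranscriptModel(
            transcript_id="tn2",
            gene_id="gn2",
            chrom="chr1",
            strand="+",
            tx_start=10300,
            tx_end=10600,
            exons=[(10300, 10600)],
        )
        # 10402 is splicing for the coding transcript and ncRNA-exonic for nc
        assert classify_variant(v("chr1", 10402), [coding, nc]) == RegionCategory.SPLICING
        assert classify_variant(v("chr1", 10402), [nc, coding]) == RegionCategory.SPLICING

    def test_order_invariance_on_random_overlapping_fixtures(self, rng):
        for _ in range(40):
            transcripts = []
            for k in range(3):
                start = int(rng.integers(5000, 8000))
                e1 = (start, start + int(rng.integers(50, 200)))
                gap = int(rng.integers(60, 300))
                e2s = e1[1] + 1 + gap
                e2 = (e2s, e2s + int(rng.integers(50, 200)))
                coding = bool(rng.integers(0, 2))
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"t{k}",
                        gene_id=f"g{k}",
                        chrom="chr1",
                        strand="+" if rng.integers(0, 2) else "-",
                        tx_start=e1[0],
                        tx_end=e2[1],
                        exons=[e1, e2],
                        cds_start=e1[0] + 10 if coding else None,
                        cds_end=e2[1] - 10 if coding else None,
                    )
                )
            positions = rng.integers(3500, 10500, size=40)
            ref = [classify_variant(v("chr1", int(p)), transcripts) for p in positions]
            perm = [transcripts[i] for i in rng.permutation(3)]
            assert [classify_variant(v("chr1", int(p)), perm) for p in positions] == ref

    def test_strand_mirror_symmetry(self, gene_fixture, rng):
        transcripts, truth, model = gene_fixture
        C = 10_000_000
        mirrored = [
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand="-" if t.strand == "+" else "+",
                tx_start=C - t.tx_end,
                tx_end=C - t.tx_start,
                exons=sorted((C - e, C - s) for s, e in t.exons),
                cds_start=C - t.cds_end if t.is_coding else None,
                cds_end=C - t.cds_start if t.is_coding else None,
            )
            for t in transcripts
        ]
        mmodel = GeneModel(mirrored)
        keys = list(truth)
        for idx in rng.choice(len(keys), size=2000, replace=False):
            chrom, pos = keys[idx]
            assert classify_variant(v(chrom, C - pos), mmodel) == truth[(chrom, pos)]

    def test_ground_truth_agreement(self, gene_fixture):
        transcripts, truth, model = gene_fixture
        mismatches = sum(
            classify_variant(v(chrom, pos), model) != cat
            for (chrom, pos), cat in truth.items()
        )
        assert mismatches == 0

    def test_annotate_variants_adds_region_column(self, gene_fixture):
        import pandas as pd

        _, truth, model = gene_fixture
        keys = list(truth)[:50]
        df = pd.DataFrame({"chrom": [k[0] for k in keys], "pos": [k[1] for k in keys]})
        out = annotate_variants(df, model)
        assert list(out["region"]) == [truth[k].value for k in keys]


class TestGeneModelLoading:
    def test_gtf_round_trip(self, tmp_path, gene_fixture):
        transcripts, _, _ = gene_fixture
        path = tmp_path / "genes.gtf"
        write_gtf(transcripts, path)
        model = load_gene_model(path, "gtf")
        assert len(model.transcripts) == len(transcripts)
        by_id = {t.transcript_id: t for t in model.transcripts}
        for t in transcripts:
            u = by_id[t.transcript_id]
            assert (u.tx_start, u.tx_end, u.strand, u.exons) == (
                t.tx_start,
                t.tx_end,
                t.strand,
                t.exons,
            )
            assert (u.cds_start, u.cds_end) == (t.cds_start, t.cds_end)

    def test_gtf_noncoding_has_no_cds(self, tmp_path):
        path = tmp_path / "nc.gtf"
        write_gtf([make_noncoding()], path)
        model = load_gene_model(path, "gtf")
        assert not model.transcripts[0].is_coding

    def test_malformed_gtf_names_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tsrc\ttranscript\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t300\t250\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="line 2"):
            load_gene_model(path, "gtf")

    def test_cds_outside_exons_rejected_with_warning(self, tmp_path, caplog):
        path = tmp_path / "cds.gtf"
        path.write_text(
            'chr1\tsrc\ttranscript\t100\t500\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\tCDS\t150\t450\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with caplog.at_level(logging.WARNING):
            model = load_gene_model(path, "gtf")
        assert len(model.transcripts) == 0
        assert any("rejecting transcript" in r.message for r in caplog.records)

    def test_refgene_dialect(self, tmp_path):
        # 0-based half-open on disk
        path = tmp_path / "genes.txt"
        path.write_text(
            "t1\tchr1\t+\t9999\t12000\t10099\t11900\t3\t"
            "9999,10999,11799,\t10400,11400,12000,\n"
            "t2\tchr1\t-\t49999\t51000\t51000\t51000\t2\t49999,50799,\t50200,51000,\n"
        )
        model = load_gene_model(path, "refgene_tsv")
        t1, t2 = model.transcripts
        assert (t1.tx_start, t1.tx_end) == (10000, 12000)
        assert t1.exons == [(10000, 10400), (11000, 11400), (11800, 12000)]
        assert (t1.cds_start, t1.cds_end) == (10100, 11900)
        assert not t2.is_coding

    def test_refgene_malformed_names_line(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("t1\tchr1\t+\tx\t12000\t0\t0\t1\t0,\t10,\n")
        with pytest.raises(ValueError, match="line 1"):
            load_gene_model(path, "refgene_tsv")


class TestInvariants:
    def test_transcript_validation(self):
        t = make_coding_plus()
        t.exons[1] = (11400, 11000)
        with pytest.raises(ValueError, match="exon start"):
            t.validate()

    def test_variant_validation(self):
        with pytest.raises(ValueError):
            Variant("chr1", 0, "A", "T", 1.0).validate()
        with pytest.raises(ValueError):
            Variant("chr1", 5, "A", "T", -1.0).validate()
        Variant("chr1", 5, "A", "T", 0.0, allele_freq=0.5).validate()
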