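"""linked_io: region extraction, VCF/FASTA/PAF/FASTQ readers and writers."""

from __future__ import annotations

import random

import pysam
import pytest

from cloudindel import linked_io as io
from cloudindel.contig_variants import GenotypedVariant

from conftest import make_bam, make_read


class TestRegion:
    def test_rejects_degenerate_and_invalid(self):
        with pytest.raises(ValueError):
            io.Region("chr1", 5, 5)
        with pytest.raises(ValueError):
            io.Region("chr1", 10, 5)
        with pytest.raises(ValueError):
            io.Region("", 0, 10)
        assert len(io.Region("chr1", 0, 10)) == 10


class TestReadRegionAlignments:
    def test_barcodeless_read_skipped_and_counted(self, tmp_path):
        bam = make_bam(
            tmp_path / "t.bam",
            [
                {"name": "r1", "pos": 100, "barcode": "BC1"},
                {"name": "r2", "pos": 200, "barcode": "BC2"},
                {"name": "r3", "pos": 300},  # no barcode
            ],
        )
        res = io.read_region_alignments(bam, io.Region("chr1", 0, 1000))
        assert len(res) == 2
        assert res.n_no_barcode == 1
        assert {r.barcode for r in res} == {"BC1", "BC2"}

    def test_empty_region_returns_empty(self, tmp_path):
        bam = make_bam(tmp_path / "t.bam", [{"name": "r1", "pos": 100, "barcode": "B"}])
        res = io.read_region_alignments(bam, io.Region("chr1", 500_000, 600_000))
        assert res.reads == []

    def test_mapq_secondary_duplicate_filters(self, tmp_path):
        bam = make_bam(
            tmp_path / "t.bam",
            [
                {"name": "lo", "pos": 100, "barcode": "B", "mapq": 5},
                {"name": "sec", "pos": 110, "barcode": "B", "flag": 0x100},
                {"name": "dup", "pos": 120, "barcode": "B", "flag": 0x400},
                {"name": "ok", "pos": 130, "barcode": "B"},
            ],
        )
        res = io.read_region_alignments(bam, io.Region("chr1", 0, 1000), min_mapq=20)
        assert [r.name for r in res] == ["ok"]
        assert res.n_filtered == 3

    def test_name_dialect_parses_suffix(self, tmp_path):
        bam = make_bam(
            tmp_path / "t.bam",
            [{"name": "x#BCA", "pos": 50}, {"name": "plain", "pos": 60}],
        )
        res = io.read_region_alignments(
            bam, io.Region("chr1", 0, 1000), barcode_dialect="name"
        )
        assert [r.barcode for r in res] == ["BCA"]
        assert res.n_no_barcode == 1

    def test_missing_index_is_explicit_error(self, tmp_path):
        bam = make_bam(tmp_path / "t.bam", [{"name": "r", "pos": 5, "barcode": "B"}])
        (tmp_path / "t.bam.bai").unlink()
        with pytest.raises(FileNotFoundError):
            io.read_region_alignments(bam, io.Region("chr1", 0, 100))


def _write_vcf(path, records, chrom="chr1", length=10_000_000):
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(chrom, length=length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">')
    header.add_sample("s")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for pos, ref, alt, gt in records:
            rec = vf.new_record(contig=chrom, start=pos, alleles=(ref, alt))
            rec.samples["s"]["GT"] = gt
            vf.write(rec)
    return path


class TestReadHetSnps:
    def test_filters_to_het_biallelic_snps(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "v.vcf",
            [
                (100, "A", "G", (0, 1)),  # het SNP: kept
                (200, "C", "T", (1, 1)),  # hom-alt SNP: dropped
                (300, "GACT", "G", (0, 1)),  # het 3bp deletion: dropped
            ],
        )
        snps = io.read_het_snps(vcf, io.Region("chr1", 0, 1000))
        assert [(s.pos, s.ref_allele, s.alt_allele) for s in snps] == [(100, "A", "G")]

    def test_region_scoping_and_empty(self, tmp_path):
        vcf = _write_vcf(tmp_path / "v.vcf", [(100, "A", "G", (0, 1))])
        assert io.read_het_snps(vcf, io.Region("chr1", 500, 900)) == []

    def test_simulated_truth_vcf_roundtrip(self, het_del_sim):
        truth = het_del_sim["truth"]
        snps = io.read_het_snps(het_del_sim["paths"]["snps"], truth.region)
        assert len(snps) == len(truth.het_snps)
        assert [(s.pos, s.ref_allele, s.alt_allele) for s in snps] == [
            (s.pos, s.ref_allele, s.alt_allele) for s in truth.het_snps
        ]


class TestReferenceWindow:
    def test_window_roundtrip_and_bounds(self, tmp_path):
        random.seed(0)
        seq = "".join(random.choice("ACGT") for _ in range(1000))
        fa = tmp_path / "r.fa"
        fa.write_text(f">chrZ\n{seq}\n")
        pysam.faidx(str(fa))
        assert io.read_reference_window(fa, io.Region("chrZ", 100, 200)) == seq[100:200]
        assert io.read_reference_window(fa, io.Region("chrZ", 0, 1000)) == seq
        with pytest.raises(ValueError, match="1000"):
            io.read_reference_window(fa, io.Region("chrZ", 900, 1100))
        with pytest.raises(KeyError):
            io.read_reference_window(fa, io.Region("chrQ", 0, 10))


class TestPafCs:
    def test_deletion_tag_grammar(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(
            "ctg\t2000\t0\t2000\t+\tchr1\t3000\t0\t2004\t2000\t2004\t60\tcs:Z::1000-acgt:1000\n"
        )
        (aln,) = io.parse_contig_alignments(p)
        assert [(o.op, o.length, o.seq) for o in aln.ops] == [
            ("match", 1000, ""),
            ("deletion", 4, "ACGT"),
            ("match", 1000, ""),
        ]
        assert aln.target_end - aln.target_start == 2004

    def test_insertion_tag_grammar(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(
            "ctg\t102\t0\t102\t+\tchr1\t200\t0\t100\t100\t102\t60\tcs:Z::50+gg:50\n"
        )
        (aln,) = io.parse_contig_alignments(p)
        assert [(o.op, o.length, o.seq) for o in aln.ops] == [
            ("match", 50, ""),
            ("insertion", 2, "GG"),
            ("match", 50, ""),
        ]
        assert aln.query_span == 102

    def test_missing_cs_tag_is_error(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("ctg\t100\t0\t100\t+\tchr1\t200\t0\t100\t100\t100\t60\n")
        with pytest.raises(ValueError, match="cs"):
            io.parse_contig_alignments(p)

    def test_write_parse_roundtrip(self, tmp_path):
        random.seed(1)
        window = "".join(random.choice("ACGT") for _ in range(500))
        ops = [
            io.AlnOp("match", 100),
            io.AlnOp("mismatch", 1, "A" if window[100] != "A" else "C"),
            io.AlnOp("match", 99),
            io.AlnOp("deletion", 20, window[200:220]),
            io.AlnOp("match", 80),
            io.AlnOp("insertion", 7, "GATTACA"),
            io.AlnOp("match", 100),
        ]
        aln = io.ContigAlignment("c1", 387, "+", "chr1", 0, 400, 60, ops)
        p = tmp_path / "rt.paf"
        io.write_paf([aln], p, window, 0)
        (back,) = io.parse_contig_alignments(p)
        assert back.ops == aln.ops
        assert (back.target_start, back.target_end, back.strand) == (0, 400, "+")


def _gv(pos, type_, ref, alt, gt, block=1, chrom="chr1"):
    size = 1 if type_ == "SNP" else abs(len(ref) - len(alt))
    return GenotypedVariant(
        chrom=chrom, pos=pos, type=type_, ref_seq=ref, alt_seq=alt,
        size=size, genotype=gt, block_id=block, supporting_contigs=["c1"],
    )


class TestPhasedVcf:
    def test_het_deletion_record_fields(self, tmp_path):
        v = _gv(499, "DEL", "GAAAA", "G", "1|0", block=7)
        path = tmp_path / "p.vcf"
        io.write_phased_vcf([v], "s1", path, {"chr1": 10_000})
        text = path.read_text()
        line = [l for l in text.splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[1] == "500"  # 1-based POS
        assert fields[3] == "GAAAA" and fields[4] == "G"
        assert "1|0" in fields[9] and fields[9].endswith("7")

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "e.vcf"
        io.write_phased_vcf([], "s1", path, {"chr1": 100})
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_unsorted_input_rejected(self, tmp_path):
        vs = [_gv(500, "SNP", "A", "G", "1|0"), _gv(100, "SNP", "C", "T", "0|1")]
        with pytest.raises(ValueError, match="sorted"):
            io.write_phased_vcf(vs, "s1", tmp_path / "u.vcf", {"chr1": 1000})

    def test_random_roundtrip_equality(self, tmp_path):
        rnd = random.Random(7)
        vs = []
        pos = 10
        for i in range(20):
            pos += rnd.randint(5, 500)
            kind = rnd.choice(["SNP", "INS", "DEL"])
            if kind == "SNP":
                vs.append(_gv(pos, "SNP", "A", "G", rnd.choice(["1|0", "0|1", "1|1"])))
            elif kind == "INS":
                ins = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 120)))
                vs.append(_gv(pos, "INS", "T", "T" + ins, rnd.choice(["1|0", "1|1"])))
            else:
                dele = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 120)))
                vs.append(_gv(pos, "DEL", "C" + dele, "C", rnd.choice(["0|1", "1|1"])))
        path = tmp_path / "rt.vcf"
        io.write_phased_vcf(vs, "s1", path, {"chr1": 10_000_000})
        back = io.read_phased_vcf(path)
        assert [
            (v.pos, v.type, v.ref_seq, v.alt_seq, v.genotype, v.block_id) for v in back
        ] == [(v.pos, v.type, v.ref_seq, v.alt_seq, v.genotype, v.block_id) for v in vs]


class TestWriteReadPairs:
    def test_pairs_and_singletons(self, tmp_path):
        reads = [
            make_read("a", "B1", 100, is_read1=True),
            make_read("a", "B1", 300, is_read1=False),
            make_read("b", "B2", 200, is_read1=True),
            make_read("b", "B2", 400, is_read1=False),
            make_read("c", "B3", 500, is_read1=True),  # no mate
        ]
        r1, r2, s = tmp_path / "R1.fq", tmp_path / "R2.fq", tmp_path / "S.fq"
        n_pairs, n_single = io.write_read_pairs(reads, r1, r2, s)
        assert (n_pairs, n_single) == (2, 1)
        assert r1.read_text().count("@") == 2
        assert r2.read_text().count("@") == 2
        assert s.read_text().count("@") == 1
        assert "#B1" in r1.read_text()  # barcode preserved in name

    def test_duplicate_mate_is_error(self, tmp_path):
        reads = [make_read("a", "B", 1), make_read("a", "B", 2)]
        with pytest.raises(ValueError, match="duplicate"):
            io.write_read_pairs(reads, tmp_path / "1.fq", tmp_path / "2.fq")
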