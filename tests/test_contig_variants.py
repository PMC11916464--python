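"""contig_variants: alignment, extraction, chaining, genotyping, refinement."""

from __future__ import annotations

import random

import pytest

from cloudindel import contig_variants as cv
from cloudindel.assembly import Contig
from cloudindel.linked_io import AlnOp, ContigAlignment, HetSNP, Region

REGION = Region("chr1", 0, 1_000_000)


def random_seq(n: int, seed: int) -> str:
    rnd = random.Random(seed)
    return "".join(rnd.choice("ACGT") for _ in range(n))


def ctg(seq: str, name="c1", hap=1) -> Contig:
    return Contig(name, hap, 1, seq)


def raw(pos, type_, size, seed=0, chrom="chr1", contig="c1", contig_len=10_000, hap=1):
    body = random_seq(max(size, 1), seed)
    if type_ == "DEL":
        ref_seq, alt_seq = "A" + body[:size], "A"
    elif type_ == "INS":
        ref_seq, alt_seq = "A", "A" + body[:size]
    else:
        ref_seq, alt_seq = "A", "G"
    return cv.RawVariant(chrom, pos, type_, ref_seq, alt_seq, size, contig, hap, 1, contig_len)


class TestAlignContigs:
    def test_exact_slice_is_pure_match(self):
        ref = random_seq(20_000, 1)
        (aln,) = cv.align_contigs([ctg(ref[5_000:15_000])], ref, REGION)
        assert aln.ops == [AlnOp("match", 10_000)]
        assert (aln.target_start, aln.target_end) == (5_000, 15_000)

    def test_implanted_deletion_recovered_at_offset(self):
        ref = random_seq(20_000, 2)
        contig = ref[1_000:5_000] + ref[5_100:9_000]  # 100bp removed at 4000
        (aln,) = cv.align_contigs([ctg(contig)], ref, REGION)
        dels = [(i, o) for i, o in enumerate(aln.ops) if o.op == "deletion"]
        assert len(dels) == 1 and dels[0][1].length == 100
        vars_ = cv.extract_variants(aln, ref, 0, 1, 1, min_aln_len=1_000)
        (v,) = [v for v in vars_ if v.type == "DEL"]
        assert v.size == 100
        # left-alignment can shift the anchor a few bases within context
        assert abs(v.pos - 4_999) <= 5

    def test_reverse_complement_contig_aligns_minus(self):
        from cloudindel.assembly import reverse_complement

        ref = random_seq(10_000, 3)
        (aln,) = cv.align_contigs([ctg(reverse_complement(ref[2_000:8_000]))], ref, REGION)
        assert aln.strand == "-"
        assert aln.ops == [AlnOp("match", 6_000)]

    def test_unalignable_contig_dropped_with_warning(self):
        ref = random_seq(5_000, 4)
        alien = random_seq(3_000, 999)
        with pytest.warns(UserWarning, match="did not align"):
            out = cv.align_contigs([ctg(alien)], ref, REGION)
        assert out == []

    @pytest.mark.parametrize("seed", range(20))
    def test_builtin_matches_minimap2_on_single_indel_contigs(self, seed):
        """Cross-oracle: same extracted indels from both aligner modes."""
        rnd = random.Random(seed)
        ref = random_seq(60_000, 100 + seed)
        size = rnd.randrange(60, 3_000)
        offset = rnd.randrange(20_000, 40_000)
        if seed % 2:
            contig = ref[5_000 : offset] + ref[offset + size : 55_000]  # DEL
        else:
            ins = random_seq(size, 5000 + seed)
            contig = ref[5_000 : offset] + ins + ref[offset : 55_000]  # INS
        region = Region("chr1", 0, 60_000)
        got = {}
        for mode in ("builtin", "external"):
            (aln,) = cv.align_contigs([ctg(contig)], ref, region, mode=mode)
            vs = cv.extract_variants(aln, ref, 0, 1, 1, min_aln_len=10_000)
            got[mode] = [(v.type, v.pos, v.size, v.ref_seq, v.alt_seq) for v in vs]
        assert got["builtin"] == got["external"]
        assert len(got["builtin"]) == 1


class TestExtractVariants:
    def _aln(self, ops, start=0, mapq=60, contig_len=50_000):
        tspan = sum(o.length for o in ops if o.op in ("match", "mismatch", "deletion"))
        return ContigAlignment("c1", contig_len, "+", "chr1", start, start + tspan, mapq, ops)

    def test_deletion_anchor_position(self):
        ref = random_seq(2_100, 5)
        ops = [AlnOp("match", 1000), AlnOp("deletion", 100, ref[1000:1100]), AlnOp("match", 1000)]
        vars_ = cv.extract_variants(self._aln(ops), ref, 0, 1, 1, min_aln_len=100)
        (v,) = vars_
        assert (v.type, v.size) == ("DEL", 100)
        assert v.pos <= 999  # anchored at the base before, then left-aligned
        assert len(v.ref_seq) == 101 and len(v.alt_seq) == 1

    def test_pure_match_yields_nothing(self):
        ref = random_seq(50, 6)
        assert cv.extract_variants(
            self._aln([AlnOp("match", 50)]), ref, 0, 1, 1, min_aln_len=10
        ) == []

    def test_mapq_and_length_gates(self):
        ref = random_seq(600, 7)
        ops = [AlnOp("match", 200), AlnOp("deletion", 100, ref[200:300]), AlnOp("match", 300)]
        assert cv.extract_variants(self._aln(ops, mapq=3), ref, 0, 1, 1, min_aln_len=100) == []
        assert cv.extract_variants(self._aln(ops), ref, 0, 1, 1, min_aln_len=10_000) == []

    def test_left_alignment_in_homopolymer(self):
        # deleting any 3 As from a homopolymer run normalizes to the run start
        ref = "GGGG" + "A" * 10 + "CCCC"
        ops = [AlnOp("match", 9), AlnOp("deletion", 3, "AAA"), AlnOp("match", 6)]
        (v,) = cv.extract_variants(self._aln(ops), ref, 0, 1, 1, min_aln_len=1)
        assert v.pos == 3 and v.ref_seq == "GAAA" and v.alt_seq == "G"

    def test_snp_extraction_with_haplotype_metadata(self):
        ref = random_seq(100, 8)
        alt = "A" if ref[50] != "A" else "G"
        ops = [AlnOp("match", 50), AlnOp("mismatch", 1, alt), AlnOp("match", 49)]
        (v,) = cv.extract_variants(self._aln(ops), ref, 0, haplotype=2, block_id=9, min_aln_len=1)
        assert (v.type, v.pos, v.ref_seq, v.alt_seq) == ("SNP", 50, ref[50], alt)
        assert (v.haplotype, v.block_id) == (2, 9)

    def test_anchored_shape_validation(self):
        with pytest.raises(ValueError):
            cv.RawVariant("chr1", 10, "DEL", "AT", "AT", 5, "c", 1, 1)


def chain_oracle(variants, cfg):
    """O(n^2) transitive closure with the same pair predicate."""
    n = len(variants)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and cv._chain_match(variants[i], variants[j], cfg):
                adj[i][j] = True
    comp = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if adj[i][j] and comp[j] != comp[i]:
                    tgt = min(comp[i], comp[j])
                    src = max(comp[i], comp[j])
                    for x in range(n):
                        if comp[x] == src:
                            comp[x] = tgt
                    changed = True
    groups: dict[int, list] = {}
    for i, v in enumerate(variants):
        groups.setdefault(comp[i], []).append(v)
    return groups


def random_variants(n, seed, span=20_000):
    rnd = random.Random(seed)
    out = []
    pos = 100
    for i in range(n):
        pos += rnd.randrange(0, span // n)
        type_ = rnd.choice(["DEL", "INS", "SNP"])
        size = 1 if type_ == "SNP" else rnd.randrange(50, 500)
        out.append(raw(pos, type_, size, seed=seed * 1000 + i,
                       contig=f"c{i}", contig_len=rnd.randrange(1_000, 50_000)))
    return sorted(out, key=lambda v: v.pos)


class TestChainVariants:
    def test_identical_duplicates_merge(self):
        a = raw(5_000, "DEL", 100, seed=1, contig="cA", contig_len=30_000)
        b = raw(5_000, "DEL", 100, seed=1, contig="cB", contig_len=20_000)
        out = cv.chain_variants([a, b])
        assert len(out) == 1 and out[0].contig_name == "cA"  # longest contig wins

    def test_distance_gate_blocks_merge(self):
        a = raw(5_000, "DEL", 100, seed=1)
        b = raw(5_600, "DEL", 100, seed=1)
        assert len(cv.chain_variants([a, b])) == 2  # 600bp > 500bp default

    def test_unsorted_input_rejected(self):
        a, b = raw(5_000, "DEL", 100), raw(1_000, "DEL", 100)
        with pytest.raises(ValueError, match="sorted"):
            cv.chain_variants([a, b])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        vs = random_variants(50, seed)
        cfg = cv.ChainConfig()
        out = cv.chain_variants(vs, cfg)
        groups = chain_oracle(vs, cfg)
        assert len(out) == len(groups)
        # representative of every oracle group appears in the output
        reps = {id(cv._representative(g)) for g in groups.values()}
        assert {id(v) for v in out} == reps

    def test_idempotent(self):
        for seed in range(5):
            vs = random_variants(50, seed)
            once = cv.chain_variants(vs)
            assert cv.chain_variants(once) == once


class TestMergeAndGenotype:
    def test_hap1_only_deletion_is_het(self):
        v = raw(5_000, "DEL", 2_070, seed=1, hap=1)
        (g,) = cv.merge_and_genotype([v], [])
        assert g.genotype == "1|0" and g.size == 2_070

    def test_shared_insertion_is_hom(self):
        a = raw(7_000, "INS", 70, seed=3, hap=1, contig="h1", contig_len=48_000)
        b = raw(7_000, "INS", 70, seed=3, hap=2, contig="h2", contig_len=41_000)
        (g,) = cv.merge_and_genotype([a], [b])
        assert g.genotype == "1|1"
        assert g.supporting_contigs == ["h1", "h2"]
        assert g.contig_len == 48_000

    def test_hap2_only_is_0_pipe_1_and_empty_ok(self):
        v = raw(5_000, "DEL", 100, hap=2)
        (g,) = cv.merge_and_genotype([], [v])
        assert g.genotype == "0|1"
        assert cv.merge_and_genotype([], []) == []

    def test_conservation_counts(self):
        rnd = random.Random(0)
        set1 = random_variants(20, 10)
        set2 = random_variants(20, 11)
        out = cv.merge_and_genotype(set1, set2)
        assert len(out) <= len(set1) + len(set2)
        n11 = sum(1 for v in out if v.genotype == "1|1")
        n10 = sum(1 for v in out if v.genotype == "1|0")
        n01 = sum(1 for v in out if v.genotype == "0|1")
        assert n11 + n10 == len(set1)
        assert n11 + n01 == len(set2)

    def test_cross_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chromosome"):
            cv.merge_and_genotype([raw(1, "DEL", 50)], [raw(1, "DEL", 50, chrom="chr2")])


class TestRefineAndClassify:
    def test_refinement_flags_contig_only_snps(self):
        known = [HetSNP("chr1", 100, "A", "G")]
        ok = cv.GenotypedVariant("chr1", 100, "SNP", "A", "G", 1, "1|0", 1)
        novel = cv.GenotypedVariant("chr1", 200, "SNP", "C", "T", 1, "0|1", 1)
        indel = cv.GenotypedVariant("chr1", 300, "DEL", "GAA", "G", 2, "1|1", 1)
        out = cv.refine_snps([ok, novel, indel], known)
        assert out[0].filter is None and out[0].genotype == "1|0"
        assert out[1].filter == "CONTIG_ONLY"
        assert out[2].filter is None

    def test_refinement_identity_on_concordant_set(self):
        known = [HetSNP("chr1", p, "A", "G") for p in (10, 20, 30)]
        vs = [cv.GenotypedVariant("chr1", p, "SNP", "A", "G", 1, "1|0", 1) for p in (10, 20, 30)]
        assert cv.refine_snps(vs, known) == vs

    @pytest.mark.parametrize(
        "type_,size,expected",
        [
            ("SNP", 1, "SNP"),
            ("DEL", 49, "small_indel"),
            ("DEL", 50, "SV_50_1k"),
            ("INS", 70, "SV_50_1k"),
            ("DEL", 2_070, "SV_1k_10k"),
            ("INS", 999, "SV_50_1k"),
            ("DEL", 10_000, "SV_gt10k"),
        ],
    )
    def test_size_bins(self, type_, size, expected):
        if type_ == "SNP":
            v = cv.GenotypedVariant("chr1", 1, "SNP", "A", "G", 1, "1|0", 1)
        elif type_ == "DEL":
            v = cv.GenotypedVariant("chr1", 1, "DEL", "A" + "C" * size, "A", size, "1|0", 1)
        else:
            v = cv.GenotypedVariant("chr1", 1, "INS", "A", "A" + "C" * size, size, "1|0", 1)
        assert cv.classify_size(v) == expected


class TestOneEditRecovery:
    @pytest.mark.parametrize("size,kind", [(1, "SNP"), (5, "DEL"), (80, "INS"),
                                           (700, "DEL"), (2_070, "DEL"), (9_000, "INS")])
    def test_single_edit_roundtrip(self, size, kind):
        """A contig that is the reference with one edit yields exactly
        that edit back (size exact; position up to left-alignment)."""
        ref = random_seq(40_000, size)
        offset = 20_000
        if kind == "SNP":
            alt = "A" if ref[offset] != "A" else "G"
            contig = ref[2_000:offset] + alt + ref[offset + 1 : 38_000]
        elif kind == "DEL":
            contig = ref[2_000:offset] + ref[offset + size : 38_000]
        else:
            contig = ref[2_000:offset] + random_seq(size, size + 1) + ref[offset:38_000]
        region = Region("chr1", 0, 40_000)
        (aln,) = cv.align_contigs([ctg(contig)], ref, region)
        vs = cv.extract_variants(aln, ref, 0, 1, 1, min_aln_len=10_000)
        assert len(vs) == 1
        (v,) = vs
        assert (v.type, v.size) == (kind, size)
        if kind == "SNP":
            assert v.pos == offset
        else:
            expect_pos, _ = cv._left_align(
                offset - 1,
                ref[offset : offset + size] if kind == "DEL" else v.alt_seq[1:],
                ref,
                0,
            )
            # junction bases that match by chance admit equivalent
            # placements a few bases apart
            assert abs(v.pos - expect_pos) <= 5
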