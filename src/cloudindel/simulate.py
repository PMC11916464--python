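"""Synthetic diploid regions and linked-read libraries with ground truth.

The generator emulates what a linked-read library looks like inside one
target window: a diploid pair of sequences differing by heterozygous SNPs
and implanted SVs; long DNA fragments drawn at physical coverage C_F with
exponentially distributed lengths of mean mu_FL; per-fragment short-read
pairs at coverage C_R; and barcodes drawn from a finite pool so that
distant fragments can collide on a barcode, which is exactly what the
deconvolution step has to untangle.

Reads are emitted at their *true* reference placement (the aligner is not
in the loop): CIGARs are derived from the known haplotype-to-reference
coordinate map, reads spanning a deletion get a D operation, reads
overhanging an insertion get clipped, and read pairs falling entirely
inside novel inserted sequence are absent from the alignment file by
default — reproducing the main failure mode of large-insertion calling,
where unmapped novel-sequence reads never reach the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pysam

from .contig_variants import GenotypedVariant
from .linked_io import HetSNP, Region, write_phased_vcf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class LibraryProfile:
    """Linked-read library statistics.

    C is the raw short-read coverage, C_F the physical coverage of the
    genome by long fragments, C_R the short-read coverage within one
    fragment, and mu_FL the mean (unweighted) fragment length. The two
    presets carry the published statistics of an stLFR and a 10x HG002
    library; note C ~= C_F * C_R by construction.
    """

    c: float
    c_f: float
    c_r: float
    mu_fl: float
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    barcode_pool: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.c, self.c_f, self.c_r) <= 0:
            raise ValueError("all coverages must be positive")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        import logging

        if abs(self.c_f * self.c_r - self.c) / self.c > 0.25:
            logging.getLogger(__name__).warning(
                "C=%.1f is far from C_F*C_R=%.1f", self.c, self.c_f * self.c_r
            )

    @classmethod
    def preset(cls, name: Literal["tenx", "stlfr"], seed: int = 0) -> "LibraryProfile":
        if name == "tenx":
            return cls(c=93, c_f=760, c_r=0.12, mu_fl=44_800, read_len=150, seed=seed)
        if name == "stlfr":
            return cls(c=48, c_f=238, c_r=0.20, mu_fl=30_100, read_len=100, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass(frozen=True)
class SVSpec:
    """An SV to implant: type DEL/INS, 0-based ref offset, size, and
    genotype 'het' or 'hom'. A deletion removes ref[offset, offset+size);
    an insertion adds novel sequence between offset-1 and offset."""

    type: Literal["DEL", "INS"]
    offset: int
    size: int
    genotype: Literal["het", "hom"]


@dataclass
class SimMolecule:
    """Truth log entry for one simulated long fragment."""

    molecule_id: int
    barcode: str
    haplotype: int  # 1 or 2
    hap_start: int
    hap_end: int
    n_pairs: int = 0


# haplotype-to-reference map block: hap interval plus ref start (None for
# novel inserted sequence, with the ref anchor recorded instead)
@dataclass(frozen=True)
class _MapBlock:
    hap_start: int
    hap_end: int
    ref_start: Optional[int]
    ref_anchor: int


@dataclass
class TruthSet:
    chrom: str
    ref_seq: str
    hap_seqs: tuple[str, str]
    hap_maps: tuple[list[_MapBlock], list[_MapBlock]]
    het_snps: list[HetSNP]
    snp_alt_hap: dict[int, int]  # snp pos -> haplotype (1/2) carrying ALT
    sv_truth: list[GenotypedVariant]
    molecules: list[SimMolecule] = field(default_factory=list)
    read_to_molecule: dict[str, int] = field(default_factory=dict)
    n_unmapped_reads: int = 0

    @property
    def region(self) -> Region:
        return Region(self.chrom, 0, len(self.ref_seq))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_diploid(
    region_len: int,
    snp_rate: float,
    svs: list[SVSpec] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> TruthSet:
    """Build a random reference window and a diploid pair derived from it.

    Heterozygous SNPs are dropped at ``snp_rate`` per bp (outside SV
    spans), the alternate allele landing on haplotype 1 or 2 by fair
    coin. SVs are applied per genotype; a het SV's carrier haplotype is
    also drawn by coin. Overlapping SVs are rejected.
    """
    svs = sorted(svs or [], key=lambda s: s.offset)
    if snp_rate < 0:
        raise ValueError("snp_rate must be >= 0")
    rng = np.random.default_rng(seed)
    ref = _random_seq(rng, region_len)

    spans = []
    for sv in svs:
        if sv.offset < 1 or sv.offset + (sv.size if sv.type == "DEL" else 0) >= region_len:
            raise ValueError(f"SV {sv} outside usable window")
        spans.append((sv.offset - 1, sv.offset + (sv.size if sv.type == "DEL" else 1)))
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("implanted SVs overlap")

    # het SNPs outside SV footprints
    hits = np.flatnonzero(rng.random(region_len) < snp_rate)
    snps: list[HetSNP] = []
    snp_alt_hap: dict[int, int] = {}
    for pos in hits.tolist():
        if any(s <= pos < e for s, e in spans):
            continue
        refb = ref[pos]
        alt = "ACGT".replace(refb, "")[rng.integers(0, 3)]
        snps.append(HetSNP(chrom, pos, refb, alt))
        snp_alt_hap[pos] = int(rng.integers(1, 3))

    # carrier haplotypes and inserted sequences, drawn once per SV
    sv_rows = []
    for sv in svs:
        carrier = 0 if sv.genotype == "hom" else int(rng.integers(1, 3))
        ins_seq = _random_seq(rng, sv.size) if sv.type == "INS" else ""
        sv_rows.append((sv, carrier, ins_seq))

    hap_seqs = []
    hap_maps = []
    for hap in (1, 2):
        base = list(ref)
        for s in snps:
            if snp_alt_hap[s.pos] == hap:
                base[s.pos] = s.alt_allele
        hap_ref = "".join(base)

        pieces: list[str] = []
        blocks: list[_MapBlock] = []
        cur_ref = 0
        cur_hap = 0

        def emit_ref(upto: int) -> None:
            nonlocal cur_ref, cur_hap
            if upto > cur_ref:
                ln = upto - cur_ref
                pieces.append(hap_ref[cur_ref:upto])
                blocks.append(_MapBlock(cur_hap, cur_hap + ln, cur_ref, cur_ref))
                cur_hap += ln
                cur_ref = upto

        for sv, carrier, ins_seq in sv_rows:
            applies = carrier in (0, hap)
            if not applies:
                continue
            if sv.type == "DEL":
                emit_ref(sv.offset)
                cur_ref += sv.size
            else:
                emit_ref(sv.offset)
                pieces.append(ins_seq)
                blocks.append(
                    _MapBlock(cur_hap, cur_hap + sv.size, None, sv.offset)
                )
                cur_hap += sv.size
        emit_ref(region_len)
        hap_seqs.append("".join(pieces))
        hap_maps.append(blocks)

    sv_truth = []
    for sv, carrier, ins_seq in sv_rows:
        anchor = sv.offset - 1
        if sv.type == "DEL":
            ref_seq = ref[anchor : anchor + sv.size + 1]
            alt_seq = ref[anchor]
        else:
            ref_seq = ref[anchor]
            alt_seq = ref[anchor] + ins_seq
        gt = "1|1" if carrier == 0 else ("1|0" if carrier == 1 else "0|1")
        sv_truth.append(
            GenotypedVariant(
                chrom=chrom,
                pos=anchor,
                type=sv.type,
                ref_seq=ref_seq,
                alt_seq=alt_seq,
                size=sv.size,
                genotype=gt,
                block_id=0,
            )
        )

    return TruthSet(
        chrom=chrom,
        ref_seq=ref,
        hap_seqs=(hap_seqs[0], hap_seqs[1]),
        hap_maps=(hap_maps[0], hap_maps[1]),
        het_snps=snps,
        snp_alt_hap=snp_alt_hap,
        sv_truth=sv_truth,
    )


def simulate_molecules(
    truth: TruthSet, profile: LibraryProfile, rng: np.random.Generator | None = None
) -> list[SimMolecule]:
    """Draw long fragments per haplotype to physical coverage C_F/2 each.

    Lengths are exponential with mean mu_FL, truncated to
    [1 kb, 5*mu_FL]; starts are uniform; barcodes are drawn uniformly
    from the pool, so distant fragments may share one.
    """
    rng = rng or np.random.default_rng(profile.seed)
    molecules: list[SimMolecule] = []
    mol_id = 0
    for hap in (1, 2):
        hap_len = len(truth.hap_seqs[hap - 1])
        target = profile.c_f / 2.0 * hap_len
        total = 0.0
        while total < target:
            ln = float(np.clip(rng.exponential(profile.mu_fl), 1_000, 5 * profile.mu_fl))
            ln = int(round(ln))
            start = int(rng.integers(0, max(1, hap_len - 1)))
            end = min(start + ln, hap_len)
            total += ln
            if end - start < 1_000:
                continue  # fragment fell off the window edge
            bc = f"BC{int(rng.integers(0, profile.barcode_pool)):07d}"
            mol_id += 1
            molecules.append(SimMolecule(mol_id, bc, hap, start, end))
    truth.molecules = molecules
    return molecules


def _cigar_and_pos(
    blocks: list[_MapBlock], s: int, e: int
) -> Optional[tuple[int, list[tuple[int, int]]]]:
    """Reference placement of haplotype interval [s, e).

    Returns (ref_pos, pysam cigartuples) or None when the interval touches
    no reference-mapped block (read lies entirely in novel sequence).
    Leading/trailing insertion overlap becomes soft clip.
    """
    ops: list[tuple[int, int]] = []
    pos: Optional[int] = None
    last_ref_end: Optional[int] = None
    for b in blocks:
        if b.hap_end <= s or b.hap_start >= e:
            continue
        lo, hi = max(s, b.hap_start), min(e, b.hap_end)
        if b.ref_start is None:
            ops.append((1, hi - lo))  # I (turned into S at the ends later)
            continue
        rs = b.ref_start + (lo - b.hap_start)
        if pos is None:
            pos = rs
        elif last_ref_end is not None and rs > last_ref_end:
            ops.append((2, rs - last_ref_end))  # D spanning a deletion
        ops.append((0, hi - lo))  # M
        last_ref_end = rs + (hi - lo)
    if pos is None or not ops:
        return None
    if ops[0][0] == 1:
        ops[0] = (4, ops[0][1])  # leading S
    if ops[-1][0] == 1:
        ops[-1] = (4, ops[-1][1])  # trailing S
    # drop leading/trailing D (cannot start/end a placement)
    while ops and ops[0][0] == 2:
        pos += ops[0][1]
        ops.pop(0)
    while ops and ops[-1][0] == 2:
        ops.pop()
    merged: list[tuple[int, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return pos, merged


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit.tolist():
        cur = chr(arr[i])
        arr[i] = ord("ACGT".replace(cur, "")[rng.integers(0, 3)])
    return arr.tobytes().decode()


def simulate_linked_reads(
    molecules: list[SimMolecule],
    truth: TruthSet,
    profile: LibraryProfile,
    outdir: str | Path,
    barcode_dialect: Literal["bx", "name"] = "bx",
    retain_insertion_reads: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Emit paired reads per fragment and write BAM, FASTQ and truth logs.

    Pair count per fragment is Poisson with mean C_R*len/(2*read_len);
    inserts are Normal(insert_mean, insert_sd); base errors are iid. Reads
    are placed at truth coordinates. Pairs entirely inside novel inserted
    sequence are left out of the BAM (they would be unmapped) unless
    ``retain_insertion_reads`` anchors them, soft-clipped, at the
    insertion point.
    """
    rng = rng or np.random.default_rng(profile.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = profile.read_len

    records = []  # (pos, name, barcode, flag-ish fields...)
    fastq1, fastq2 = [], []
    truth.read_to_molecule = {}
    truth.n_unmapped_reads = 0
    ridx = 0
    for mol in molecules:
        hap_seq = truth.hap_seqs[mol.haplotype - 1]
        blocks = truth.hap_maps[mol.haplotype - 1]
        mlen = mol.hap_end - mol.hap_start
        lam = profile.c_r * mlen / (2.0 * rl)
        n_pairs = int(rng.poisson(lam))
        mol.n_pairs = n_pairs
        for _ in range(n_pairs):
            insert = int(np.clip(rng.normal(profile.insert_mean, profile.insert_sd), rl, mlen))
            start = int(rng.integers(mol.hap_start, max(mol.hap_start + 1, mol.hap_end - insert)))
            end = min(start + insert, mol.hap_end)
            if end - start < rl:
                continue
            ridx += 1
            base = f"sim{ridx:07d}"
            name = f"{base}#{mol.barcode}" if barcode_dialect == "name" else base
            s1, e1 = start, start + rl
            s2, e2 = end - rl, end
            seq1 = _apply_errors(rng, hap_seq[s1:e1], profile.error_rate)
            seq2 = _apply_errors(rng, hap_seq[s2:e2], profile.error_rate)
            truth.read_to_molecule[base] = mol.molecule_id
            fastq1.append((name, seq1))
            fastq2.append((name, _revcomp(seq2)))
            place1 = _cigar_and_pos(blocks, s1, e1)
            place2 = _cigar_and_pos(blocks, s2, e2)
            for mate, (hs, he), place, seq in (
                (1, (s1, e1), place1, seq1),
                (2, (s2, e2), place2, seq2),
            ):
                if place is None:
                    if retain_insertion_reads:
                        anchor = _insertion_anchor(blocks, hs)
                        place = (anchor, [(0, 1), (4, rl - 1)])
                    else:
                        truth.n_unmapped_reads += 1
                        continue
                pos, cig = place
                records.append((pos, name, mol.barcode, mate, seq, cig, mate == 2))
    records.sort(key=lambda r: (r[0], r[1], r[3]))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": truth.chrom, "LN": len(truth.ref_seq)}],
    }
    bam_path = outdir / "reads.bam"
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for pos, name, barcode, mate, seq, cig, is_rev in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            # SAM stores reverse-strand reads in reference orientation,
            # which is how the sequence was simulated
            a.query_sequence = seq
            a.flag = (0x1 | 0x2) | (0x40 if mate == 1 else 0x80) | (0x10 if is_rev else 0x20)
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(op, ln) for op, ln in cig] if not is_rev else _rev_cigar(cig)
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            if barcode_dialect == "bx":
                a.set_tag("BX", barcode, "Z")
            bam.write(a)
    pysam.index(str(bam_path))

    fq1, fq2 = outdir / "reads_R1.fastq", outdir / "reads_R2.fastq"
    for path, recs in ((fq1, fastq1), (fq2, fastq2)):
        with open(path, "w") as fh:
            for name, seq in recs:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    mol_tsv = outdir / "molecules.tsv"
    with open(mol_tsv, "w") as fh:
        fh.write("molecule_id\tbarcode\thaplotype\thap_start\thap_end\tn_pairs\n")
        for m in molecules:
            fh.write(
                f"{m.molecule_id}\t{m.barcode}\t{m.haplotype}\t"
                f"{m.hap_start}\t{m.hap_end}\t{m.n_pairs}\n"
            )
    read_tsv = outdir / "reads.tsv"
    with open(read_tsv, "w") as fh:
        fh.write("read\tmolecule_id\n")
        for name in sorted(truth.read_to_molecule):
            fh.write(f"{name}\t{truth.read_to_molecule[name]}\n")

    return {"bam": bam_path, "r1": fq1, "r2": fq2, "molecules": mol_tsv, "reads": read_tsv}


def _rev_cigar(cig: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # the reverse-strand mate was simulated on the forward haplotype and
    # then reverse-complemented; its stored sequence is the reverse strand
    # but the placement CIGAR stays in reference orientation
    return [(op, ln) for op, ln in cig]


def _insertion_anchor(blocks: list[_MapBlock], hap_pos: int) -> int:
    for b in blocks:
        if b.hap_start <= hap_pos < b.hap_end:
            return b.ref_anchor if b.ref_start is None else b.ref_start + (hap_pos - b.hap_start)
    return blocks[-1].ref_anchor


def write_inputs(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write the pipeline inputs and truth files for a simulated region:
    reference FASTA (+fai), het-SNP VCF (FreeBayes-style, unphased 0/1)
    and the truth SV VCF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_fa = outdir / "ref.fa"
    with open(ref_fa, "w") as fh:
        fh.write(f">{truth.chrom}\n")
        for i in range(0, len(truth.ref_seq), 80):
            fh.write(truth.ref_seq[i : i + 80] + "\n")
    pysam.faidx(str(ref_fa))

    snp_vcf = outdir / "snps.vcf"
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(truth.chrom, length=len(truth.ref_seq))
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("sim")
    with pysam.VariantFile(str(snp_vcf), "w", header=header) as vf:
        for s in truth.het_snps:
            rec = vf.new_record(
                contig=s.chrom, start=s.pos, alleles=(s.ref_allele, s.alt_allele)
            )
            rec.samples["sim"]["GT"] = (0, 1)
            vf.write(rec)

    truth_vcf = outdir / "truth_svs.vcf"
    write_phased_vcf(
        sorted(truth.sv_truth, key=lambda v: (v.chrom, v.pos)),
        "truth",
        truth_vcf,
        {truth.chrom: len(truth.ref_seq)},
    )
    return {"ref": ref_fa, "snps": snp_vcf, "truth_svs": truth_vcf}


# ---------------------------------------------------------------------------
# direct molecule sampling for haplotyper studies


def sample_annotated_molecules(
    n_molecules: int,
    n_snps: int,
    error_rate: float = 0.0,
    seed: int = 0,
    min_loci: int = 2,
    locus_spacing: int = 1_000,
):
    """Draw annotated molecules straight from a two-haplotype truth.

    Bypasses read simulation: each molecule picks a haplotype by coin and
    a contiguous run of at least ``min_loci`` SNP loci, and copies that
    haplotype's alleles with iid per-allele error. Returns
    (molecules, truth_haplotypes, hp1_alleles) where loci are at
    ``locus_spacing`` intervals.
    """
    from .readcloud import Molecule

    rng = np.random.default_rng(seed)
    hp1 = rng.integers(0, 2, size=n_snps)
    loci = [i * locus_spacing for i in range(n_snps)]
    molecules, truth_hap = [], []
    for i in range(n_molecules):
        hap = int(rng.integers(1, 3))
        ln = int(rng.integers(min_loci, n_snps + 1))
        a = int(rng.integers(0, n_snps - ln + 1))
        alleles = {}
        for j in range(a, a + ln):
            code = int(hp1[j]) if hap == 1 else 1 - int(hp1[j])
            if error_rate > 0 and rng.random() < error_rate:
                code = 1 - code
            alleles[loci[j]] = code
        m = Molecule(
            barcode=f"M{i:04d}",
            chrom="chr1",
            start=loci[a],
            end=loci[a + ln - 1] + 1,
            reads=[],
            alleles=alleles,
        )
        molecules.append(m)
        truth_hap.append(hap)
    return molecules, truth_hap, {loci[j]: int(hp1[j]) for j in range(n_snps)}
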