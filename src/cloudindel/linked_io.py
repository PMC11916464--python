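"""Readers and writers for the formats the pipeline touches.

Everything in memory is 0-based, half-open. Conversion to the 1-based
conventions of VCF happens only at the file boundary, in this module.

BAM/SAM, VCF and FASTA access is delegated to pysam; PAF with a cs
difference string is parsed and written here (there is no standard
in-memory PAF container to reach for).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pysam

# pysam numeric CIGAR operation codes
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H, _CIG_P, _CIG_EQ, _CIG_X = range(9)

BarcodeDialect = Literal["bx", "name"]


@dataclass(frozen=True)
class Region:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Region.chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class BarcodedRead:
    """One aligned short read carrying a linked-read barcode."""

    name: str
    barcode: str
    chrom: str
    pos: int  # 0-based leftmost mapped position
    mapq: int
    sequence: str
    quals: str  # phred+33 string, same length as sequence
    is_read1: bool = True
    cigar: list[tuple[int, int]] = field(default_factory=list)
    snp_alleles: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("read position must be >= 0")
        if len(self.sequence) != len(self.quals):
            raise ValueError("sequence and quality strings differ in length")

    @property
    def reference_end(self) -> int:
        """0-based exclusive end on the reference, from the CIGAR."""
        span = sum(ln for op, ln in self.cigar if op in (_CIG_M, _CIG_D, _CIG_N, _CIG_EQ, _CIG_X))
        return self.pos + (span if span else len(self.sequence))

    def base_at(self, ref_pos: int) -> Optional[tuple[str, int]]:
        """Base call and phred quality covering ``ref_pos``, or None.

        Walks the CIGAR; deletions and skips cover no base, soft clips
        consume query only.
        """
        cigar = self.cigar or [(_CIG_M, len(self.sequence))]
        rpos, qpos = self.pos, 0
        for op, ln in cigar:
            if op in (_CIG_M, _CIG_EQ, _CIG_X):
                if rpos <= ref_pos < rpos + ln:
                    q = qpos + (ref_pos - rpos)
                    return self.sequence[q], ord(self.quals[q]) - 33
                rpos += ln
                qpos += ln
            elif op in (_CIG_D, _CIG_N):
                if rpos <= ref_pos < rpos + ln:
                    return None
                rpos += ln
            elif op in (_CIG_I, _CIG_S):
                qpos += ln
            # H and P consume nothing we track
        return None


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous SNP, 0-based position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"allele {a!r} is not a single ACGT base")


# op codes for contig-to-reference difference operations
OP_MATCH = "match"
OP_MISMATCH = "mismatch"
OP_INS = "insertion"
OP_DEL = "deletion"

_TARGET_CONSUMING = {OP_MATCH, OP_MISMATCH, OP_DEL}
_QUERY_CONSUMING = {OP_MATCH, OP_MISMATCH, OP_INS}


@dataclass(frozen=True)
class AlnOp:
    """One difference-string operation.

    ``seq`` holds the inserted bases (insertion), the substituted query
    base (mismatch), or the deleted reference bases (deletion); empty for
    match runs.
    """

    op: str
    length: int
    seq: str = ""


@dataclass
class ContigAlignment:
    """Best placement of one assembled contig on the reference."""

    contig_name: str
    contig_len: int
    strand: str  # '+' or '-'
    target_chrom: str
    target_start: int
    target_end: int
    mapq: int
    ops: list[AlnOp]

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("alignment must carry at least one op")
        span = sum(o.length for o in self.ops if o.op in _TARGET_CONSUMING)
        if span != self.target_end - self.target_start:
            raise ValueError(
                f"ops span {span}bp but target interval is "
                f"{self.target_end - self.target_start}bp"
            )

    @property
    def query_span(self) -> int:
        return sum(o.length for o in self.ops if o.op in _QUERY_CONSUMING)


@dataclass
class ExtractionResult:
    """Reads pulled from an alignment file plus skip bookkeeping."""

    reads: list[BarcodedRead]
    n_no_barcode: int = 0
    n_filtered: int = 0  # unmapped/secondary/supplementary/dup/low-mapq

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def _barcode_of(aln: pysam.AlignedSegment, dialect: BarcodeDialect) -> Optional[str]:
    if dialect == "bx":
        if aln.has_tag("BX"):
            bx = aln.get_tag("BX")
            return str(bx) if bx else None
        return None
    if dialect == "name":
        name = aln.query_name or ""
        if "#" in name:
            bc = name.rsplit("#", 1)[1]
            return bc or None
        return None
    raise ValueError(f"unknown barcode dialect {dialect!r}")


def read_region_alignments(
    path: str | Path,
    region: Region,
    min_mapq: int = 20,
    barcode_dialect: BarcodeDialect = "bx",
) -> ExtractionResult:
    """Extract barcoded reads overlapping ``region`` from an indexed BAM/SAM.

    Only primary, mapped, non-duplicate alignments with mapping quality at
    least ``min_mapq`` and a parseable barcode are returned. Reads lacking
    a barcode are skipped and counted, never fatal; a missing index is an
    explicit error because random access is required.
    """
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    out: list[BarcodedRead] = []
    n_nobc = 0
    n_filt = 0
    with pysam.AlignmentFile(path, mode) as af:
        try:
            it = af.fetch(region.chrom, region.start, region.end)
        except ValueError as exc:
            raise FileNotFoundError(
                f"cannot fetch {region} from {path}: is the file "
                f"coordinate-sorted and indexed? ({exc})"
            ) from exc
        for aln in it:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
                or aln.mapping_quality < min_mapq
            ):
                n_filt += 1
                continue
            bc = _barcode_of(aln, barcode_dialect)
            if bc is None:
                n_nobc += 1
                continue
            quals = aln.query_qualities
            qstr = (
                "".join(chr(q + 33) for q in quals)
                if quals is not None
                else "I" * len(aln.query_sequence or "")
            )
            out.append(
                BarcodedRead(
                    name=aln.query_name,
                    barcode=bc,
                    chrom=aln.reference_name,
                    pos=aln.reference_start,
                    mapq=aln.mapping_quality,
                    sequence=(aln.query_sequence or "").upper(),
                    quals=qstr,
                    is_read1=not aln.is_read2,
                    cigar=list(aln.cigartuples or []),
                )
            )
    return ExtractionResult(out, n_no_barcode=n_nobc, n_filtered=n_filt)


_HET_GTS = {(0, 1), (1, 0)}


def read_het_snps(path: str | Path, region: Region) -> list[HetSNP]:
    """Biallelic heterozygous SNPs inside ``region``, sorted by position.

    Homozygous records, indels, multi-allelic sites and records with a
    malformed genotype are excluded (the latter with a warning).
    """
    import warnings

    out: list[HetSNP] = []
    with pysam.VariantFile(str(path)) as vf:
        if vf.index is not None:
            it = vf.fetch(region.chrom, region.start, region.end)
        else:
            it = (
                r
                for r in vf
                if r.chrom == region.chrom and region.start <= r.start < region.end
            )
        for rec in it:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                continue
            try:
                sample = rec.samples[0]
                gt = tuple(sample["GT"])
            except (KeyError, IndexError, TypeError):
                warnings.warn(f"skipping record at {rec.chrom}:{rec.pos}: bad GT field")
                continue
            if None in gt or tuple(sorted(gt)) != (0, 1):
                continue
            out.append(HetSNP(rec.chrom, rec.start, ref, alt))
    out.sort(key=lambda s: s.pos)
    return out


def read_reference_window(path: str | Path, region: Region) -> str:
    """Uppercase reference sequence for ``region`` from an indexed FASTA."""
    with pysam.FastaFile(str(path)) as fa:
        if region.chrom not in fa.references:
            raise KeyError(f"contig {region.chrom!r} not in {path}")
        clen = fa.get_reference_length(region.chrom)
        if region.end > clen:
            raise ValueError(
                f"region {region} extends past contig {region.chrom} "
                f"(length {clen})"
            )
        return fa.fetch(region.chrom, region.start, region.end).upper()


# --- PAF with cs difference string ------------------------------------------

_CS_TOKEN = re.compile(r"(:\d+|\*[a-zA-Z]{2}|\+[a-zA-Z]+|-[a-zA-Z]+)")


def _ops_from_cs(cs: str) -> list[AlnOp]:
    ops: list[AlnOp] = []
    consumed = 0
    for tok in _CS_TOKEN.finditer(cs):
        t = tok.group(0)
        consumed += len(t)
        if t[0] == ":":
            ops.append(AlnOp(OP_MATCH, int(t[1:])))
        elif t[0] == "*":
            ops.append(AlnOp(OP_MISMATCH, 1, t[2].upper()))
        elif t[0] == "+":
            ops.append(AlnOp(OP_INS, len(t) - 1, t[1:].upper()))
        else:
            ops.append(AlnOp(OP_DEL, len(t) - 1, t[1:].upper()))
    if consumed != len(cs):
        raise ValueError(f"unparseable cs string: {cs!r}")
    return ops


def _cs_from_ops(ops: Sequence[AlnOp]) -> str:
    parts = []
    for o in ops:
        if o.op == OP_MATCH:
            parts.append(f":{o.length}")
        elif o.op == OP_MISMATCH:
            # reference base is not stored on the op; cs requires it, so the
            # writer takes it via ContigAlignment + reference (see write_paf)
            raise ValueError("mismatch ops need reference context; use write_paf")
        elif o.op == OP_INS:
            parts.append(f"+{o.seq.lower()}")
        else:
            parts.append(f"-{o.seq.lower()}")
    return "".join(parts)


def parse_contig_alignments(path: str | Path) -> list[ContigAlignment]:
    """Parse a PAF file whose lines carry a ``cs:Z:`` difference tag.

    One ContigAlignment per line. Lines without the cs tag are an error:
    variant extraction is impossible without the difference string.
    """
    out: list[ContigAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: truncated PAF line")
            cs = None
            for tag in f[12:]:
                if tag.startswith("cs:Z:"):
                    cs = tag[5:]
                    break
            if cs is None:
                raise ValueError(
                    f"{path}:{lineno}: no cs:Z: tag; variant extraction "
                    "requires a difference string"
                )
            ops = _ops_from_cs(cs)
            aln = ContigAlignment(
                contig_name=f[0],
                contig_len=int(f[1]),
                strand=f[4],
                target_chrom=f[5],
                target_start=int(f[7]),
                target_end=int(f[8]),
                mapq=int(f[11]),
                ops=ops,
            )
            out.append(aln)
    return out


def write_paf(
    alignments: Iterable[ContigAlignment],
    path: str | Path,
    ref_window: str,
    window_start: int,
) -> None:
    """Write alignments as PAF lines with a cs:Z: tag.

    ``ref_window``/``window_start`` supply reference bases for mismatch
    tokens (cs stores both the reference and the substituted base).
    """
    with open(path, "w") as fh:
        for a in alignments:
            parts = []
            rp = a.target_start
            for o in a.ops:
                if o.op == OP_MATCH:
                    parts.append(f":{o.length}")
                    rp += o.length
                elif o.op == OP_MISMATCH:
                    refb = ref_window[rp - window_start]
                    parts.append(f"*{refb.lower()}{o.seq.lower()}")
                    rp += 1
                elif o.op == OP_INS:
                    parts.append(f"+{o.seq.lower()}")
                else:
                    parts.append(f"-{o.seq.lower()}")
            cs = "".join(parts)
            qspan = a.query_span
            nmatch = sum(o.length for o in a.ops if o.op == OP_MATCH)
            blocklen = sum(o.length for o in a.ops)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.contig_name,
                        a.contig_len,
                        0,
                        qspan,
                        a.strand,
                        a.target_chrom,
                        window_start + len(ref_window),
                        a.target_start,
                        a.target_end,
                        nmatch,
                        blocklen,
                        a.mapq,
                        f"cs:Z:{cs}",
                    )
                )
                + "\n"
            )


# --- phased VCF --------------------------------------------------------------


def write_phased_vcf(
    variants,  # list[GenotypedVariant]; late import avoids a module cycle
    sample: str,
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    """Write genotyped variants as a phased single-sample VCF 4.2.

    Positions become 1-based; indels are expected already anchored with one
    reference base. Input must be sorted by (chrom, pos); unsorted input is
    an error, never silently reordered.
    """
    variants = list(variants)
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos) before writing")

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, ln in contig_lengths.items():
        header.contigs.add(chrom, length=ln)
    header.add_line('##FILTER=<ID=CONTIG_ONLY,Description="SNP seen only in contigs, not in the input small-variant VCF">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed indel length">')
    header.add_line('##INFO=<ID=CONTIGS,Number=.,Type=String,Description="Supporting contig names">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set (block) identifier">')
    header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos,
                alleles=(v.ref_seq, v.alt_seq),
                filter=(v.filter or "PASS"),
            )
            rec.info["SVTYPE"] = v.type
            if v.type != "SNP":
                rec.info["SVLEN"] = v.size if v.type == "INS" else -v.size
            if v.supporting_contigs:
                rec.info["CONTIGS"] = tuple(v.supporting_contigs)
            a, b = (int(x) for x in v.genotype.split("|"))
            rec.samples[sample]["GT"] = (a, b)
            rec.samples[sample].phased = True
            rec.samples[sample]["PS"] = int(v.block_id)
            vf.write(rec)


def read_phased_vcf(path: str | Path):
    """Re-read a phased VCF written by :func:`write_phased_vcf`."""
    from .contig_variants import GenotypedVariant  # local import, no cycle

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                vtype, size = "SNP", 1
            elif len(alt) > len(ref):
                vtype, size = "INS", len(alt) - len(ref)
            else:
                vtype, size = "DEL", len(ref) - len(alt)
            sample = rec.samples[0]
            gt = "|".join(str(x) for x in sample["GT"])
            filters = list(rec.filter.keys())
            contigs = list(rec.info.get("CONTIGS", ()) or ())
            out.append(
                GenotypedVariant(
                    chrom=rec.chrom,
                    pos=rec.start,
                    type=vtype,
                    ref_seq=ref,
                    alt_seq=alt,
                    size=size,
                    genotype=gt,
                    block_id=int(sample["PS"]),
                    supporting_contigs=contigs,
                    filter=(filters[0] if filters and filters[0] != "PASS" else None),
                )
            )
    return out


# --- FASTQ pairs -------------------------------------------------------------


def write_read_pairs(
    reads: Iterable[BarcodedRead],
    path_r1: str | Path,
    path_r2: str | Path,
    path_singleton: str | Path | None = None,
) -> tuple[int, int]:
    """Write reads as a FASTQ pair, mate-matched by name.

    The barcode is preserved as a ``#barcode`` read-name suffix so it
    survives tools that drop tags. Reads without a mate go to the singleton
    file. Returns (n_pairs, n_singletons). A duplicated (name, mate) is an
    error.
    """
    by_name: dict[str, dict[bool, BarcodedRead]] = {}
    for r in reads:
        slot = by_name.setdefault(r.name, {})
        if r.is_read1 in slot:
            raise ValueError(f"duplicate read {r.name} mate {1 if r.is_read1 else 2}")
        slot[r.is_read1] = r

    def fq(rec: BarcodedRead) -> str:
        name = rec.name if "#" in rec.name else f"{rec.name}#{rec.barcode}"
        return f"@{name}\n{rec.sequence}\n+\n{rec.quals}\n"

    n_pairs = n_single = 0
    singles: list[BarcodedRead] = []
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for name in sorted(by_name):
            slot = by_name[name]
            if True in slot and False in slot:
                f1.write(fq(slot[True]))
                f2.write(fq(slot[False]))
                n_pairs += 1
            else:
                singles.append(next(iter(slot.values())))
    if path_singleton is not None:
        with open(path_singleton, "w") as fs:
            for r in singles:
                fs.write(fq(r))
                n_single += 1
    else:
        n_single = len(singles)
    return n_pairs, n_single
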