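"""Per-region orchestration of the four-stage pipeline.

extract -> deconvolve/annotate -> phase -> assemble per haplotype ->
align -> call -> chain -> merge/genotype -> refine -> phased VCF.

Each target region is processed independently: a failure in one region of
a batch is recorded and the run continues. Intermediates (molecule and
block tables, per-haplotype FASTQ, contig FASTA, PAF, VCF) are serialized
next to the output VCF so any stage can be inspected or resumed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pysam

from . import assembly as asm
from . import contig_variants as cv
from . import haplotyper as hap
from . import linked_io as io
from . import readcloud as rc


@dataclass
class RunConfig:
    flank_bp: int = 25_000
    technology: str = "tenx"
    barcode_dialect: io.BarcodeDialect = "bx"
    min_mapq: int = 20
    deconv: Optional[rc.DeconvolutionConfig] = None
    chain: cv.ChainConfig = field(default_factory=cv.ChainConfig)
    assembler: Literal["external", "builtin"] = "builtin"
    aligner: Literal["external", "builtin"] = "builtin"
    kmer: int = 31
    min_aln_len: int = 10_000
    min_call_mapq: int = 5
    joint_unphased: bool = False
    sample: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")
        if self.deconv is None:
            self.deconv = rc.DeconvolutionConfig.for_technology(self.technology)


def build_target_region(
    chrom: str, breakpoints: tuple[int, int], flank_bp: int = 25_000
) -> io.Region:
    """Target window: SV breakpoints padded by the flank on both sides,
    clipped at the chromosome start."""
    start, end = breakpoints
    if start > end:
        raise ValueError("breakpoints must satisfy start <= end")
    return io.Region(chrom, max(0, start - flank_bp), end + flank_bp)


def run_region(
    bam: str | Path,
    vcf: str | Path,
    ref: str | Path,
    region: io.Region,
    cfg: RunConfig,
    outdir: str | Path,
) -> tuple[list[cv.GenotypedVariant], dict]:
    """Run the full pipeline on one region; returns (variants, diagnostics).

    An unphaseable region (no het SNPs / no phase blocks) yields an empty
    VCF and an UNPHASED diagnostic, unless joint unphased assembly is
    enabled, in which case all extracted reads are assembled together and
    calls are emitted as homozygous.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diag: dict = {"region": str(region), "unphased": False, "timings_s": {}}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        diag["timings_s"][stage] = round(now - t0, 3)
        t0 = now

    with pysam.FastaFile(str(ref)) as fa:
        contig_lengths = {region.chrom: fa.get_reference_length(region.chrom)}
    region = io.Region(
        region.chrom, region.start, min(region.end, contig_lengths[region.chrom])
    )
    ref_window = io.read_reference_window(ref, region)

    extraction = io.read_region_alignments(
        bam, region, min_mapq=cfg.min_mapq, barcode_dialect=cfg.barcode_dialect
    )
    snps = io.read_het_snps(vcf, region)
    diag["n_reads"] = len(extraction)
    diag["n_reads_skipped_no_barcode"] = extraction.n_no_barcode
    diag["n_het_snps"] = len(snps)
    tick("extract")

    molecules = rc.deconvolve_barcodes(extraction.reads, cfg.deconv)
    rc.annotate_molecules(molecules, snps, region)
    diag["n_molecules"] = len(molecules)
    diag["phased_molecule_fraction"] = round(rc.phased_molecule_fraction(molecules), 4)
    _write_molecules_tsv(molecules, outdir / "molecules.tsv")
    tick("deconvolve")

    blocks = hap.partition_molecules(molecules)
    diag["n_blocks"] = len(blocks)
    diag["block_sizes"] = [
        len(b.hp1_molecules) + len(b.hp2_molecules) for b in blocks
    ]
    _write_blocks_tsv(blocks, outdir / "blocks.tsv")
    tick("phase")

    vcf_out = outdir / "phased.vcf"
    if not blocks and not cfg.joint_unphased:
        diag["unphased"] = True
        io.write_phased_vcf([], cfg.sample, vcf_out, contig_lengths)
        diag["n_variants"] = 0
        return [], diag

    contigs: list[asm.Contig] = []
    contig_meta: dict[str, tuple[int, int]] = {}  # name -> (haplotype, block)
    if blocks:
        parts = hap.partition_reads(blocks)
        for block, part in zip(blocks, parts):
            for hnum, reads in ((1, part.r_hp1), (2, part.r_hp2)):
                io.write_read_pairs(
                    reads,
                    outdir / f"block{block.block_id}_hp{hnum}_R1.fastq",
                    outdir / f"block{block.block_id}_hp{hnum}_R2.fastq",
                )
                cs = asm.assemble_haplotype(
                    reads,
                    mode=cfg.assembler,
                    k=cfg.kmer,
                    haplotype=hnum,
                    block_id=block.block_id,
                    workdir=outdir,
                )
                contigs.extend(cs)
                for c in cs:
                    contig_meta[c.name] = (hnum, block.block_id)
    else:  # joint unphased mode on a region without heterozygosity
        diag["unphased"] = True
        cs = asm.assemble_haplotype(
            extraction.reads, mode=cfg.assembler, k=cfg.kmer, haplotype=1,
            block_id=0, workdir=outdir,
        )
        contigs.extend(cs)
        for c in cs:
            contig_meta[c.name] = (1, 0)
    diag["n_contigs"] = len(contigs)
    diag["contig_n50"] = asm.contig_n50(contigs)
    with open(outdir / "contigs.fasta", "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n{c.sequence}\n")
    tick("assemble")

    alignments = cv.align_contigs(contigs, ref_window, region, mode=cfg.aligner)
    io.write_paf(alignments, outdir / "contigs.paf", ref_window, region.start)
    by_hap_block: dict[tuple[int, int], list[cv.RawVariant]] = {}
    for aln in alignments:
        hnum, bid = contig_meta[aln.contig_name]
        vs = cv.extract_variants(
            aln,
            ref_window,
            region.start,
            haplotype=hnum,
            block_id=bid,
            min_call_mapq=cfg.min_call_mapq,
            min_aln_len=cfg.min_aln_len,
        )
        by_hap_block.setdefault((bid, hnum), []).extend(vs)
    tick("align_call")

    genotyped: list[cv.GenotypedVariant] = []
    block_ids = sorted({bid for bid, _ in by_hap_block})
    for bid in block_ids:
        set1 = sorted(by_hap_block.get((bid, 1), []), key=lambda v: v.pos)
        set2 = sorted(by_hap_block.get((bid, 2), []), key=lambda v: v.pos)
        set1 = cv.chain_variants(set1, cfg.chain)
        set2 = cv.chain_variants(set2, cfg.chain)
        merged = cv.merge_and_genotype(set1, set2, cfg.chain)
        if not blocks:  # joint mode: single read pool, calls are homozygous
            merged = [
                cv.GenotypedVariant(
                    **{**v.__dict__, "genotype": "1|1"}
                )
                for v in merged
            ]
        genotyped.extend(merged)
    genotyped.sort(key=lambda v: (v.pos, v.type, v.size))
    genotyped = cv.chain_variants(genotyped, cfg.chain)
    genotyped = cv.refine_snps(genotyped, snps)
    io.write_phased_vcf(genotyped, cfg.sample, vcf_out, contig_lengths)
    diag["n_variants"] = len(genotyped)
    diag["n_sv_calls"] = sum(
        1 for v in genotyped if cv.classify_size(v).startswith("SV")
    )
    tick("genotype_write")
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    return genotyped, diag


def run_batch(
    bam: str | Path,
    vcf: str | Path,
    ref: str | Path,
    bed: str | Path,
    cfg: RunConfig,
    outdir: str | Path,
) -> tuple[int, list[dict]]:
    """Run every BED record as an independent target region.

    Returns (n_failures, per-region diagnostics). A failing region is
    logged and skipped; the rest of the batch proceeds.
    """
    outdir = Path(outdir)
    results = []
    failures = 0
    with open(bed) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            region = build_target_region(
                chrom, (int(start), int(end)), cfg.flank_bp
            )
            rdir = outdir / f"region_{idx:04d}_{chrom}_{start}_{end}"
            try:
                _, diag = run_region(bam, vcf, ref, region, cfg, rdir)
            except Exception as exc:  # noqa: BLE001 - independent region failures
                failures += 1
                diag = {"region": str(region), "failed": True, "error": str(exc)}
            results.append(diag)
    with open(outdir / "batch.jsonl", "w") as fh:
        for diag in results:
            fh.write(json.dumps(diag) + "\n")
    return failures, results


def _write_molecules_tsv(molecules: list[rc.Molecule], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tchrom\tstart\tend\tn_reads\tn_alleles\tannotation\n")
        for m in molecules:
            fh.write(
                f"{m.barcode}\t{m.chrom}\t{m.start}\t{m.end}\t{len(m)}\t"
                f"{len(m.alleles)}\t{m.annotation_string()}\n"
            )


def _write_blocks_tsv(blocks: list[hap.PhaseBlock], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tn_loci\tfirst_locus\tlast_locus\tn_hp1\tn_hp2\tn_unphased\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{len(b.loci)}\t{b.loci[0]}\t{b.loci[-1]}\t"
                f"{len(b.hp1_molecules)}\t{len(b.hp2_molecules)}\t"
                f"{len(b.unphased_molecules)}\n"
            )
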