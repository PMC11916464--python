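"""Shared fixtures: tiny BAM/VCF/FASTA builders and one simulated region."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from cloudindel import simulate as sim
from cloudindel.linked_io import BarcodedRead


def make_bam(
    path: Path,
    reads: list[dict],
    chrom: str = "chr1",
    chrom_len: int = 1_000_000,
) -> Path:
    """Write a coordinate-sorted, indexed BAM from read dicts.

    Keys: name, pos; optional barcode (BX tag), mapq, seq, flag, cigar.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r["pos"])
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r["name"]
            seq = r.get("seq", "ACGT" * 25)
            a.query_sequence = seq
            a.flag = r.get("flag", 0)
            a.reference_id = 0
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigartuples = r.get("cigar", [(0, len(seq))])
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if "barcode" in r:
                a.set_tag("BX", r["barcode"], "Z")
            bam.write(a)
    pysam.index(str(path))
    return path


def make_read(
    name: str,
    barcode: str,
    pos: int,
    seq: str = "ACGT" * 25,
    chrom: str = "chr1",
    mapq: int = 60,
    is_read1: bool = True,
    quals: str | None = None,
    cigar=None,
) -> BarcodedRead:
    return BarcodedRead(
        name=name,
        barcode=barcode,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        sequence=seq,
        quals=quals if quals is not None else "I" * len(seq),
        is_read1=is_read1,
        cigar=cigar if cigar is not None else [(0, len(seq))],
    )


@pytest.fixture(scope="session")
def het_del_sim(tmp_path_factory):
    """One simulated 50kb tenx region with a het 2.07kb deletion,
    reads/BAM/VCF/FASTA on disk; shared across tests."""
    out = tmp_path_factory.mktemp("het_del_sim")
    truth = sim.simulate_diploid(
        50_000, 1e-3, [sim.SVSpec("DEL", 25_000, 2_070, "het")], seed=42
    )
    prof = sim.LibraryProfile.preset("tenx", seed=42)
    rng = np.random.default_rng(43)
    mols = sim.simulate_molecules(truth, prof, rng)
    paths = sim.simulate_linked_reads(mols, truth, prof, out, rng=rng)
    paths.update(sim.write_inputs(truth, out))
    return {"truth": truth, "profile": prof, "paths": paths, "outdir": out}
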