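"""Canned simulation studies exercising the whole pipeline.

These drive the simulator, pipeline and evaluator together at the study
conditions used throughout the package's validation: 50 kb target
regions, the 10x-style library preset, error-free reads and the builtin
assembler, with SV matching at the benchmarking thresholds
r=200 / P=0.1 / p=0.1 / O=0.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluate as ev
from . import pipeline as pl
from . import simulate as sim
from .haplotyper import partition_molecules

MATCH_CFG = ev.MatchConfig(refdist=200, pctsize=0.1, pctsim=0.1, pctovl=0.0)


@dataclass
class RegionOutcome:
    size: int
    genotype: str
    tp: bool
    gt_match: bool
    phased_fraction: float


def _run_one(
    svs: list[sim.SVSpec],
    seed: int,
    workdir: Path,
    region_len: int = 50_000,
    retain_insertion_reads: bool = False,
) -> tuple[list, ev.SVMatchReport, dict, sim.TruthSet]:
    truth = sim.simulate_diploid(region_len, 1e-3, svs, seed=seed)
    prof = sim.LibraryProfile.preset("tenx", seed=seed)
    rng = np.random.default_rng(seed + 1)
    mols = sim.simulate_molecules(truth, prof, rng)
    paths = sim.simulate_linked_reads(
        mols, truth, prof, workdir, retain_insertion_reads=retain_insertion_reads,
        rng=rng,
    )
    paths.update(sim.write_inputs(truth, workdir))
    variants, diag = pl.run_region(
        paths["bam"], paths["snps"], paths["ref"], truth.region,
        pl.RunConfig(), workdir / "out",
    )
    pairs, report = ev.match_calls(variants, truth.sv_truth, MATCH_CFG)
    return variants, report, diag, truth


def deletion_study(
    n_regions: int = 20, seed: int = 1, workdir: str | Path | None = None
) -> dict:
    """Implanted het/hom deletions of 100 bp - 2 kb across independent
    50 kb regions; returns aggregate counts and per-region outcomes.

    Sizes sweep the range geometrically; genotypes alternate het/hom.
    """
    sizes = np.unique(
        np.geomspace(100, 2_000, n_regions).round().astype(int)
    ).tolist()
    while len(sizes) < n_regions:
        sizes.append(2_000)
    outcomes: list[RegionOutcome] = []
    tp = tp_gt = fp = fn = 0
    phased_fracs = []
    with tempfile.TemporaryDirectory() as td:
        base = Path(workdir) if workdir else Path(td)
        for i in range(n_regions):
            gt = "het" if i % 2 == 0 else "hom"
            svs = [sim.SVSpec("DEL", 25_000, int(sizes[i]), gt)]
            region_seed = seed * 10_000 + i
            _, rep, diag, truth = _run_one(svs, region_seed, base / f"r{i:02d}")
            tp += rep.TP
            tp_gt += rep.TP_GT
            fp += rep.FP
            fn += rep.FN
            phased_fracs.append(diag["phased_molecule_fraction"])
            outcomes.append(
                RegionOutcome(
                    size=int(sizes[i]),
                    genotype=truth.sv_truth[0].genotype,
                    tp=rep.TP == 1,
                    gt_match=rep.TP_GT == 1,
                    phased_fraction=diag["phased_molecule_fraction"],
                )
            )
    report = ev.SVMatchReport(TP=tp, TP_GT=tp_gt, FP=fp, FN=fn)
    return {
        "report": report,
        "outcomes": outcomes,
        "mean_phased_fraction": float(np.mean(phased_fracs)),
    }


def insertion_cases(seed: int = 1, workdir: str | Path | None = None) -> dict:
    """The two canonical insertion outcomes.

    A 70 bp homozygous insertion is spanned by 150 bp reads and is
    recovered as 1|1. A large (600 bp) insertion loses its interior
    read pairs to unmappability, so the assembler cannot spell the novel
    sequence and the call is a false negative - the characteristic
    failure mode of large-insertion detection from mapped reads only.
    """
    with tempfile.TemporaryDirectory() as td:
        base = Path(workdir) if workdir else Path(td)
        _, rep70, _, _ = _run_one(
            [sim.SVSpec("INS", 25_000, 70, "hom")], seed * 10_000 + 101,
            base / "ins70", retain_insertion_reads=True,
        )
        _, rep_large, _, truth_large = _run_one(
            [sim.SVSpec("INS", 25_000, 600, "hom")], seed * 10_000 + 102,
            base / "ins600",
        )
    return {
        "ins70_recovered": rep70.TP == 1 and rep70.TP_GT == 1,
        "ins70_report": rep70,
        "large_ins_fn": rep_large.FN,
        "large_ins_tp": rep_large.TP,
        "large_ins_unmapped_reads": truth_large.n_unmapped_reads,
    }


def haplotyping_accuracy(error_rate: float, seed: int = 1,
                         n_molecules: int = 200, n_snps: int = 20) -> float:
    """Molecule-to-haplotype assignment accuracy (max over label swap)."""
    mols, truth_hap, _ = sim.sample_annotated_molecules(
        n_molecules, n_snps, error_rate=error_rate, seed=seed
    )
    blocks = partition_molecules(mols)
    idx = {id(m): i for i, m in enumerate(mols)}
    correct = total = 0
    for b in blocks:
        agree = [0, 0]
        for label, group in ((1, b.hp1_molecules), (2, b.hp2_molecules)):
            for m in group:
                total += 1
                agree[0 if truth_hap[idx[id(m)]] == label else 1] += 1
        correct += max(agree)
    return correct / total if total else 0.0
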