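"""Partition annotated molecules into two complementary haplotypes.

The two parental haplotypes carry complementary alleles at every
heterozygous SNP: if one haplotype reads "01001" over five het SNPs the
other reads "10110". Molecules annotated with allele codes therefore fall
into two orientation classes, recoverable by clustering: molecules from
the same haplotype agree at shared loci, molecules from opposite
haplotypes disagree everywhere.

The clustering is deterministic and agglomerative. Every molecule starts
as its own cluster with an orientation bit. The score of a cluster pair is
max over relative orientation of (#allele agreements - #disagreements)
between the cluster consensus vectors on shared loci; the highest-scoring
pair with positive score is merged (flipping orientations as needed) until
no positive-scoring pair remains. Phase blocks are the connected
components of the molecule-locus sharing graph; within each block the
orientation classes of the largest surviving cluster are the two
haplotypes, and molecules in other surviving clusters (equally consistent
with both orientations) stay unphased rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linked_io import BarcodedRead
from .readcloud import Molecule


@dataclass
class PhaseBlock:
    """A set of jointly phased het-SNP loci and the molecule bipartition."""

    block_id: int
    loci: list[int]
    hp1_alleles: dict[int, int]
    hp2_alleles: dict[int, int]
    hp1_molecules: list[Molecule] = field(default_factory=list)
    hp2_molecules: list[Molecule] = field(default_factory=list)
    unphased_molecules: list[Molecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus in self.loci:
            if self.hp2_alleles[locus] != 1 - self.hp1_alleles[locus]:
                raise ValueError(f"haplotypes not complementary at locus {locus}")


@dataclass
class ReadPartition:
    """Barcoded reads split by haplotype within one phase block."""

    block_id: int
    r_hp1: list[BarcodedRead] = field(default_factory=list)
    r_hp2: list[BarcodedRead] = field(default_factory=list)
    unassigned: list[BarcodedRead] = field(default_factory=list)


def _components(molecules: list[Molecule]) -> list[list[Molecule]]:
    """Connected components of the molecule-locus sharing graph."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for mol in molecules:
        loci = list(mol.alleles)
        for locus in loci:
            parent.setdefault(locus, locus)
        for a, b in zip(loci, loci[1:]):
            union(a, b)

    groups: dict[int, list[Molecule]] = {}
    for mol in molecules:
        root = find(next(iter(mol.alleles)))
        groups.setdefault(root, []).append(mol)
    comps = list(groups.values())
    comps.sort(key=lambda ms: min(min(m.alleles) for m in ms))
    return comps


def _cluster_component(mols: list[Molecule]) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Agglomerative orientation clustering of one component.

    Returns (sorted loci, orientation array with -1 = unphased / 0 / 1,
    consensus vector over loci in {-1, 0, +1} where +1 encodes allele 0 of
    the orientation-0 class).
    """
    loci = sorted({locus for m in mols for locus in m.alleles})
    col = {locus: j for j, locus in enumerate(loci)}
    n, width = len(mols), len(loci)

    # +1 for allele 0, -1 for allele 1, 0 uncovered
    M = np.zeros((n, width), dtype=np.int64)
    for i, m in enumerate(mols):
        for locus, code in m.alleles.items():
            M[i, col[locus]] = 1 if code == 0 else -1

    # cluster state: count vector (sum of oriented member rows)
    counts = M.astype(np.float64).copy()
    sign = np.sign(counts)
    # score[i, j] = |dot(sign_i, sign_j)| — agreements minus disagreements,
    # maximized over relative orientation
    dot = sign @ sign.T
    score = np.abs(dot)
    np.fill_diagonal(score, 0)
    active = np.ones(n, dtype=bool)
    orient = np.zeros(n, dtype=np.int8)  # per-molecule orientation bit
    member_of = np.arange(n)  # molecule -> cluster index
    members: list[list[int]] = [[i] for i in range(n)]

    masked = score.copy()
    while True:
        flat = int(np.argmax(masked))
        i, j = divmod(flat, n)
        if masked[i, j] <= 0:
            break
        if i > j:
            i, j = j, i
        o = 1 if dot[i, j] >= 0 else -1
        counts[i] += o * counts[j]
        if o < 0:
            for mi in members[j]:
                orient[mi] ^= 1
        members[i].extend(members[j])
        member_of[members[j]] = i
        members[j] = []
        active[j] = False
        masked[j, :] = 0
        masked[:, j] = 0
        si = np.sign(counts[i])
        d = sign @ si
        d[~active] = 0
        dot[i, :] = d
        dot[:, i] = d
        sign[i] = si
        row = np.abs(d)
        row[i] = 0
        masked[i, :] = row
        masked[:, i] = row

    # largest surviving cluster is the phased backbone
    sizes = [(len(members[i]), -i) for i in range(n)]
    backbone = max(range(n), key=lambda i: sizes[i])
    orientation = np.full(n, -1, dtype=np.int8)
    for mi in members[backbone]:
        orientation[mi] = orient[mi]
    consensus = np.sign(counts[backbone]).astype(np.int64)
    return loci, orientation, consensus


def partition_molecules(molecules: list[Molecule]) -> list[PhaseBlock]:
    """Phase annotated molecules into blocks of two complementary haplotypes.

    Only molecules with at least one annotated allele participate. Within
    each block HP1 is canonically the haplotype whose consensus allele at
    the leftmost phased locus is 0, so output labels are reproducible.
    Returns an empty list when nothing is annotated (region unphaseable).
    """
    annotated = [m for m in molecules if m.alleles]
    if not annotated:
        return []

    blocks: list[PhaseBlock] = []
    for block_id, comp in enumerate(_components(annotated), start=1):
        # canonical molecule order: leftmost annotated locus, then barcode
        comp = sorted(comp, key=lambda m: (min(m.alleles), m.barcode, m.start))
        loci, orientation, consensus = _cluster_component(comp)

        phased_loci = [locus for locus, c in zip(loci, consensus) if c != 0]
        if not phased_loci:
            continue
        # consensus +1 -> orientation-0 class carries allele 0
        hp1 = {locus: (0 if c > 0 else 1) for locus, c in zip(loci, consensus) if c != 0}
        if hp1[phased_loci[0]] == 1:  # canonical labeling: HP1 has 0 at leftmost
            hp1 = {locus: 1 - code for locus, code in hp1.items()}
            orientation = np.where(orientation >= 0, 1 - orientation, orientation)
        hp2 = {locus: 1 - code for locus, code in hp1.items()}

        block = PhaseBlock(
            block_id=block_id,
            loci=phased_loci,
            hp1_alleles=hp1,
            hp2_alleles=hp2,
        )
        for mol, o in zip(comp, orientation):
            if o == 0:
                block.hp1_molecules.append(mol)
            elif o == 1:
                block.hp2_molecules.append(mol)
            else:
                block.unphased_molecules.append(mol)
        blocks.append(block)
    return blocks


def partition_reads(blocks: list[PhaseBlock]) -> list[ReadPartition]:
    """Split barcoded reads by haplotype: all member reads of an HP1
    molecule go to R_HP1, of an HP2 molecule to R_HP2. Reads of unphased
    molecules are left unassigned and excluded from assembly."""
    out = []
    for b in blocks:
        part = ReadPartition(block_id=b.block_id)
        for m in b.hp1_molecules:
            part.r_hp1.extend(m.reads)
        for m in b.hp2_molecules:
            part.r_hp2.extend(m.reads)
        for m in b.unphased_molecules:
            part.unassigned.extend(m.reads)
        out.append(part)
    return out
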