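"""Per-haplotype local assembly.

Real use drives an external short-read assembler (SPAdes by default)
through a small subprocess adapter. For self-contained operation and
testing there is also a builtin assembler: a plain de Bruijn graph on
k-mers with non-branching path compression (unitigs) and dead-end tip
removal. The builtin assembler does no error correction or scaffolding —
it targets low-error reads at high coverage, which is exactly what the
phased read sets of a 50 kb window look like; noisy real libraries should
use the external mode.

Both strands of every read are inserted into the graph, so each unitig
appears together with its reverse complement; contigs are reported in
canonical form (the lexicographically smaller of the two strands), which
makes the output invariant to the strand of the input reads.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np

from .linked_io import BarcodedRead, write_read_pairs

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase
_DEC = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class AssemblerError(RuntimeError):
    pass


@dataclass
class Contig:
    name: str
    haplotype: int
    block_id: int
    sequence: str
    source: Literal["external", "builtin"] = "builtin"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("contig sequence must be non-empty")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("contig sequence must be uppercase ACGTN")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExternalAssemblerConfig:
    """Subprocess adapter for an external assembler.

    ``command`` is a template with {r1}, {r2}, {outdir} placeholders;
    ``contig_path`` locates the output FASTA inside {outdir}. The default
    targets SPAdes; any assembler with a compatible shape can be swapped
    in, including extra raw arguments via the template.
    """

    command: str = "spades.py -1 {r1} -2 {r2} -o {outdir} --only-assembler"
    contig_path: str = "{outdir}/contigs.fasta"
    timeout_s: int = 1800


# ---------------------------------------------------------------------------
# builtin de Bruijn assembler


def _kmer_values(seqs: Iterable[str], k: int) -> np.ndarray:
    """2-bit-packed k-mer values of all sequences and their reverse
    complements, as one int64 array (with duplicates)."""
    joined = "N".join(seqs)
    if not joined:
        return np.zeros(0, dtype=np.int64)
    fwd = _ENC[np.frombuffer(joined.encode(), dtype=np.uint8)]
    rev = (3 - fwd[::-1]) % 5  # complement; sentinel 4 maps to 4
    rev[fwd[::-1] == 4] = 4
    chunks = []
    for codes in (fwd, rev):
        n = codes.size
        if n < k:
            continue
        m = n - k + 1
        acc = np.zeros(m, dtype=np.int64)
        for j in range(k):
            acc += codes[j : j + m].astype(np.int64) << (2 * (k - 1 - j))
        bad = (codes >= 4).astype(np.int64)
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k:] - cs[:-k]) == 0
        chunks.append(acc[valid])
    if not chunks:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(chunks)


def _neighbor_index(U: np.ndarray, cand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.searchsorted(U, cand)
    idx_c = np.minimum(idx, U.size - 1)
    exists = U[idx_c] == cand
    return idx_c, exists


def _unitigs(U: np.ndarray, k: int) -> list[np.ndarray]:
    """Maximal non-branching paths over the sorted unique k-mer array."""
    n = U.size
    if n == 0:
        return []
    mask = (np.int64(1) << (2 * (k - 1))) - 1
    suffix = U & mask
    cand_out = suffix[:, None] * 4 + np.arange(4, dtype=np.int64)
    out_idx, out_ok = _neighbor_index(U, cand_out)
    outdeg = out_ok.sum(axis=1)
    succ = np.where(out_ok, out_idx, 0).sum(axis=1)  # valid only when outdeg==1

    prefix = U >> 2
    cand_in = prefix[None, :] + (np.arange(4, dtype=np.int64)[:, None] << (2 * (k - 1)))
    in_idx, in_ok = _neighbor_index(U, cand_in.T.copy())
    indeg = in_ok.sum(axis=1)
    pred = np.where(in_ok, in_idx, 0).sum(axis=1)

    pred_safe = np.where(indeg == 1, pred, 0)  # pred only meaningful at indeg==1
    internal = (indeg == 1) & (outdeg[pred_safe] == 1)
    visited = np.zeros(n, dtype=bool)
    paths: list[np.ndarray] = []
    outdeg_l = outdeg.tolist()
    succ_l = succ.tolist()
    internal_l = internal.tolist()

    for s in range(n):
        if internal_l[s] or visited[s]:
            continue
        path = [s]
        visited[s] = True
        cur = s
        while outdeg_l[cur] == 1:
            nxt = succ_l[cur]
            if not internal_l[nxt] or visited[nxt]:
                break
            path.append(nxt)
            visited[nxt] = True
            cur = nxt
        paths.append(np.asarray(path))
    # leftover perfect cycles
    for s in range(n):
        if visited[s]:
            continue
        path = [s]
        visited[s] = True
        cur = succ_l[s]
        while cur != s:
            path.append(cur)
            visited[cur] = True
            cur = succ_l[cur]
        paths.append(np.asarray(path))
    return paths


def _spell(U: np.ndarray, path: np.ndarray, k: int) -> str:
    first = int(U[path[0]])
    bases = [_DEC[(first >> (2 * (k - 1 - j))) & 3] for j in range(k)]
    tail = (U[path[1:]] & 3).tolist()
    bases.extend(_DEC[b] for b in tail)
    return "".join(bases)


def _dead_end_degrees(U: np.ndarray, path: np.ndarray, k: int) -> tuple[int, int]:
    mask = (np.int64(1) << (2 * (k - 1))) - 1
    first, last = int(U[path[0]]), int(U[path[-1]])
    indeg = sum(
        1
        for b in range(4)
        if np.searchsorted(U, (first >> 2) + (b << (2 * (k - 1)))) < U.size
        and U[np.searchsorted(U, (first >> 2) + (b << (2 * (k - 1))))]
        == (first >> 2) + (b << (2 * (k - 1)))
    )
    outdeg = sum(
        1
        for b in range(4)
        if np.searchsorted(U, ((last & mask) * 4) + b) < U.size
        and U[np.searchsorted(U, ((last & mask) * 4) + b)] == ((last & mask) * 4) + b
    )
    return indeg, outdeg


def assemble_builtin(sequences: list[str], k: int = 31) -> list[str]:
    """Assemble raw sequences into canonical unitig contigs.

    Tips (dead-end unitigs) shorter than 2k are removed once and the graph
    recompressed; contigs of at least 2k bases are emitted, each the
    lexicographically smaller of the unitig and its reverse complement,
    ordered by descending length then sequence.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be an odd integer >= 3")
    vals = _kmer_values(sequences, k)
    if vals.size == 0:
        return []
    U = np.unique(vals)

    for _round in range(2):
        paths = _unitigs(U, k)
        drop = np.zeros(U.size, dtype=bool)
        any_tip = False
        for path in paths:
            length = k + len(path) - 1
            if length >= 2 * k:
                continue
            indeg, outdeg = _dead_end_degrees(U, path, k)
            if indeg == 0 or outdeg == 0:  # a tip: dead end at either side
                drop[path] = True
                any_tip = True
        if not any_tip:
            break
        U = U[~drop]
        if U.size == 0:
            return []

    paths = _unitigs(U, k)
    contigs = set()
    for path in paths:
        seq = _spell(U, path, k)
        if len(seq) < 2 * k:
            continue
        contigs.add(min(seq, reverse_complement(seq)))
    return sorted(contigs, key=lambda s: (-len(s), s))


# ---------------------------------------------------------------------------


def assemble_haplotype(
    reads: list[BarcodedRead],
    mode: Literal["external", "builtin"] = "builtin",
    k: int = 31,
    haplotype: int = 1,
    block_id: int = 1,
    external: Optional[ExternalAssemblerConfig] = None,
    workdir: str | Path | None = None,
) -> list[Contig]:
    """Assemble one haplotype's reads into contigs.

    Builtin mode needs no external binary and is deterministic for fixed
    input and k. External mode writes the reads as a FASTQ pair, invokes
    the configured assembler and parses its contig FASTA. An empty read
    set, or a read set yielding no contig, returns an empty list (the
    region is reported uncalled for this haplotype).
    """
    if not reads:
        return []
    if mode == "builtin":
        if any(len(r.sequence) <= k for r in reads if r.sequence):
            pass  # short reads simply contribute no k-mers
        seqs = sorted(r.sequence for r in reads if len(r.sequence) >= k)
        raw = assemble_builtin(seqs, k=k)
        return [
            Contig(
                name=f"hp{haplotype}_block{block_id}_ctg{i}",
                haplotype=haplotype,
                block_id=block_id,
                sequence=s,
                source="builtin",
            )
            for i, s in enumerate(raw, start=1)
        ]
    if mode != "external":
        raise ValueError(f"unknown assembly mode {mode!r}")

    cfg = external or ExternalAssemblerConfig()
    exe = cfg.command.split()[0]
    if shutil.which(exe) is None:
        raise AssemblerError(
            f"external assembler executable {exe!r} not found on PATH; "
            "install it or run with mode='builtin'"
        )
    workdir = Path(workdir or ".")
    workdir.mkdir(parents=True, exist_ok=True)
    r1 = workdir / f"hp{haplotype}_b{block_id}_R1.fastq"
    r2 = workdir / f"hp{haplotype}_b{block_id}_R2.fastq"
    outdir = workdir / f"hp{haplotype}_b{block_id}_asm"
    write_read_pairs(reads, r1, r2, workdir / f"hp{haplotype}_b{block_id}_single.fastq")
    cmd = cfg.command.format(r1=r1, r2=r2, outdir=outdir)
    try:
        subprocess.run(cmd.split(), check=True, timeout=cfg.timeout_s, capture_output=True)
    except subprocess.CalledProcessError as exc:
        raise AssemblerError(
            f"external assembler failed (exit {exc.returncode}): {cmd}"
        ) from exc
    fasta = Path(cfg.contig_path.format(outdir=outdir))
    if not fasta.exists():
        raise AssemblerError(f"assembler produced no contig FASTA at {fasta}")
    contigs = []
    name, seq = None, []
    entries: list[tuple[str, str]] = []
    with open(fasta) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None and seq:
                    entries.append((name, "".join(seq)))
                name, seq = line[1:].split()[0], []
            else:
                seq.append(line.upper())
        if name is not None and seq:
            entries.append((name, "".join(seq)))
    for i, (_orig, s) in enumerate(entries, start=1):
        contigs.append(
            Contig(
                name=f"hp{haplotype}_block{block_id}_ctg{i}",
                haplotype=haplotype,
                block_id=block_id,
                sequence=s,
                source="external",
            )
        )
    return contigs


def contig_n50(contigs: list[Contig]) -> int:
    """N50 of contig lengths; 0 for an empty set."""
    lens = sorted((len(c) for c in contigs), reverse=True)
    if not lens:
        return 0
    half = sum(lens) / 2
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= half:
            return ln
    return lens[-1]
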