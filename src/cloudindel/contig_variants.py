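"""Contig-to-reference comparison and variant calling.

Assembled haplotype contigs are aligned back to the reference window;
the alignment difference string is walked to extract SNPs, insertions and
deletions; within-haplotype duplicates from overlapping contigs are
chained away; the two haplotype call sets are merged and genotyped
(shared -> 1|1, only haplotype 1 -> 1|0, only haplotype 2 -> 0|1); and
contig-derived SNPs are cross-checked against the input small-variant
calls, which are near-perfect for SNPs.

The builtin aligner is an anchor-chaining aligner in the style of the
assembly-to-reference mappers: k-mers unique in both contig and window
become anchors, colinearly chained runs of anchors become match blocks,
and the short unanchored segments between blocks are resolved by common
prefix/suffix trimming into mismatch runs and single clean gaps. On
assembly-quality contigs this recovers each indel as one contiguous gap
operation (a unit-cost edit-distance path would shred a large gap into
dozens of runs via chance matches). The external mode shells out to
minimap2 with a cs tag.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import edlib

from .assembly import Contig, reverse_complement
from .linked_io import (
    OP_DEL,
    OP_INS,
    OP_MATCH,
    OP_MISMATCH,
    AlnOp,
    ContigAlignment,
    HetSNP,
    Region,
    parse_contig_alignments,
)

VariantType = Literal["SNP", "INS", "DEL"]


@dataclass
class RawVariant:
    """A variant extracted from one haplotype contig, VCF-style anchored."""

    chrom: str
    pos: int  # 0-based anchor base
    type: VariantType
    ref_seq: str
    alt_seq: str
    size: int
    contig_name: str
    haplotype: int
    block_id: int
    contig_len: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("variant size must be >= 1")
        if self.type == "DEL" and (
            len(self.ref_seq) != self.size + 1 or len(self.alt_seq) != 1
        ):
            raise ValueError("DEL must be anchored: ref = anchor+deleted, alt = anchor")
        if self.type == "INS" and (
            len(self.alt_seq) != self.size + 1 or len(self.ref_seq) != 1
        ):
            raise ValueError("INS must be anchored: alt = anchor+inserted, ref = anchor")

    @property
    def span(self) -> tuple[int, int]:
        """Reference footprint, 0-based half-open."""
        if self.type == "DEL":
            return (self.pos + 1, self.pos + 1 + self.size)
        return (self.pos, self.pos + 1)


@dataclass
class GenotypedVariant:
    chrom: str
    pos: int
    type: VariantType
    ref_seq: str
    alt_seq: str
    size: int
    genotype: str  # "1|0", "0|1" or "1|1"
    block_id: int
    supporting_contigs: list[str] = field(default_factory=list)
    filter: Optional[str] = None
    contig_len: int = 0

    @property
    def span(self) -> tuple[int, int]:
        if self.type == "DEL":
            return (self.pos + 1, self.pos + 1 + self.size)
        return (self.pos, self.pos + 1)

    @property
    def is_het(self) -> bool:
        return self.genotype in ("1|0", "0|1")


@dataclass
class ChainConfig:
    """Intra-caller deduplication thresholds.

    Deliberately stricter (0.7) than the 0.1 similarity used for
    benchmark matching: chaining collapses redundant calls from
    overlapping contigs, it is not a tolerant benchmark comparison.
    """

    max_dist: int = 500
    min_size_sim: float = 0.7
    min_seq_sim: float = 0.7

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        for r in (self.min_size_sim, self.min_seq_sim):
            if not 0 <= r <= 1:
                raise ValueError("similarity ratios must lie in [0, 1]")


def sequence_similarity(a: str, b: str) -> float:
    """Normalized edit similarity: 1 - editdist / max(len)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def size_similarity(s1: int, s2: int) -> float:
    return min(s1, s2) / max(s1, s2)


def reciprocal_overlap(span1: tuple[int, int], span2: tuple[int, int]) -> float:
    ov = min(span1[1], span2[1]) - max(span1[0], span2[0])
    if ov <= 0:
        return 0.0
    return min(ov / (span1[1] - span1[0]), ov / (span2[1] - span2[0]))


# ---------------------------------------------------------------------------
# alignment


_ANCHOR_K = 21


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _anchor_runs(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal runs of k-mers unique in both sequences on one diagonal.

    Returns (qpos, tpos, length) match blocks, length >= k.
    """
    tpos = _unique_kmer_positions(target, k)
    anchors = []
    qseen: dict[str, int] = {}
    qdup: set[str] = set()
    for i in range(len(query) - k + 1):
        km = query[i : i + k]
        if km in qdup:
            continue
        if km in qseen:
            qdup.add(km)
            qseen[km] = -1
        else:
            qseen[km] = i
    for km, qi in qseen.items():
        if qi >= 0 and km in tpos:
            anchors.append((qi, tpos[km]))
    anchors.sort()
    runs: list[tuple[int, int, int]] = []
    for q, t in anchors:
        if runs and runs[-1][0] + runs[-1][2] - k + 1 == q and runs[-1][1] + runs[-1][2] - k + 1 == t:
            qs, ts, ln = runs[-1]
            runs[-1] = (qs, ts, ln + 1)
        else:
            runs.append((q, t, k))
    return runs


def _chain_runs(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best colinear non-overlapping chain of match runs (max total length)."""
    if not runs:
        return []
    runs = sorted(runs)
    n = len(runs)
    score = [0.0] * n
    prev = [-1] * n
    for i, (qi, ti, li) in enumerate(runs):
        score[i] = float(li)
        for j in range(i):
            qj, tj, lj = runs[j]
            # strict progress on both sequences; head overlap (chance base
            # matches at a gap junction) is tolerated and trimmed later
            ov = max(qj + lj - qi, tj + lj - ti, 0)
            if qi > qj and ti > tj and ov < li and ov < lj:
                gap = abs((qi - (qj + lj)) - (ti - (tj + lj)))
                cand = score[j] + (li - ov) - 0.01 * gap
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(runs[best])
        best = prev[best]
    return chain[::-1]


def _segment_ops(qseg: str, tseg: str) -> list[AlnOp]:
    """Difference ops for one short unanchored segment.

    Common prefix and suffix are trimmed to matches; the remainder becomes
    a mismatch run (equal lengths), a single clean gap (one side empty),
    or a deletion-plus-insertion block (both sides non-empty, e.g. a
    complex substitution)."""
    p = 0
    while p < min(len(qseg), len(tseg)) and qseg[p] == tseg[p]:
        p += 1
    s = 0
    while (
        s < min(len(qseg), len(tseg)) - p
        and qseg[len(qseg) - 1 - s] == tseg[len(tseg) - 1 - s]
    ):
        s += 1
    ops: list[AlnOp] = []
    if p:
        ops.append(AlnOp(OP_MATCH, p))
    qr = qseg[p : len(qseg) - s]
    tr = tseg[p : len(tseg) - s]
    if qr and tr and len(qr) == len(tr):
        for qb, tb in zip(qr, tr):
            if qb == tb:
                if ops and ops[-1].op == OP_MATCH:
                    ops[-1] = AlnOp(OP_MATCH, ops[-1].length + 1)
                else:
                    ops.append(AlnOp(OP_MATCH, 1))
            else:
                ops.append(AlnOp(OP_MISMATCH, 1, qb))
    else:
        if tr:
            ops.append(AlnOp(OP_DEL, len(tr), tr))
        if qr:
            ops.append(AlnOp(OP_INS, len(qr), qr))
    if s:
        ops.append(AlnOp(OP_MATCH, s))
    return ops


def _merge_ops(ops: list[AlnOp]) -> list[AlnOp]:
    merged: list[AlnOp] = []
    for o in ops:
        if o.length == 0:
            continue
        if merged and merged[-1].op == o.op and o.op != OP_MISMATCH:
            prev = merged.pop()
            merged.append(AlnOp(o.op, prev.length + o.length, prev.seq + o.seq))
        else:
            merged.append(o)
    return merged


def _align_one(query: str, target: str, k: int) -> Optional[tuple[int, list[AlnOp], int]]:
    """Anchor-chain ``query`` onto ``target``.

    Returns (target_start, ops, matched_bases) or None if no anchor.
    Query sequence hanging off the outermost anchors is clipped, matching
    the semantics of a local contig placement.
    """
    chain = _chain_runs(_anchor_runs(query, target, k))
    if not chain:
        return None
    # trim head overlaps between consecutive runs (same amount off query
    # and target keeps the diagonal)
    trimmed = [chain[0]]
    for q, t, l in chain[1:]:
        pq, pt, pl = trimmed[-1]
        d = max(pq + pl - q, pt + pl - t, 0)
        if d >= l:
            continue
        trimmed.append((q + d, t + d, l - d))
    chain = trimmed
    # extend the outer anchors by direct base comparison
    q0, t0, l0 = chain[0]
    while q0 > 0 and t0 > 0 and query[q0 - 1] == target[t0 - 1]:
        q0, t0, l0 = q0 - 1, t0 - 1, l0 + 1
    chain[0] = (q0, t0, l0)
    qn, tn, ln = chain[-1]
    while (
        qn + ln < len(query)
        and tn + ln < len(target)
        and query[qn + ln] == target[tn + ln]
    ):
        ln += 1
    chain[-1] = (qn, tn, ln)

    ops: list[AlnOp] = []
    matched = 0
    for idx, (q, t, l) in enumerate(chain):
        if idx:
            pq, pt, pl = chain[idx - 1]
            ops.extend(_segment_ops(query[pq + pl : q], target[pt + pl : t]))
        ops.append(AlnOp(OP_MATCH, l))
        matched += l
    ops = _merge_ops(ops)
    # fill deletion sequences from the target
    filled: list[AlnOp] = []
    tp = chain[0][1]
    for o in ops:
        if o.op == OP_DEL and not o.seq:
            o = AlnOp(OP_DEL, o.length, target[tp : tp + o.length])
        filled.append(o)
        if o.op in (OP_MATCH, OP_MISMATCH, OP_DEL):
            tp += o.length
    return chain[0][1], filled, matched


def align_contigs(
    contigs: list[Contig],
    ref_window: str,
    region: Region,
    mode: Literal["external", "builtin"] = "builtin",
    minimap2_preset: str = "asm5",
    anchor_k: int = _ANCHOR_K,
) -> list[ContigAlignment]:
    """One best placement per contig on the reference window.

    Both strands are tried and the one with more anchored bases kept
    (tie: forward). Contigs that fail to align are dropped with a
    warning. External mode runs minimap2 with a cs tag; coordinates are
    lifted from window space back to ``region.chrom``.
    """
    if mode == "external":
        return _align_minimap2(contigs, ref_window, region, minimap2_preset)
    if mode != "builtin":
        raise ValueError(f"unknown alignment mode {mode!r}")

    out: list[ContigAlignment] = []
    for c in contigs:
        best = None
        for strand, seq in (("+", c.sequence), ("-", reverse_complement(c.sequence))):
            r = _align_one(seq, ref_window, anchor_k)
            if r is None:
                continue
            t_start, ops, matched = r
            if best is None or matched > best[0]:
                best = (matched, strand, t_start, ops)
        if best is None:
            warnings.warn(f"contig {c.name} did not align; dropped")
            continue
        _, strand, t_start, ops = best
        tspan = sum(o.length for o in ops if o.op in (OP_MATCH, OP_MISMATCH, OP_DEL))
        out.append(
            ContigAlignment(
                contig_name=c.name,
                contig_len=len(c),
                strand=strand,
                target_chrom=region.chrom,
                target_start=region.start + t_start,
                target_end=region.start + t_start + tspan,
                mapq=60,
                ops=ops,
            )
        )
    return out


def _align_minimap2(
    contigs: list[Contig], ref_window: str, region: Region, preset: str
) -> list[ContigAlignment]:
    if shutil.which("minimap2") is None:
        raise RuntimeError(
            "external aligner 'minimap2' not found on PATH; use mode='builtin'"
        )
    with tempfile.TemporaryDirectory() as td:
        ref = Path(td) / "window.fa"
        qry = Path(td) / "contigs.fa"
        ref.write_text(f">{region.chrom}\n{ref_window}\n")
        with open(qry, "w") as fh:
            for c in contigs:
                fh.write(f">{c.name}\n{c.sequence}\n")
        paf = Path(td) / "aln.paf"
        with open(paf, "w") as out:
            subprocess.run(
                ["minimap2", "-x", preset, "--cs", "-c", str(ref), str(qry)],
                stdout=out,
                stderr=subprocess.DEVNULL,
                check=True,
            )
        alns = parse_contig_alignments(paf)
    # keep the single best (most matched bases) alignment per contig, lift coords
    best: dict[str, ContigAlignment] = {}
    for a in alns:
        nmatch = sum(o.length for o in a.ops if o.op == OP_MATCH)
        prev = best.get(a.contig_name)
        if prev is None or nmatch > sum(
            o.length for o in prev.ops if o.op == OP_MATCH
        ):
            best[a.contig_name] = a
    out = []
    for c in contigs:
        a = best.get(c.name)
        if a is None:
            warnings.warn(f"contig {c.name} did not align (minimap2); dropped")
            continue
        a.target_start += region.start
        a.target_end += region.start
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# variant extraction


def _left_align(pos: int, seq: str, ref_window: str, wstart: int) -> tuple[int, str]:
    """Shift an indel (anchored at ``pos``, varying bases ``seq``) left
    while the base preceding it equals the last varying base."""
    while pos > wstart and ref_window[pos - wstart] == seq[-1]:
        seq = ref_window[pos - wstart] + seq[:-1]
        pos -= 1
    return pos, seq


def extract_variants(
    aln: ContigAlignment,
    ref_window: str,
    window_start: int,
    haplotype: int,
    block_id: int,
    min_call_mapq: int = 5,
    min_aln_len: int = 10_000,
) -> list[RawVariant]:
    """Walk alignment ops and emit anchored, left-aligned variants.

    Alignments below ``min_call_mapq`` or spanning less than
    ``min_aln_len`` on the reference are ignored entirely (short or
    dubious placements breed artifact calls).
    """
    if aln.mapq < min_call_mapq:
        return []
    if aln.target_end - aln.target_start < min_aln_len:
        return []
    if aln.target_end - window_start > len(ref_window):
        raise ValueError("alignment extends past the reference window")

    out: list[RawVariant] = []
    rp = aln.target_start
    for o in aln.ops:
        if o.op == OP_MATCH:
            rp += o.length
        elif o.op == OP_MISMATCH:
            refb = ref_window[rp - window_start]
            if refb != o.seq:
                out.append(
                    RawVariant(
                        chrom=aln.target_chrom,
                        pos=rp,
                        type="SNP",
                        ref_seq=refb,
                        alt_seq=o.seq,
                        size=1,
                        contig_name=aln.contig_name,
                        haplotype=haplotype,
                        block_id=block_id,
                        contig_len=aln.contig_len,
                    )
                )
            rp += 1
        elif o.op == OP_INS:
            anchor = rp - 1
            if anchor >= window_start:
                pos, seq = _left_align(anchor, o.seq, ref_window, window_start)
                refb = ref_window[pos - window_start]
                out.append(
                    RawVariant(
                        chrom=aln.target_chrom,
                        pos=pos,
                        type="INS",
                        ref_seq=refb,
                        alt_seq=refb + seq,
                        size=o.length,
                        contig_name=aln.contig_name,
                        haplotype=haplotype,
                        block_id=block_id,
                        contig_len=aln.contig_len,
                    )
                )
        elif o.op == OP_DEL:
            anchor = rp - 1
            deleted = o.seq or ref_window[rp - window_start : rp - window_start + o.length]
            if anchor >= window_start:
                pos, seq = _left_align(anchor, deleted, ref_window, window_start)
                refb = ref_window[pos - window_start]
                out.append(
                    RawVariant(
                        chrom=aln.target_chrom,
                        pos=pos,
                        type="DEL",
                        ref_seq=refb + seq,
                        alt_seq=refb,
                        size=o.length,
                        contig_name=aln.contig_name,
                        haplotype=haplotype,
                        block_id=block_id,
                        contig_len=aln.contig_len,
                    )
                )
            rp += o.length
    out.sort(key=lambda v: (v.pos, v.type, v.size))
    return out


# ---------------------------------------------------------------------------
# chaining, merging, genotyping

AnyVariant = Union[RawVariant, GenotypedVariant]


def _chain_match(v1: AnyVariant, v2: AnyVariant, cfg: ChainConfig) -> bool:
    """Shared comparator for intra-haplotype chaining and cross-haplotype
    merging: same type, nearby, similar size, similar sequence."""
    if v1.type != v2.type or v1.chrom != v2.chrom:
        return False
    if abs(v1.pos - v2.pos) > cfg.max_dist:
        return False
    if size_similarity(v1.size, v2.size) < cfg.min_size_sim:
        return False
    if v1.type == "DEL":
        # deleted sequence equals the reference span; reciprocal span
        # overlap stands in for sequence similarity
        return reciprocal_overlap(v1.span, v2.span) >= cfg.min_size_sim
    return sequence_similarity(v1.alt_seq, v2.alt_seq) >= cfg.min_seq_sim


def _representative(group: list[AnyVariant]) -> AnyVariant:
    return max(group, key=lambda v: (v.contig_len, -v.pos, v.size))


def chain_variants(
    variants: Sequence[AnyVariant], cfg: ChainConfig | None = None
) -> list[AnyVariant]:
    """Collapse redundant calls from overlapping contigs.

    Union-find over all qualifying pairs (merging is transitive); each
    merged group is represented by the call from the longest supporting
    contig, ties broken leftmost then largest. Idempotent, and invariant
    to input order for fixed tie-break rules. Input must be sorted by
    position.
    """
    cfg = cfg or ChainConfig()
    variants = list(variants)
    if [v.pos for v in variants] != sorted(v.pos for v in variants):
        raise ValueError("chain_variants expects position-sorted input")
    n = len(variants)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if variants[j].pos - variants[i].pos > cfg.max_dist:
                break
            if _chain_match(variants[i], variants[j], cfg):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[AnyVariant]] = {}
    for i, v in enumerate(variants):
        groups.setdefault(find(i), []).append(v)
    out = []
    for group in groups.values():
        rep = _representative(group)
        if isinstance(rep, GenotypedVariant):
            contigs = sorted({c for g in group for c in g.supporting_contigs})
            rep = replace(rep, supporting_contigs=contigs)
        out.append(rep)
    out.sort(key=lambda v: (v.pos, v.type, v.size))
    return out


def merge_and_genotype(
    set1: list[RawVariant],
    set2: list[RawVariant],
    cfg: ChainConfig | None = None,
) -> list[GenotypedVariant]:
    """Merge the two haplotype call sets and genotype them.

    Variants matched across sets (same comparator as chaining, greedy
    one-to-one in ascending position distance) are emitted once as 1|1;
    unmatched haplotype-1 calls become 1|0 and unmatched haplotype-2
    calls 0|1. Every input variant contributes to exactly one output.
    """
    cfg = cfg or ChainConfig()
    chroms = {v.chrom for v in set1} | {v.chrom for v in set2}
    if len(chroms) > 1:
        raise ValueError(f"inputs span multiple chromosomes: {sorted(chroms)}")

    pairs = []
    for i, v1 in enumerate(set1):
        for j, v2 in enumerate(set2):
            if _chain_match(v1, v2, cfg):
                pairs.append((abs(v1.pos - v2.pos), v1.pos, v2.pos, i, j))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _d, _p1, _p2, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matches.append((i, j))

    def to_gt(v: RawVariant, genotype: str, supports: list[RawVariant]) -> GenotypedVariant:
        return GenotypedVariant(
            chrom=v.chrom,
            pos=v.pos,
            type=v.type,
            ref_seq=v.ref_seq,
            alt_seq=v.alt_seq,
            size=v.size,
            genotype=genotype,
            block_id=v.block_id,
            supporting_contigs=sorted({s.contig_name for s in supports}),
            contig_len=max(s.contig_len for s in supports),
        )

    out: list[GenotypedVariant] = []
    for i, j in matches:
        rep = _representative([set1[i], set2[j]])
        out.append(to_gt(rep, "1|1", [set1[i], set2[j]]))
    for i, v in enumerate(set1):
        if i not in used1:
            out.append(to_gt(v, "1|0", [v]))
    for j, v in enumerate(set2):
        if j not in used2:
            out.append(to_gt(v, "0|1", [v]))
    out.sort(key=lambda v: (v.pos, v.type, v.size))
    return out


def refine_snps(
    genotyped: list[GenotypedVariant], fb_snps: list[HetSNP]
) -> list[GenotypedVariant]:
    """Cross-check contig SNPs against the input small-variant calls.

    A contig SNP confirmed by the small-variant VCF (same position and
    alleles) keeps its contig phase and passes; a contig-only SNP is
    flagged FILTER=CONTIG_ONLY but retained. Indels pass through
    untouched.
    """
    known = {(s.pos, s.ref_allele, s.alt_allele) for s in fb_snps}
    out = []
    for v in genotyped:
        if v.type == "SNP" and (v.pos, v.ref_seq, v.alt_seq) not in known:
            out.append(replace(v, filter="CONTIG_ONLY"))
        else:
            out.append(v)
    return out


SIZE_BINS = ("SNP", "small_indel", "SV_50_1k", "SV_1k_10k", "SV_gt10k")


def classify_size(v: GenotypedVariant) -> str:
    """Size bin: SNP, small indel (<50bp), or SV bin [50,1k)/[1k,10k)/>=10k."""
    if v.type == "SNP":
        return "SNP"
    if v.size < 50:
        return "small_indel"
    if v.size < 1_000:
        return "SV_50_1k"
    if v.size < 10_000:
        return "SV_1k_10k"
    return "SV_gt10k"
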