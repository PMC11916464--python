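"""Benchmarking of SV call sets against a truth set.

Implements the matching scheme of the standard SV benchmarking tools:
a call matches a truth entry if it has the same type, starts within
``refdist`` bases, has size similarity at least ``pctsize``, sequence
similarity at least ``pctsim`` (insertions; deleted sequence equals the
reference span, so size similarity stands in for deletions) and
reciprocal overlap at least ``pctovl``. Matching is greedy one-to-one in
ascending start distance. Matched truth entries are true positives (TP,
and TP_GT when the genotype also agrees), unmatched truth entries false
negatives, unmatched calls false positives.

Only indel SVs (DEL/INS of at least 50 bp) are benchmarked. Genotype
agreement is phase-agnostic: 1|0 and 0|1 are the same unordered
heterozygous genotype, phase labels being arbitrary per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .contig_variants import (
    GenotypedVariant,
    reciprocal_overlap,
    sequence_similarity,
    size_similarity,
)

SV_MIN_SIZE = 50


@dataclass
class MatchConfig:
    """Thresholds in the benchmarking tool's notation: r, P, p, O."""

    refdist: int = 200
    pctsize: float = 0.1
    pctsim: float = 0.1
    pctovl: float = 0.0

    def __post_init__(self) -> None:
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        for r in (self.pctsize, self.pctsim, self.pctovl):
            if not 0 <= r <= 1:
                raise ValueError("ratio thresholds must lie in [0, 1]")


@dataclass
class SVMatchReport:
    TP: int
    TP_GT: int
    FP: int
    FN: int
    recall: float = field(init=False)
    precision: float = field(init=False)
    f1: float = field(init=False)
    gt_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.TP, self.TP_GT, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP_GT > self.TP:
            raise ValueError("TP_GT cannot exceed TP")
        self.recall = self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0
        self.precision = self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0
        pr = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / pr if pr else 0.0
        self.gt_accuracy = self.TP_GT / self.TP if self.TP else 0.0

    def as_percentages(self) -> dict[str, float]:
        """Rates on the percent scale, rounded to one decimal for display."""
        return {
            "Recall": round(100 * self.recall, 1),
            "Precision": round(100 * self.precision, 1),
            "F1": round(100 * self.f1, 1),
            "GT_accuracy": round(100 * self.gt_accuracy, 1),
        }

    def as_row(self) -> dict[str, float]:
        row = {"TP": self.TP, "TP_GT": self.TP_GT, "FP": self.FP, "FN": self.FN}
        row.update(self.as_percentages())
        return row


def _is_sv(v: GenotypedVariant) -> bool:
    return v.type in ("DEL", "INS") and v.size >= SV_MIN_SIZE


def _gt_equal(a: str, b: str) -> bool:
    return tuple(sorted(a.split("|"))) == tuple(sorted(b.split("|")))


def _candidate(call: GenotypedVariant, tru: GenotypedVariant, cfg: MatchConfig) -> bool:
    if call.type != tru.type or call.chrom != tru.chrom:
        return False
    if abs(call.pos - tru.pos) > cfg.refdist:
        return False
    if size_similarity(call.size, tru.size) < cfg.pctsize:
        return False
    if cfg.pctovl > 0 and reciprocal_overlap(call.span, tru.span) < cfg.pctovl:
        return False
    if call.type == "INS" and cfg.pctsim > 0:
        if sequence_similarity(call.alt_seq[1:], tru.alt_seq[1:]) < cfg.pctsim:
            return False
    return True


def match_calls(
    calls: list[GenotypedVariant],
    truth: list[GenotypedVariant],
    cfg: MatchConfig | None = None,
) -> tuple[list[tuple[GenotypedVariant, GenotypedVariant]], SVMatchReport]:
    """Match calls to truth and count TP/TP_GT/FP/FN.

    Both sets are first restricted to indel SVs (>= 50 bp DEL/INS).
    Returns the matched (call, truth) pairs and the count report.
    """
    cfg = cfg or MatchConfig()
    calls = [v for v in calls if _is_sv(v)]
    truth = [v for v in truth if _is_sv(v)]

    cand = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            if _candidate(c, t, cfg):
                cand.append((abs(c.pos - t.pos), c.pos, t.pos, i, j))
    cand.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[GenotypedVariant, GenotypedVariant]] = []
    tp_gt = 0
    for _d, _pc, _pt, i, j in cand:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        pairs.append((calls[i], truth[j]))
        if _gt_equal(calls[i].genotype, truth[j].genotype):
            tp_gt += 1
    tp = len(pairs)
    report = SVMatchReport(
        TP=tp, TP_GT=tp_gt, FP=len(calls) - tp, FN=len(truth) - tp
    )
    return pairs, report


def compute_metrics(TP: int, TP_GT: int, FP: int, FN: int) -> SVMatchReport:
    """Recall, precision, F1 and genotype accuracy from raw counts."""
    return SVMatchReport(TP=TP, TP_GT=TP_GT, FP=FP, FN=FN)


def report_by_size_bin(
    calls: list[GenotypedVariant],
    truth: list[GenotypedVariant],
    cfg: MatchConfig | None = None,
) -> dict[str, SVMatchReport]:
    """Per-size-bin reports ({50bp-1kb, 1kb-10kb, >10kb, overall}), each
    bin stratified by the truth entry's size (calls binned by their own
    size for the FP side)."""
    from .contig_variants import classify_size

    bins = {"SV_50_1k": "50bp-1kb", "SV_1k_10k": "1kb-10kb", "SV_gt10k": ">10kb"}
    out: dict[str, SVMatchReport] = {}
    for bin_key, label in bins.items():
        c_bin = [v for v in calls if classify_size(v) == bin_key]
        t_bin = [v for v in truth if classify_size(v) == bin_key]
        _, rep = match_calls(c_bin, t_bin, cfg)
        out[label] = rep
    _, out["overall"] = match_calls(calls, truth, cfg)
    return out
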