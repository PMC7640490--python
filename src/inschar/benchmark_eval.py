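"""Scoring of predicted insertion callsets against a simulated truth set.

Two recall definitions are computed.  *Insertion-site-only* recall counts a
truth insertion as recovered when a retained call lies within a fixed
margin (default 10 bp) of the true site.  *Sequence-resolved* recall
additionally requires the predicted inserted sequence to match the truth:
end-to-end identity of at least 90% and a size within +/-10% of the
simulated one.  False positives are reported as an absolute count of
retained calls matching no truth insertion (precision/FDR depend on the
true-positive count and are deliberately not reported).

Matching is greedy one-to-one by increasing site distance (ties broken by
leftmost call), so one call never validates two truth insertions and the
result is stable under permutation of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .alignment_engine import GenomeIndex, global_identity
from .insertion_simulator import TruthSet
from .variant_io import Callset, InsertionRecord


@dataclass
class MatchConfig:
    site_margin: int = 10
    min_identity: float = 0.90
    size_tolerance: float = 0.10
    min_call_size: int = 50
    pass_only: bool = True
    # INFO keys from which a symbolic call's duplicated copy is resolved
    dup_chrom_key: str = "DUP_CHROM"
    dup_start_key: str = "DUP_START"   # 1-based inclusive
    dup_end_key: str = "DUP_END"       # 1-based inclusive

    def __post_init__(self):
        if self.site_margin < 0:
            raise ValueError("site_margin must be >= 0")
        if not 0 <= self.size_tolerance < 1:
            raise ValueError("size_tolerance must be in [0, 1)")


@dataclass
class RecallReport:
    n_truth: int
    n_calls_considered: int
    n_tp_site: int
    n_tp_seq: int
    n_fp: int
    recall_site: float
    recall_seq: float
    pass_only: bool
    tp_site_truth_indices: Set[int] = field(default_factory=set)
    tp_seq_truth_indices: Set[int] = field(default_factory=set)


def filter_calls(calls: Callset, cfg: MatchConfig) -> Callset:
    """Retain PASS calls larger than the minimum size.

    Symbolic (unresolved) calls are retained for later sequence resolution;
    their size is unknown at this point so only the PASS criterion applies.
    """
    kept: List[InsertionRecord] = []
    for r in calls.records:
        if cfg.pass_only and r.filter_field not in ("PASS", "."):
            continue
        if r.resolved and r.size <= cfg.min_call_size:
            continue
        kept.append(r)
    return Callset(kept, convention=calls.convention, source_label=calls.source_label)


def resolve_symbolic(call: InsertionRecord, genome: GenomeIndex,
                     cfg: MatchConfig = MatchConfig()) -> InsertionRecord:
    """Fill a symbolic call's inserted sequence from annotated copy coordinates.

    Dispersed-duplication style calls may report the duplicated copy's
    location instead of the sequence; when the configured INFO keys are
    present and valid the sequence is extracted from the reference so the
    call can be evaluated like any sequence-resolved one.  Otherwise the
    call is returned unchanged (eligible for site-only matching).
    """
    if call.resolved:
        return call
    try:
        chrom = str(call.info_tags[cfg.dup_chrom_key])
        start = int(call.info_tags[cfg.dup_start_key])
        end = int(call.info_tags[cfg.dup_end_key])
    except (KeyError, TypeError, ValueError):
        return call
    if chrom not in genome or not 1 <= start <= end <= genome.length(chrom):
        return call
    seq = genome.fetch(chrom, start - 1, end)
    return replace(call, inserted_seq=seq, resolved=True)


def _sequence_match(call: InsertionRecord, truth_seq: str,
                    cfg: MatchConfig) -> bool:
    if not call.resolved or not call.inserted_seq:
        return False
    if abs(call.size - len(truth_seq)) > cfg.size_tolerance * len(truth_seq):
        return False
    return global_identity(call.inserted_seq, truth_seq) >= cfg.min_identity


def match_and_score(truth: TruthSet, calls: Callset,
                    cfg: MatchConfig = MatchConfig(),
                    genome: Optional[GenomeIndex] = None) -> RecallReport:
    """Greedy one-to-one matching of calls to truth insertions.

    Candidate pairs within ``site_margin`` are taken by increasing distance
    (leftmost call on ties); each truth and each call is used at most once.
    A matched pair is a site TP; it is additionally a sequence TP when the
    call's (possibly symbolically resolved) sequence passes the identity and
    size checks.  Retained calls matching no truth count as FP.
    """
    retained = filter_calls(calls, cfg)
    if genome is not None:
        retained = Callset([resolve_symbolic(r, genome, cfg) for r in retained],
                           convention=retained.convention,
                           source_label=retained.source_label)
    truth_chroms = {t.chrom for t in truth.records}
    call_chroms = {c.chrom for c in retained.records}
    if truth.records and retained.records and not (truth_chroms & call_chroms):
        raise ValueError(
            f"no chromosome shared between truth {sorted(truth_chroms)} "
            f"and calls {sorted(call_chroms)}")

    pairs: List[Tuple[int, int, int, int]] = []  # (distance, call_pos, ti, ci)
    for ti, t in enumerate(truth.records):
        for ci, c in enumerate(retained.records):
            if c.chrom != t.chrom:
                continue
            d = abs(c.pos - t.pos)
            if d <= cfg.site_margin:
                pairs.append((d, c.pos, ti, ci))
    pairs.sort()
    used_truth: Set[int] = set()
    used_call: Set[int] = set()
    tp_site: Set[int] = set()
    tp_seq: Set[int] = set()
    for d, _, ti, ci in pairs:
        if ti in used_truth or ci in used_call:
            continue
        used_truth.add(ti)
        used_call.add(ci)
        tp_site.add(ti)
        if _sequence_match(retained.records[ci], truth.records[ti].inserted_seq, cfg):
            tp_seq.add(ti)
    n_truth = len(truth.records)
    n_fp = len(retained.records) - len(used_call)
    return RecallReport(
        n_truth=n_truth,
        n_calls_considered=len(retained.records),
        n_tp_site=len(tp_site),
        n_tp_seq=len(tp_seq),
        n_fp=n_fp,
        recall_site=len(tp_site) / n_truth if n_truth else 0.0,
        recall_seq=len(tp_seq) / n_truth if n_truth else 0.0,
        pass_only=cfg.pass_only,
        tp_site_truth_indices=tp_site,
        tp_seq_truth_indices=tp_seq,
    )


@dataclass
class CombinationReport:
    per_tool: Dict[str, RecallReport]
    union_count: int
    intersection_count: int
    k_of_n: Dict[int, int]  # truth insertions validated by exactly k tools

    @property
    def union_recall(self) -> float:
        n = next(iter(self.per_tool.values())).n_truth
        return self.union_count / n if n else 0.0

    @property
    def intersection_recall(self) -> float:
        n = next(iter(self.per_tool.values())).n_truth
        return self.intersection_count / n if n else 0.0


def combine_callsets(callsets: Dict[str, Callset], truth: TruthSet,
                     cfg: MatchConfig = MatchConfig(),
                     genome: Optional[GenomeIndex] = None) -> CombinationReport:
    """Score several callers independently and combine their site TP sets.

    Reports the union and intersection of truth insertions recovered by the
    tools and the count validated by exactly k of them.
    """
    if len(callsets) < 2:
        raise ValueError("combining requires at least two callsets")
    per_tool = {name: match_and_score(truth, cs, cfg, genome)
                for name, cs in callsets.items()}
    tp_sets = [r.tp_site_truth_indices for r in per_tool.values()]
    union = set().union(*tp_sets)
    inter = set.intersection(*tp_sets)
    k_of_n: Dict[int, int] = {}
    for ti in union:
        k = sum(1 for s in tp_sets if ti in s)
        k_of_n[k] = k_of_n.get(k, 0) + 1
    return CombinationReport(per_tool, len(union), len(inter), k_of_n)
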