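"""Callset-level summaries across the four characterization axes.

Combines the classifier, junctional-homology detector, genomic-context
labeller and discovery-technology tags into per-callset feature tables:
counts and fractions by insertion type, size class, repeat context and
junctional-homology class, optionally stratified by discovery technology —
plus cross-callset comparisons (pairwise shared sites and multi-way common
sites within a distance window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment_engine import GenomeIndex
from .genomic_context import AnnotationTrackSet, classify_site
from .insertion_classifier import ClassifierConfig, classify_callset
from .junctional_homology import junctional_homology_size
from .variant_io import Callset, Technology, parse_discovery_technology

#: size-class bin edges in bp (right-open; last class unbounded)
SIZE_BINS = (50, 250, 500, 1000)
SIZE_LABELS = ("[50,250)", "[250,500)", "[500,1000)", ">=1000")
#: junctional-homology class bin edges in bp
HOMOLOGY_LABELS = ("<=10", "(10,50]", ">50")


def size_class(size: int, bins: Sequence[int] = SIZE_BINS,
               labels: Sequence[str] = SIZE_LABELS) -> str:
    for edge, label in zip(bins[1:], labels[:-1]):
        if size < edge:
            return label
    return labels[-1]


def homology_class(total: int) -> str:
    if total <= 10:
        return HOMOLOGY_LABELS[0]
    if total <= 50:
        return HOMOLOGY_LABELS[1]
    return HOMOLOGY_LABELS[2]


@dataclass
class FeatureSummary:
    """Per-record feature table plus per-axis count/fraction tables."""

    table: pd.DataFrame
    axes: Dict[str, pd.DataFrame]

    def counts(self, axis: str) -> pd.Series:
        return self.axes[axis]["count"]

    def fractions(self, axis: str) -> pd.Series:
        return self.axes[axis]["fraction"]


def _axis_table(values: pd.Series) -> pd.DataFrame:
    counts = values.value_counts()
    total = counts.sum()
    return pd.DataFrame({
        "count": counts,
        "fraction": counts / total if total else 0.0,
    })


def summarize_callset(cs: Callset,
                      genome: GenomeIndex,
                      tracks: AnnotationTrackSet,
                      me_library: Dict[str, str],
                      cfg: ClassifierConfig = ClassifierConfig()) -> FeatureSummary:
    """Characterize every record on all four axes.

    Every record lands in exactly one class per axis; the result is
    deterministic and independent of record order.
    """
    type_df = classify_callset(cs, genome, me_library, cfg)
    rows = []
    for r, (_, trow) in zip(cs.records, type_df.iterrows()):
        hom = junctional_homology_size(r, genome, cfg.min_identity)
        ctx = classify_site(r.chrom, r.zero_based_site, tracks)
        tech = parse_discovery_technology(r, cs.convention)
        rows.append({
            "record_id": r.record_id,
            "label": trow["label"],
            "size": r.size,
            "size_class": size_class(r.size),
            "repeat_context": ctx.repeat_context,
            "genic_context": ctx.genic_context,
            "homology_total": hom.total_size,
            "homology_class": homology_class(hom.total_size),
            "technology": tech.value,
        })
    table = pd.DataFrame(rows)
    axes = {}
    for axis in ("label", "size_class", "repeat_context", "genic_context",
                 "homology_class", "technology"):
        axes[axis] = _axis_table(table[axis]) if len(table) else pd.DataFrame(
            columns=["count", "fraction"])
    return FeatureSummary(table, axes)


def stratified_sr_recall(summary: FeatureSummary,
                         axis: str = "label") -> pd.DataFrame:
    """Fraction of each class discovered by short-read technology.

    Classes with zero members are reported with NaN (undefined), never 0.
    """
    t = summary.table
    if not len(t):
        return pd.DataFrame(columns=["n", "n_short_read", "sr_fraction"])
    grouped = t.groupby(axis)
    n = grouped.size()
    sr = grouped.apply(
        lambda g: (g["technology"] == Technology.short_read.value).sum(),
        include_groups=False)
    out = pd.DataFrame({"n": n, "n_short_read": sr})
    out["sr_fraction"] = np.where(out["n"] > 0,
                                  out["n_short_read"] / out["n"], np.nan)
    return out


def shared_insertions(a: Callset, b: Callset, window: int = 1000) -> int:
    """Count of insertion sites shared between two callsets.

    One-to-one nearest matching with strict distance < ``window``;
    symmetric in its arguments.
    """
    pairs: List[Tuple[int, int, int, int]] = []
    b_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for j, r in enumerate(b.records):
        b_by_chrom.setdefault(r.chrom, []).append((r.pos, j))
    for i, r in enumerate(a.records):
        for pos, j in b_by_chrom.get(r.chrom, ()):
            d = abs(r.pos - pos)
            if d < window:
                pairs.append((d, min(r.pos, pos), i, j))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    count = 0
    for d, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        count += 1
    return count


def multiway_common(callsets: Sequence[Callset], window: int = 1000) -> int:
    """Sites present in every callset, by single-linkage clustering.

    All sites are pooled and clustered per chromosome (link when consecutive
    sites are < ``window`` apart); a cluster counts when it contains at
    least one site from every callset.
    """
    if len(callsets) < 2:
        raise ValueError("multiway comparison requires at least two callsets")
    if any(len(cs) == 0 for cs in callsets):
        return 0
    sites: List[Tuple[str, int, int]] = []
    for k, cs in enumerate(callsets):
        for r in cs.records:
            sites.append((r.chrom, r.pos, k))
    sites.sort()
    count = 0
    members: set = set()
    prev_chrom: Optional[str] = None
    prev_pos = 0
    for chrom, pos, k in sites:
        if prev_chrom == chrom and pos - prev_pos < window:
            members.add(k)
        else:
            if len(members) == len(callsets):
                count += 1
            members = {k}
        prev_chrom, prev_pos = chrom, pos
    if len(members) == len(callsets):
        count += 1
    return count
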