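"""Genomic-context classification of insertion sites.

Each insertion site (the single anchor point) is labelled on two axes:
a repeat axis (simple repeat, SINE, LINE, other repeat, non-repeated) and a
genic axis (exonic, intronic, intergenic).  Annotation tracks come from a
RepeatMasker-style BED, a dedicated simple-repeat BED and a GTF of gene
models; intervals are held in per-chromosome interval trees so point
queries are logarithmic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from intervaltree import IntervalTree

REPEAT_CLASSES = ("simple_repeat", "sine", "line", "other_repeat")
REPEAT_PRIORITY = ("simple_repeat", "sine", "line", "other_repeat")
GENIC_PRIORITY = ("exon", "intron")


@dataclass(frozen=True)
class ContextLabel:
    repeat_context: str  # simple_repeat | sine | line | other_repeat | non_repeated
    genic_context: str   # exonic | intronic | intergenic


class AnnotationTrackSet:
    """Interval tracks (0-based half-open) with point-query support."""

    TRACKS = ("simple_repeats", "sines", "lines", "other_repeats", "exons", "introns")

    def __init__(self, chrom_lengths: Optional[Dict[str, int]] = None):
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths or {})
        self._trees: Dict[str, Dict[str, IntervalTree]] = {
            t: {} for t in self.TRACKS}

    def add(self, track: str, chrom: str, start: int, end: int) -> None:
        if track not in self._trees:
            raise KeyError(f"unknown track {track!r}")
        if end <= start:
            return
        self._trees[track].setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, track: str, chrom: str, pos: int) -> bool:
        tree = self._trees[track].get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def intervals(self, track: str, chrom: Optional[str] = None) -> List[Tuple[str, int, int]]:
        out = []
        for c, tree in self._trees[track].items():
            if chrom is not None and c != chrom:
                continue
            for iv in sorted(tree):
                out.append((c, iv.begin, iv.end))
        return out

    def merged_length(self, track: str) -> int:
        total = 0
        for tree in self._trees[track].values():
            t = tree.copy()
            t.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in t)
        return total


def _route_repeat_class(raw: str, warnings: List[str]) -> str:
    cls = raw.split("/")[0].strip()
    low = cls.lower()
    if low.startswith("sine"):
        return "sines"
    if low.startswith("line"):
        return "lines"
    if low in ("simple_repeat", "simple", "low_complexity", "satellite",
               "ltr", "dna", "rc", "retroposon", "srna", "trna", "rrna",
               "scrna", "snrna", "unknown", "other"):
        if low == "simple_repeat":
            return "simple_repeats"
        return "other_repeats"
    warnings.append(f"unknown repeat class {raw!r} routed to other_repeat")
    return "other_repeats"


def _read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                     dtype={0: str, 3: str})
    return df


_GTF_COLS = ["chrom", "source", "feature", "start", "end",
             "score", "strand", "frame", "attributes"]


def _read_gtf(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#",
                     names=_GTF_COLS, dtype={"chrom": str})
    df["gene_id"] = df["attributes"].str.extract(r'gene_id "?([^";]+)"?')
    return df


def load_tracks(rmsk_bed, simple_repeat_bed, gene_gtf,
                chrom_lengths: Optional[Dict[str, int]] = None) -> AnnotationTrackSet:
    """Build an :class:`AnnotationTrackSet` from BED/GTF annotation files.

    The RepeatMasker BED's name column is routed by repeat class
    (SINE*/LINE*/other); simple repeats come from the dedicated BED; exons
    come from GTF exon features and introns are derived as gene extent minus
    exons.  Unknown repeat classes fall into other_repeat with a warning.
    """
    tracks = AnnotationTrackSet(chrom_lengths)
    warnings: List[str] = []
    for _, row in _read_bed(rmsk_bed).iterrows():
        track = _route_repeat_class(str(row["name"]), warnings)
        tracks.add(track, row["chrom"], int(row["start"]), int(row["end"]))
    for _, row in _read_bed(simple_repeat_bed).iterrows():
        tracks.add("simple_repeats", row["chrom"], int(row["start"]), int(row["end"]))
    gtf = _read_gtf(gene_gtf)
    exons = gtf[gtf["feature"] == "exon"]
    for _, row in exons.iterrows():
        tracks.add("exons", row["chrom"], int(row["start"]) - 1, int(row["end"]))
    # introns: per-gene extent minus its exons
    for (chrom, gene_id), grp in exons.groupby(["chrom", "gene_id"], sort=False):
        genes = gtf[(gtf["feature"] == "gene") & (gtf["gene_id"] == gene_id)]
        if len(genes):
            g0 = int(genes["start"].min()) - 1
            g1 = int(genes["end"].max())
        else:
            g0 = int(grp["start"].min()) - 1
            g1 = int(grp["end"].max())
        covered = sorted((int(s) - 1, int(e)) for s, e in zip(grp["start"], grp["end"]))
        cursor = g0
        for s, e in covered:
            if s > cursor:
                tracks.add("introns", chrom, cursor, s)
            cursor = max(cursor, e)
        if g1 > cursor:
            tracks.add("introns", chrom, cursor, g1)
    tracks.load_warnings = warnings  # type: ignore[attr-defined]
    return tracks


_REPEAT_TRACK_OF = {"simple_repeat": "simple_repeats", "sine": "sines",
                    "line": "lines", "other_repeat": "other_repeats"}


def classify_site(chrom: str, pos: int, tracks: AnnotationTrackSet) -> ContextLabel:
    """Label one insertion point; overlaps resolve by fixed priority.

    Repeat axis: simple_repeat > sine > line > other_repeat > non_repeated.
    Genic axis: exonic > intronic > intergenic.
    """
    if tracks.chrom_lengths and chrom not in tracks.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    repeat = "non_repeated"
    for label in REPEAT_PRIORITY:
        if tracks.overlaps(_REPEAT_TRACK_OF[label], chrom, pos):
            repeat = label
            break
    genic = "intergenic"
    if tracks.overlaps("exons", chrom, pos):
        genic = "exonic"
    elif tracks.overlaps("introns", chrom, pos):
        genic = "intronic"
    return ContextLabel(repeat, genic)


def genome_fraction(tracks: AnnotationTrackSet, track: str,
                    total_length: Optional[int] = None) -> float:
    """Merged-interval length of one track divided by total genome length."""
    if total_length is None:
        total_length = sum(tracks.chrom_lengths.values())
    if not total_length:
        raise ValueError("genome length unknown: provide total_length or chrom_lengths")
    return tracks.merged_length(track) / total_length
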