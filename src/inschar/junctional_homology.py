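"""Junctional homology measurement for insertion variants.

A junctional homology is a sequence present both at one side of the
insertion site and at the corresponding extremity of the inserted sequence:
the left flank is compared with the *end* of the insertion, the right flank
with its *beginning*.  When both sides carry homology the total is the sum
of the two sizes after removing any overlap of the two segments on the
inserted sequence.

Two detection tiers are used.  Small homologies (up to 10 bp per side) are
found by a strict base-by-base scan outward from the insertion site until
the first mismatch.  When a side saturates the 10 bp cap, an
alignment-based search takes over: local alignments between the flanking
windows (same length as the insertion, capped) and the inserted sequence
are filtered to those landing within 10 bp of the insertion site and within
10 bp of the relevant extremity of the inserted sequence; among candidates
the one closest to the extremities wins (larger homology on ties).  The
reported total is the maximum of the two tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .alignment_engine import GenomeIndex, LocalAlignment, local_align
from .variant_io import InsertionRecord

SCAN_CAP = 10          # strict-scan cap per side (bp)
MAX_EXTREMITY_DIST = 10  # alignment-tier distance tolerance (bp)
MAX_WINDOW = 10_000    # flank window cap for very large insertions (bp)
MIN_ALIGN_QUERY = 20   # below this the alignment tier is not attempted


@dataclass(frozen=True)
class HomologyResult:
    """Per-insertion homology sizes; ``total_size`` is overlap-corrected."""

    left_size: int
    right_size: int
    total_size: int
    method: str  # strict_scan | alignment | none
    at_contig_edge: bool = False


def small_homology(left_flank_10: str, right_flank_10: str, ins: str) -> Tuple[int, int]:
    """Strict junction scan: identical bases outward from the site until mismatch.

    Left side compares the flank suffix with the insertion suffix; right
    side compares the flank prefix with the insertion prefix.  Capped at
    10 bp and at the insertion length; ``N`` never matches.
    """
    ins = ins.upper()
    left_flank_10 = left_flank_10.upper()
    right_flank_10 = right_flank_10.upper()
    left = 0
    cap_l = min(SCAN_CAP, len(ins), len(left_flank_10))
    for k in range(1, cap_l + 1):
        a, b = left_flank_10[-k], ins[-k]
        if a != b or a == "N":
            break
        left = k
    right = 0
    cap_r = min(SCAN_CAP, len(ins), len(right_flank_10))
    for k in range(cap_r):
        a, b = right_flank_10[k], ins[k]
        if a != b or a == "N":
            break
        right = k + 1
    return left, right


def _overlap_corrected_total(left_iv: Optional[Tuple[int, int]],
                             right_iv: Optional[Tuple[int, int]]) -> int:
    left = left_iv[1] - left_iv[0] if left_iv else 0
    right = right_iv[1] - right_iv[0] if right_iv else 0
    overlap = 0
    if left_iv and right_iv:
        overlap = max(0, min(left_iv[1], right_iv[1]) - max(left_iv[0], right_iv[0]))
    return left + right - overlap


def _right_candidate(ins: str, window: str,
                     min_identity: float) -> Optional[Tuple[int, int]]:
    """Best right-side homology as an interval on the inserted sequence."""
    if len(ins) < MIN_ALIGN_QUERY or len(window) < 1:
        return None
    cands = []
    for a in local_align(ins, window, min_identity=min_identity,
                         both_strands=False, min_matches=SCAN_CAP + 1):
        if a.query_start <= MAX_EXTREMITY_DIST and a.target_start <= MAX_EXTREMITY_DIST:
            dist = a.query_start + a.target_start
            cands.append((dist, -a.query_span, a))
    if not cands:
        return None
    a = min(cands)[2]
    return a.query_start, a.query_end


def _left_candidate(ins: str, window: str,
                    min_identity: float) -> Optional[Tuple[int, int]]:
    """Best left-side homology as an interval on the inserted sequence."""
    if len(ins) < MIN_ALIGN_QUERY or len(window) < 1:
        return None
    L, W = len(ins), len(window)
    cands = []
    for a in local_align(ins, window, min_identity=min_identity,
                         both_strands=False, min_matches=SCAN_CAP + 1):
        if (L - a.query_end) <= MAX_EXTREMITY_DIST and (W - a.target_end) <= MAX_EXTREMITY_DIST:
            dist = (L - a.query_end) + (W - a.target_end)
            cands.append((dist, -a.query_span, a))
    if not cands:
        return None
    a = min(cands)[2]
    return a.query_start, a.query_end


def large_homology(junction_windows: Tuple[str, str], ins: str,
                   min_identity: float = 0.90) -> HomologyResult:
    """Alignment-tier homology from (left_window, right_window) flanks.

    Windows are the reference sequences immediately left/right of the
    insertion site (ideally the insertion's own length, capped at 10 kb).
    When no candidate alignment satisfies the distance constraints, sizes
    fall back to the strict scan on the terminal 10 bp.
    """
    left_window, right_window = junction_windows
    ins = ins.upper()
    left_iv = _left_candidate(ins, left_window.upper(), min_identity)
    right_iv = _right_candidate(ins, right_window.upper(), min_identity)
    sl, sr = small_homology(left_window[-SCAN_CAP:], right_window[:SCAN_CAP], ins)
    if left_iv is None and sl > 0:
        left_iv = (len(ins) - sl, len(ins))
    if right_iv is None and sr > 0:
        right_iv = (0, sr)
    total = _overlap_corrected_total(left_iv, right_iv)
    left = left_iv[1] - left_iv[0] if left_iv else 0
    right = right_iv[1] - right_iv[0] if right_iv else 0
    method = "alignment" if total > 0 else "none"
    return HomologyResult(left, right, total, method)


def junctional_homology_size(r: InsertionRecord,
                             genome: GenomeIndex,
                             min_identity: float = 0.90) -> HomologyResult:
    """Two-tier homology for one insertion record against its reference flanks.

    The strict scan runs first; if either side saturates the 10 bp cap the
    alignment tier refines it and the larger of the two totals is reported.
    Insertions at a contig edge use whatever flank is available and are
    flagged.
    """
    if not r.resolved or not r.inserted_seq:
        raise ValueError("junctional homology requires a sequence-resolved record")
    site = r.zero_based_site
    chrom_len = genome.length(r.chrom)
    ins = r.inserted_seq
    at_edge = site < SCAN_CAP or site + SCAN_CAP > chrom_len
    left10 = genome.fetch(r.chrom, site - SCAN_CAP, site)
    right10 = genome.fetch(r.chrom, site, site + SCAN_CAP)
    sl, sr = small_homology(left10, right10, ins)
    strict_iv_l = (len(ins) - sl, len(ins)) if sl else None
    strict_iv_r = (0, sr) if sr else None
    strict_total = _overlap_corrected_total(strict_iv_l, strict_iv_r)
    strict = HomologyResult(sl, sr, strict_total,
                            "strict_scan" if strict_total else "none", at_edge)
    cap = min(SCAN_CAP, len(ins))
    if sl < cap and sr < cap:
        return strict
    w = min(len(ins), MAX_WINDOW)
    left_window = genome.fetch(r.chrom, site - w, site)
    right_window = genome.fetch(r.chrom, site, site + w)
    aligned = large_homology((left_window, right_window), ins, min_identity)
    if aligned.total_size > strict.total_size:
        return HomologyResult(aligned.left_size, aligned.right_size,
                              aligned.total_size, "alignment", at_edge)
    return strict


def random_null_homology(genome: GenomeIndex,
                         n: int = 2000,
                         ins_len: int = 250,
                         seed: int = 0,
                         min_identity: float = 0.90) -> Tuple[np.ndarray, int]:
    """Null distribution of homology sizes for uniform-random insertions.

    ``n`` insertion sites are sampled uniformly over the genome and ``n``
    inserted sequences are drawn i.i.d. uniform over A/C/G/T; each is scored
    with the same two-tier machinery as real insertions.  Returns the full
    size distribution and its maximum (0 for an empty distribution).
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chroms()
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    sizes = np.zeros(n, dtype=int)
    bases = np.array(list("ACGT"))
    for i in range(n):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        pos = int(rng.integers(SCAN_CAP, genome.length(chrom) - SCAN_CAP))
        ins = "".join(rng.choice(bases, size=ins_len))
        rec = InsertionRecord(chrom=chrom, pos=pos, inserted_seq=ins,
                              record_id=f"null_{i}")
        sizes[i] = junctional_homology_size(rec, genome, min_identity).total_size
    return sizes, int(sizes.max(initial=0))
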