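"""Sequence-comparison primitives for insertion characterization.

This module provides the four alignment-flavoured operations the rest of the
package is built on:

* :func:`local_align` — BLAT-style local alignment discovery via exact k-mer
  seeding, diagonal clustering, and Smith–Waterman refinement of each
  candidate locus;
* :func:`global_identity` — end-to-end percent identity between two
  sequences (matches / alignment columns, gaps counted as columns);
* :func:`find_tandem_structure` — detection of tandem arrays inside a
  sequence, reporting the smallest verified period, copy number and the
  fraction of the sequence covered by the array;
* :func:`count_genomic_copies` — the number of distinct genomic loci
  carrying a near-full-length copy of a query sequence.

Identity is defined throughout as matched columns divided by total alignment
columns; an ``N`` base never matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import edlib
import numpy as np
from skbio.alignment import pair_align

# ---------------------------------------------------------------------------
# Configuration defaults (aligner scoring, seeding)
# ---------------------------------------------------------------------------

SEED_K = 11                 # exact seed length for local alignment discovery
SEED_BAND = 16              # max diagonal drift within one seed cluster
SEED_MAX_GAP = 120          # max along-target gap between chained seeds (bp)
WINDOW_PAD = 60             # padding around a seed cluster before refinement
MATCH_SCORE = 2             # Smith-Waterman match reward
MISMATCH_SCORE = -3         # Smith-Waterman mismatch penalty
GAP_OPEN = 5                # affine gap open cost (positive = penalty)
GAP_EXTEND = 2              # affine gap extension cost
MIN_QUERY_LEN = 20          # local_align rejects shorter queries
MAX_N_FRACTION = 0.5        # local_align rejects more ambiguous queries
MIN_MATCHES_CAP = 30        # default minimum matched bases per alignment

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 2-bit code; anything that is not ACGT maps to 4 (invalid in k-mers)
_CODE_LUT = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Return (kmer integer codes, start positions) for every valid k-mer."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 4).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kmers = win @ powers
    pos = np.nonzero(valid)[0]
    return kmers[valid], pos


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment between a query and a (named) target sequence.

    Coordinates are 0-based half-open.  Query coordinates always refer to the
    forward orientation of the query as supplied; ``strand`` records which
    orientation matched the target.
    """

    chrom: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    identity: float
    n_matches: int

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


class GenomeIndex:
    """In-memory genome with lazily-built k-mer indexes per chromosome.

    Wraps a ``{name: sequence}`` mapping; the 2-bit k-mer index for a
    chromosome is built on first alignment query against it and cached.
    """

    def __init__(self, sequences: Dict[str, str], k: int = SEED_K):
        self.k = k
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        self._kmer_index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_fasta(cls, path, k: int = SEED_K) -> "GenomeIndex":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs, k=k)

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} absent from genome index")
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequence(chrom)
        return seq[max(0, start):max(0, end)]

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def _index(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if chrom not in self._kmer_index:
            kmers, pos = _kmer_codes(_encode(self.sequence(chrom)), self.k)
            order = np.argsort(kmers, kind="stable")
            self._kmer_index[chrom] = (kmers[order], pos[order])
        return self._kmer_index[chrom]

    def seed_hits(self, query: str, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """All exact k-mer matches of ``query`` on ``chrom``: (qpos, tpos)."""
        sk, spos = self._index(chrom)
        qk, qpos = _kmer_codes(_encode(query), self.k)
        if qk.size == 0 or sk.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo = np.searchsorted(sk, qk, side="left")
        hi = np.searchsorted(sk, qk, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        q_out = np.repeat(qpos, counts)
        t_out = np.concatenate([spos[a:b] for a, b in zip(lo, hi) if b > a])
        return q_out, t_out


def _cluster_seeds(qpos: np.ndarray, tpos: np.ndarray,
                   band: int = SEED_BAND,
                   max_gap: int = SEED_MAX_GAP) -> List[Tuple[int, int, int, int]]:
    """Group seed hits into candidate loci.

    Hits are sorted by diagonal then target position; a new cluster starts
    when the diagonal drifts by more than ``band`` or the target gap exceeds
    ``max_gap``.  Clusters sharing overlapping target extents are then merged
    so one homologous locus yields one candidate window.
    Returns (qmin, qmax, tmin, tmax) extents (inclusive of seed length start,
    exclusive coordinates handled by caller).
    """
    if qpos.size == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    qpos, tpos, diag = qpos[order], tpos[order], diag[order]
    clusters = []
    start = 0
    for i in range(1, qpos.size + 1):
        if (i == qpos.size
                or diag[i] - diag[i - 1] > band
                or (diag[i] == diag[i - 1] and tpos[i] - tpos[i - 1] > max_gap)):
            q = qpos[start:i]
            t = tpos[start:i]
            clusters.append([int(q.min()), int(q.max()), int(t.min()), int(t.max())])
            start = i
    # merge clusters whose target extents overlap (split diagonals of one locus)
    clusters.sort(key=lambda c: (c[2], c[3]))
    merged: List[List[int]] = []
    for c in clusters:
        if merged and c[2] <= merged[-1][3] + max_gap and _q_compatible(merged[-1], c):
            m = merged[-1]
            m[0] = min(m[0], c[0])
            m[1] = max(m[1], c[1])
            m[2] = min(m[2], c[2])
            m[3] = max(m[3], c[3])
        else:
            merged.append(list(c))
    return [tuple(c) for c in merged]


def _q_compatible(a: Sequence[int], b: Sequence[int]) -> bool:
    """Merge only clusters whose query extents are consistent (overlap/adjacent)."""
    return not (b[0] > a[1] + SEED_MAX_GAP or a[0] > b[1] + SEED_MAX_GAP)


def _path_stats(path, seq1: str, seq2: str) -> Tuple[int, int, int, int, int, int]:
    """Walk a PairAlignPath; return (matches, columns, q_start, q_end, t_start, t_end).

    ``seq1`` is the query, ``seq2`` the target, both as aligned (local
    coordinates).  N never matches.
    """
    q, t = int(path.starts[0]), int(path.starts[1])
    q0, t0 = q, t
    matches = 0
    columns = 0
    states = np.asarray(path.states).ravel()
    for seg_len, state in zip(path.lengths, states):
        seg_len = int(seg_len)
        columns += seg_len
        if state == 0:  # aligned columns
            for i in range(seg_len):
                c1, c2 = seq1[q + i], seq2[t + i]
                if c1 == c2 and c1 != "N":
                    matches += 1
            q += seg_len
            t += seg_len
        elif state == 1:  # gap in seq1 -> consumes seq2
            t += seg_len
        else:  # gap in seq2 -> consumes seq1
            q += seg_len
    return matches, columns, q0, q, t0, t


def _refine_window(query: str, target_window: str) -> Union[Tuple[float, int, int, int, int, int], None]:
    """Smith-Waterman the full query against a candidate target window."""
    if not target_window:
        return None
    res = pair_align(query, target_window, mode="local",
                     sub_score=(MATCH_SCORE, MISMATCH_SCORE),
                     gap_cost=(GAP_OPEN, GAP_EXTEND))
    if not res.paths:
        return None
    matches, columns, q0, q1, t0, t1 = _path_stats(res.paths[0], query, target_window)
    if columns == 0 or q1 <= q0:
        return None
    return matches / columns, matches, q0, q1, t0, t1


def _validate_query(query: str) -> str:
    query = query.upper()
    if len(query) < MIN_QUERY_LEN:
        raise ValueError(
            f"query of {len(query)} bp is below the {MIN_QUERY_LEN} bp minimum")
    if query.count("N") > MAX_N_FRACTION * len(query):
        raise ValueError("low-complexity/ambiguous query (more than 50% N)")
    return query


def _as_index(target: Union[str, GenomeIndex]) -> GenomeIndex:
    if isinstance(target, GenomeIndex):
        return target
    return GenomeIndex({"seq": str(target)})


def local_align(query: str,
                target: Union[str, GenomeIndex],
                min_identity: float = 0.9,
                both_strands: bool = True,
                min_matches: Optional[int] = None) -> List[LocalAlignment]:
    """Discover local alignments of ``query`` on ``target``.

    Seed-and-extend: exact ``k``-mer seeds (k=11) are clustered by diagonal
    into candidate loci; each locus window is refined with a Smith-Waterman
    alignment and reported if its identity (matches / alignment columns)
    reaches ``min_identity``.  Both strands are searched unless
    ``both_strands`` is false.  Results are sorted by (chrom, target_start)
    and near-duplicate loci are collapsed keeping the highest identity
    (leftmost target coordinate on ties).

    ``min_matches`` is the minimum matched bases per reported alignment
    (the minimum-score role a genome-scale local aligner plays); default is
    30, reduced for short queries.  Isolated chance seed hits are discarded
    by this floor before refinement.
    """
    query = _validate_query(query)
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    index = _as_index(target)
    if min_matches is None:
        min_matches = min(MIN_MATCHES_CAP, max(index.k, len(query) // 2))
    out: List[LocalAlignment] = []
    qlen = len(query)
    for chrom in index.chroms():
        tlen = index.length(chrom)
        for strand in ("+", "-") if both_strands else ("+",):
            q = query if strand == "+" else reverse_complement(query)
            qpos, tpos = index.seed_hits(q, chrom)
            for qmin, qmax, tmin, tmax in _cluster_seeds(qpos, tpos):
                if qmax - qmin + index.k < 0.7 * min_matches:
                    continue  # chance isolated seed, cannot reach the floor
                w0 = max(0, tmin - qmin - WINDOW_PAD)
                w1 = min(tlen, tmax + index.k + (qlen - qmax) + WINDOW_PAD)
                ref = _refine_window(q, index.fetch(chrom, w0, w1))
                if ref is None:
                    continue
                ident, matches, q0, q1, t0, t1 = ref
                if ident < min_identity or matches < min_matches:
                    continue
                if strand == "-":
                    q0, q1 = qlen - q1, qlen - q0
                out.append(LocalAlignment(chrom, q0, q1, w0 + t0, w0 + t1,
                                          strand, ident, matches))
    return _dedupe(out)


def _dedupe(alns: List[LocalAlignment]) -> List[LocalAlignment]:
    """Collapse alignments covering essentially the same target locus."""
    alns = sorted(alns, key=lambda a: (a.chrom, a.target_start, -a.identity))
    kept: List[LocalAlignment] = []
    for a in alns:
        dup = False
        for b in kept:
            if b.chrom != a.chrom:
                continue
            ov = min(a.target_end, b.target_end) - max(a.target_start, b.target_start)
            if ov > 0.9 * min(a.target_span, b.target_span):
                dup = True
                if (a.identity, a.n_matches) > (b.identity, b.n_matches):
                    kept[kept.index(b)] = a
                break
        if not dup:
            kept.append(a)
    kept.sort(key=lambda a: (a.chrom, a.target_start, a.query_start))
    return kept


# ---------------------------------------------------------------------------
# Global identity
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """End-to-end identity: matched columns / alignment columns.

    The pair is ordered canonically before alignment so the function is
    exactly symmetric even when several optimal alignment paths exist.
    ``N`` bases never match.
    """
    if not a or not b:
        raise ValueError("global_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    if (len(a), a) > (len(b), b):
        a, b = b, a
    res = edlib.align(a, b, task="path", mode="NW")
    nice = edlib.getNiceAlignment(res, a, b)
    qal, tal, bar = nice["query_aligned"], nice["target_aligned"], nice["matched_aligned"]
    matches = sum(1 for i, c in enumerate(bar) if c == "|" and qal[i] != "N")
    return matches / len(bar)


# ---------------------------------------------------------------------------
# Tandem structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemAnnotation:
    """A tandem array detected inside a sequence.

    ``covered_span`` is the 0-based half-open interval of the query covered
    by the array (seed copy included); ``coverage`` is its fraction of the
    full query length.
    """

    seed_size: int
    copy_number: float
    covered_span: Tuple[int, int]
    coverage: float


def _candidate_periods(seq: str, max_brute: int = 64, probe_k: int = 8) -> List[int]:
    L = len(seq)
    cands = set(range(1, min(L // 2, max_brute) + 1))
    if L // 2 > max_brute:
        # propose larger periods from distances between repeated k-mer occurrences
        occ: Dict[str, int] = {}
        for i in range(L - probe_k + 1):
            kmer = seq[i:i + probe_k]
            if kmer in occ:
                d = i - occ[kmer]
                if max_brute < d <= L // 2:
                    cands.add(d)
            occ[kmer] = i
    return sorted(cands)


def _best_array_for_period(codes: np.ndarray, p: int,
                           per_copy_identity: float) -> Union[Tuple[int, int, float], None]:
    """Longest window of copies with overall match fraction >= threshold.

    Returns (span_start, span_end, matched_fraction) in sequence coordinates,
    seed copy included, or None.
    """
    L = codes.size
    m = (codes[p:] == codes[:-p]) & (codes[p:] != 4)
    n = m.size
    if n == 0:
        return None
    # per-copy match counts; last copy may be partial
    n_copies = (n + p - 1) // p
    counts = np.zeros(n_copies)
    sizes = np.zeros(n_copies)
    for j in range(n_copies):
        seg = m[j * p:(j + 1) * p]
        counts[j] = seg.sum()
        sizes[j] = seg.size
    # longest contiguous window of copies with mean match >= threshold
    excess = counts - per_copy_identity * sizes
    prefix = np.concatenate([[0.0], np.cumsum(excess)])
    best = None  # (window_bases, start_copy, end_copy)
    for i in range(n_copies):  # O(n_copies^2): fine at insertion scale
        for j in range(n_copies, i, -1):
            if prefix[j] - prefix[i] >= -1e-9:
                bases = int(sizes[i:j].sum())
                if best is None or bases > best[0]:
                    best = (bases, i, j)
                break
    if best is None:
        return None
    bases, i, j = best
    span_start = i * p                     # seed copy included
    span_end = p + i * p + bases
    window = m[i * p: i * p + bases]
    frac = float(window.mean()) if window.size else 1.0
    return span_start, span_end, frac


def find_tandem_structure(seq: str,
                          per_copy_identity: float = 0.9,
                          min_coverage: float = 0.3) -> List[TandemAnnotation]:
    """Detect tandem arrays in ``seq``.

    For each candidate period (all small periods brute-forced, larger ones
    proposed from repeated k-mer spacings) the longest window of tandem
    copies matching the previous copy at >= ``per_copy_identity`` is found.
    Annotations below ``min_coverage`` of the sequence are dropped; for
    near-identical spans the smallest period wins.  Result is sorted by
    coverage (descending), then seed size (ascending).
    """
    seq = seq.upper()
    L = len(seq)
    if L < 2:
        return []
    codes = _encode(seq)
    raw: List[TandemAnnotation] = []
    for p in _candidate_periods(seq):
        hit = _best_array_for_period(codes, p, per_copy_identity)
        if hit is None:
            continue
        span_start, span_end, _ = hit
        span = span_end - span_start
        if span < 2 * p:  # need at least two copies to call a tandem
            continue
        cov = span / L
        if cov >= min_coverage:
            raw.append(TandemAnnotation(p, span / p, (span_start, span_end), cov))
    raw.sort(key=lambda a: (-a.coverage, a.seed_size))
    kept: List[TandemAnnotation] = []
    for a in raw:
        redundant = False
        for b in kept:
            ov = (min(a.covered_span[1], b.covered_span[1])
                  - max(a.covered_span[0], b.covered_span[0]))
            if ov > 0.5 * (a.covered_span[1] - a.covered_span[0]):
                redundant = True
                break
        if not redundant:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# Genomic copy counting
# ---------------------------------------------------------------------------

def count_genomic_copies(seq: str,
                         genome: Union[str, GenomeIndex],
                         min_identity: float = 0.9,
                         min_query_cov: float = 0.8) -> int:
    """Number of disjoint genomic loci carrying a near-full-length copy.

    A locus counts if it has an alignment with identity >= ``min_identity``
    covering >= ``min_query_cov`` of the query; loci overlapping by more
    than 50% are merged.
    """
    qlen = len(seq)
    alns = [a for a in local_align(seq, genome, min_identity=min_identity)
            if a.query_span >= min_query_cov * qlen]
    loci: List[Tuple[str, int, int]] = []
    for a in sorted(alns, key=lambda x: (x.chrom, x.target_start)):
        if loci:
            c, s, e = loci[-1]
            if c == a.chrom:
                ov = min(e, a.target_end) - max(s, a.target_start)
                if ov > 0.5 * min(e - s, a.target_span):
                    loci[-1] = (c, min(s, a.target_start), max(e, a.target_end))
                    continue
        loci.append((a.chrom, a.target_start, a.target_end))
    return len(loci)
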