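"""Download-free synthetic stand-ins for the external inputs.

The generator emulates, at desk scale, the resources the analysis needs: a
reference chromosome with planted gene models (exons and introns), simple
repeats (genuine tandem arrays, small and large), SINE- and LINE-like
mobile-element instances (mutated copies of library consensus sequences)
and a consensus library FASTA — plus labeled insertion callsets whose
records are each constructed to satisfy exactly one insertion sub-type
definition, with designed junctional homology and site context.

Everything is deterministic under a seed and requires no network access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment_engine import GenomeIndex
from .genomic_context import AnnotationTrackSet
from .variant_io import Callset, Convention, InsertionRecord

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute a ``divergence`` fraction of positions (<= 10% keeps the
    planted copies above the 90%-identity rules)."""
    seq = list(seq)
    n_mut = int(round(divergence * len(seq)))
    for i in rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False):
        alt = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alt[int(rng.integers(3))]
    return "".join(seq)


@dataclass
class SyntheticGenomeConfig:
    """Shape of the synthetic reference and its annotation.

    Defaults give a 1 Mb chromosome with enough planted features for every
    scenario and context class while keeping full runs to seconds.
    """

    length: int = 1_000_000
    chrom: str = "chr3"
    n_genes: int = 30              # each: 2 exons of exon_len with an intron
    exon_len: int = 300
    intron_len: int = 400
    n_simple_repeats_small: int = 20   # arrays < 300 bp
    n_simple_repeats_large: int = 20   # arrays > 300 bp
    n_sines: int = 60
    n_lines: int = 6
    n_other_repeats: int = 8
    sine_family_count: int = 2
    sine_consensus_len: int = 300
    line_consensus_len: int = 1_200
    me_divergence: float = 0.04
    gc: float = 0.41
    min_feature_gap: int = 1_600
    seed: int = 0


def _allocate_slots(rng: np.random.Generator, genome_len: int,
                    sizes: Sequence[int], gap: int) -> List[int]:
    """Non-overlapping start positions with at least ``gap`` bp between
    features; raises when the requested features cannot be packed."""
    need = sum(sizes) + gap * (len(sizes) + 1)
    if need > genome_len:
        raise ValueError(f"cannot pack {len(sizes)} features into {genome_len} bp")
    slack = genome_len - sum(sizes) - gap * (len(sizes) + 1)
    cuts = np.sort(rng.integers(0, slack + 1, size=len(sizes)))
    starts = []
    offset = gap
    for i, size in enumerate(sizes):
        starts.append(int(cuts[i]) + offset)
        offset += size + gap
    return starts


def generate_genome(cfg: SyntheticGenomeConfig = SyntheticGenomeConfig()
                    ) -> Tuple[GenomeIndex, AnnotationTrackSet, Dict[str, str]]:
    """Build (genome index, annotation tracks, mobile-element library).

    Every planted feature's interval is recorded in the matching track;
    SINE/LINE instances are mutated copies of the library consensus; simple
    repeats are genuine tandem arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    backbone = list(_random_seq(rng, cfg.length, cfg.gc))

    me_library: Dict[str, str] = {}
    for i in range(cfg.sine_family_count):
        me_library[f"SINE{i + 1}"] = _random_seq(rng, cfg.sine_consensus_len, 0.5)
    me_library["LINE1"] = _random_seq(rng, cfg.line_consensus_len, 0.45)
    other_consensus = _random_seq(rng, 400, 0.5)  # deliberately not in library

    gene_span = 2 * cfg.exon_len + cfg.intron_len
    sizes: List[int] = [gene_span] * cfg.n_genes
    kinds: List[Tuple[str, object]] = [("gene", None)] * cfg.n_genes

    for _ in range(cfg.n_simple_repeats_small):
        p = int(rng.integers(2, 11))
        span = int(rng.integers(100, 280))
        kinds.append(("simple_small", (p, span)))
        sizes.append(span)
    for _ in range(cfg.n_simple_repeats_large):
        p = int(rng.integers(2, 11))
        span = int(rng.integers(320, 700))
        kinds.append(("simple_large", (p, span)))
        sizes.append(span)
    for _ in range(cfg.n_sines):
        fam = f"SINE{int(rng.integers(1, cfg.sine_family_count + 1))}"
        kinds.append(("sine", fam))
        sizes.append(cfg.sine_consensus_len)
    for _ in range(cfg.n_lines):
        kinds.append(("line", "LINE1"))
        sizes.append(cfg.line_consensus_len)
    for _ in range(cfg.n_other_repeats):
        kinds.append(("other", None))
        sizes.append(len(other_consensus))

    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]
    sizes = [sizes[i] for i in order]
    starts = _allocate_slots(rng, cfg.length, sizes, cfg.min_feature_gap)

    tracks = AnnotationTrackSet({cfg.chrom: cfg.length})
    for (kind, payload), start, size in zip(kinds, starts, sizes):
        if kind == "gene":
            e1 = (start, start + cfg.exon_len)
            intr = (e1[1], e1[1] + cfg.intron_len)
            e2 = (intr[1], intr[1] + cfg.exon_len)
            tracks.add("exons", cfg.chrom, *e1)
            tracks.add("introns", cfg.chrom, *intr)
            tracks.add("exons", cfg.chrom, *e2)
            continue  # gene bodies keep backbone sequence
        if kind in ("simple_small", "simple_large"):
            p, span = payload
            motif = _random_seq(rng, p, 0.5)
            payload_seq = (motif * (span // p + 1))[:span]
            tracks.add("simple_repeats", cfg.chrom, start, start + span)
        elif kind == "sine":
            payload_seq = _mutate(rng, me_library[payload], cfg.me_divergence)
            tracks.add("sines", cfg.chrom, start, start + len(payload_seq))
        elif kind == "line":
            payload_seq = _mutate(rng, me_library[payload], cfg.me_divergence)
            tracks.add("lines", cfg.chrom, start, start + len(payload_seq))
        else:  # other repeat family
            payload_seq = _mutate(rng, other_consensus, cfg.me_divergence)
            tracks.add("other_repeats", cfg.chrom, start, start + len(payload_seq))
        backbone[start:start + len(payload_seq)] = list(payload_seq)

    genome = GenomeIndex({cfg.chrom: "".join(backbone)})
    return genome, tracks, me_library


# ---------------------------------------------------------------------------
# Labeled callsets
# ---------------------------------------------------------------------------

DEFAULT_TYPE_MIX = {
    "tandem_repeat": 0.40,
    "mobile_element": 0.20,
    "tandem_duplication": 0.15,
    "dispersed_duplication": 0.10,
    "novel_sequence": 0.15,
}
#: representative sizes for the four size classes
DEFAULT_SIZE_MIX = {150: 0.55, 300: 0.30, 700: 0.10, 1200: 0.05}


@dataclass
class LabeledCallsetConfig:
    n: int = 100
    type_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    size_mix: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_MIX))
    homology_mix: Dict[int, float] = field(default_factory=lambda: {0: 1.0})
    context_mix: Dict[str, float] = field(default_factory=lambda: {"non_repeated": 1.0})
    seed: int = 0

    def __post_init__(self):
        for mix in (self.type_mix, self.size_mix, self.homology_mix, self.context_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("mix fractions must sum to 1")


def _draw(rng: np.random.Generator, mix: Dict) -> object:
    keys = list(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _clean_sites(rng: np.random.Generator, genome: GenomeIndex,
                 tracks: AnnotationTrackSet, chrom: str, n: int,
                 clearance: int, spacing: int = 2_000,
                 max_tries: int = 50_000) -> List[int]:
    """Sample insertion points with ``clearance`` bp free of any repeat or
    gene feature on both sides, pairwise ``spacing`` apart."""
    length = genome.length(chrom)
    chosen: List[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} clean sites (got {len(chosen)})")
        pos = int(rng.integers(clearance, length - clearance))
        if any(abs(pos - c) < spacing for c in chosen):
            continue
        clean = True
        for track in ("simple_repeats", "sines", "lines", "other_repeats",
                      "exons", "introns"):
            ivs = tracks._trees[track].get(chrom)
            if ivs is not None and ivs.overlaps(pos - clearance, pos + clearance):
                clean = False
                break
        if clean:
            chosen.append(pos)
    return sorted(chosen)


def _sites_in_track(rng: np.random.Generator, tracks: AnnotationTrackSet,
                    track: str, chrom: str, n: int,
                    size_filter=None, margin: int = 5) -> List[int]:
    ivs = [(s, e) for c, s, e in tracks.intervals(track, chrom)
           if (size_filter is None or size_filter(e - s)) and e - s > 2 * margin]
    if not ivs:
        raise ValueError(f"no eligible intervals in track {track!r}")
    sites = []
    for _ in range(n):
        s, e = ivs[int(rng.integers(len(ivs)))]
        sites.append(int(rng.integers(s + margin, e - margin)))
    return sorted(sites)


GUARD_LEN = 20          # bases after the planted homology kept unalignable
GUARD_MAX_SHIFT = 10    # offsets over which the guard must stay unalignable
GUARD_MAX_MATCH = 0.45  # per-offset match fraction the guard may not exceed


def _guard_ok(ins: List[str], right_flank: str, start: int, guard: int) -> bool:
    """True when the guard block cannot seed or sustain an alignment with the
    flank at any small offset (so a local aligner stops at the designed
    homology instead of gap-shifting past it)."""
    block = ins[start:start + guard]
    for d in range(-GUARD_MAX_SHIFT, GUARD_MAX_SHIFT + 1):
        matches = 0
        compared = 0
        run = 0
        for j, base in enumerate(block):
            fj = start + d + j
            if 0 <= fj < len(right_flank):
                compared += 1
                if base == right_flank[fj]:
                    matches += 1
                    run += 1
                    if run > 3:  # a 4-match run pays for a gap jump
                        return False
                else:
                    run = 0
        if compared and matches > GUARD_MAX_MATCH * compared:
            return False
    return True


def _enforce_junction_mismatch(rng: np.random.Generator, ins: List[str],
                               left_anchor: str, right_flank: str,
                               homology: int) -> None:
    """Pin the designed homology exactly.

    The bases bounding the planted segment are forced to mismatch the
    corresponding flank bases, and the following guard block is resampled
    until it is unalignable against the flank at every small offset; the
    last insertion base is mismatched against the left junction.
    """
    L = len(ins)
    guard = min(GUARD_LEN, L - homology)
    for attempt in range(200):
        for j in range(homology, homology + guard):
            if j < len(right_flank):
                while ins[j] == right_flank[j]:
                    ins[j] = str(rng.choice(BASES))
        if _guard_ok(ins, right_flank, homology, guard):
            break
        for j in range(homology, homology + guard):
            ins[j] = str(rng.choice(BASES))
    while L > 0 and ins[-1] == left_anchor:
        ins[-1] = str(rng.choice(BASES))


def make_insertion_sequence(rng: np.random.Generator,
                            ins_type: str,
                            size: int,
                            genome: GenomeIndex,
                            tracks: AnnotationTrackSet,
                            me_library: Dict[str, str],
                            chrom: str,
                            site: int,
                            donor_site: Optional[int] = None) -> str:
    """Construct one inserted sequence satisfying exactly one sub-type
    definition at the given site."""
    if ins_type == "tandem_repeat":
        p = int(rng.integers(4, 9))
        motif = _random_seq(rng, p, 0.5)
        return (motif * (size // p + 2))[:size]
    if ins_type == "mobile_element":
        fams = [f for f, s in me_library.items() if len(s) >= size]
        if not fams:
            raise ValueError(f"no ME consensus of length >= {size}")
        fam = fams[int(rng.integers(len(fams)))]
        cons = me_library[fam]
        off = int(rng.integers(0, len(cons) - size + 1))
        return _mutate(rng, cons[off:off + size], 0.03)
    if ins_type == "tandem_duplication":
        return genome.fetch(chrom, site, site + size)
    if ins_type == "dispersed_duplication":
        if donor_site is None:
            raise ValueError("dispersed duplication requires a donor site")
        return genome.fetch(chrom, donor_site, donor_site + size)
    if ins_type == "novel_sequence":
        return _random_seq(rng, size, 0.5)
    raise ValueError(f"unknown insertion type {ins_type!r}")


def generate_labeled_callset(genome: GenomeIndex,
                             tracks: AnnotationTrackSet,
                             me_library: Dict[str, str],
                             cfg: LabeledCallsetConfig = LabeledCallsetConfig()
                             ) -> Tuple[Callset, pd.DataFrame]:
    """Generate a callset with known per-record truth labels.

    Each record is built per its target type's definition with annotation
    coverage >= 0.95, designed junctional homology and designed site
    context; the truth table carries (record_id, type, size, homology,
    context).
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = genome.chroms()[0]
    draws = []
    for i in range(cfg.n):
        draws.append((
            str(_draw(rng, cfg.type_mix)),
            int(_draw(rng, cfg.size_mix)),
            int(_draw(rng, cfg.homology_mix)),
            str(_draw(rng, cfg.context_mix)),
        ))
    max_size = max((d[1] for d in draws), default=250)
    n_clean = sum(1 for d in draws if d[3] == "non_repeated")
    clean_sites = _clean_sites(rng, genome, tracks, chrom, n_clean,
                               clearance=max_size + 100)
    donor_sites = _clean_sites(rng, genome, tracks, chrom,
                               sum(1 for d in draws
                                   if d[0] == "dispersed_duplication"),
                               clearance=max_size + 100)
    ctx_sites: Dict[str, List[int]] = {}
    for ctx in set(d[3] for d in draws) - {"non_repeated"}:
        track, size_filter = {
            "sine": ("sines", None),
            "line": ("lines", None),
            "simple_repeat_small": ("simple_repeats", lambda s: s < 300),
            "simple_repeat_large": ("simple_repeats", lambda s: s > 300),
            "exonic": ("exons", None),
        }[ctx]
        ctx_sites[ctx] = _sites_in_track(
            rng, tracks, track, chrom, sum(1 for d in draws if d[3] == ctx),
            size_filter)

    clean_iter = iter(clean_sites)
    donor_iter = iter(donor_sites)
    ctx_iters = {k: iter(v) for k, v in ctx_sites.items()}
    records: List[InsertionRecord] = []
    truth_rows = []
    for i, (ins_type, size, homology, ctx) in enumerate(draws):
        site = next(clean_iter) if ctx == "non_repeated" else next(ctx_iters[ctx])
        donor = next(donor_iter) if ins_type == "dispersed_duplication" else None
        seq = make_insertion_sequence(rng, ins_type, size, genome, tracks,
                                      me_library, chrom, site, donor)
        if ins_type in ("novel_sequence", "mobile_element", "dispersed_duplication"):
            ins = list(seq)
            if homology > 0:
                ins[:homology] = list(genome.fetch(chrom, site, site + homology))
            _enforce_junction_mismatch(
                rng, ins, genome.fetch(chrom, site - 1, site),
                genome.fetch(chrom, site, site + len(ins)), homology)
            seq = "".join(ins)
        records.append(InsertionRecord(
            chrom=chrom, pos=site, inserted_seq=seq,
            filter_field="PASS", genotype="1/1",
            record_id=f"syn{i}",
            info_tags={"TYPE": ins_type, "HOMLEN": str(homology), "CONTEXT": ctx},
            ref_anchor=genome.fetch(chrom, site - 1, site) or "N"))
        truth_rows.append({"record_id": f"syn{i}", "type": ins_type,
                           "size": size, "homology": homology, "context": ctx})
    cs = Callset(records, convention=Convention.generic, source_label="synthetic")
    truth = pd.DataFrame(truth_rows)
    return cs, truth


def donor_pool(rng: np.random.Generator, n: int, length: int = 1_200,
               gc: float = 0.40) -> List[str]:
    """Pool of novel donor sequences (stand-in for foreign exonic sequence);
    random composition makes them absent from the synthetic reference."""
    return [_random_seq(rng, length, gc) for _ in range(n)]
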