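"""Simulation suite: scenario specs -> truth sets -> mutated FASTA + truth VCF.

The suite enumerates 22 datasets of homozygous insertions on one reference
chromosome: a baseline (novel 250 bp sequences inserted in exons with no
junctional homology), three insertion sizes (50/500/1000 bp at the baseline
sites), five insertion types (dispersed duplication, tandem repeats with
6 bp and 25 bp seeds, tandem duplication, mobile element), five junctional
homology sizes (10/20/50/100/150 bp), five genomic contexts (SINE, LINE,
small and large simple repeats, proximal pairs) and three datasets derived
from a supplied real callset (novel sequences at the real sites, the real
sequences in exons, and the real sequences at their real sites).

Read simulation is deliberately out of scope: the module emits the mutated
FASTA that read simulators consume (the study used 2x150 bp reads at 40x
with 300 bp inserts, and long reads at 40x) together with the truth VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .alignment_engine import GenomeIndex
from .genomic_context import AnnotationTrackSet
from .synthetic_data import _enforce_junction_mismatch, _random_seq
from .variant_io import Callset, Convention, InsertionRecord, write_vcf

SCENARIOS = ("baseline", "size", "type", "homology", "context", "real")
SIZE_PARAMS = (50, 500, 1000)
TYPE_PARAMS = ("dispersed_dup", "tr_seed6", "tr_seed25", "tandem_dup",
               "mobile_element")
HOMOLOGY_PARAMS = (10, 20, 50, 100, 150)
CONTEXT_PARAMS = ("sine", "line", "simple_repeat_small", "simple_repeat_large",
                  "proximal")
REAL_PARAMS = ("novel_at_real_sites", "real_in_exons", "real_at_real_sites")

BASELINE_SIZE = 250


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: str
    parameter: Optional[Union[int, str]] = None
    n_insertions: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        legal = {
            "baseline": (None,),
            "size": SIZE_PARAMS,
            "type": TYPE_PARAMS,
            "homology": HOMOLOGY_PARAMS,
            "context": CONTEXT_PARAMS,
            "real": REAL_PARAMS,
        }[self.scenario]
        if self.parameter not in legal:
            raise ValueError(
                f"parameter {self.parameter!r} not legal for scenario {self.scenario!r}")
        if self.n_insertions < 1:
            raise ValueError("n_insertions must be >= 1")

    @property
    def name(self) -> str:
        return self.scenario if self.parameter is None \
            else f"{self.scenario}_{self.parameter}"


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int                    # 1-based anchor base, insertion right after it
    inserted_seq: str
    ins_type: str
    expected_homology: Optional[int]
    context: str
    scenario: str = ""
    parameter: str = ""

    @property
    def size(self) -> int:
        return len(self.inserted_seq)

    @property
    def zero_based_site(self) -> int:
        return self.pos


@dataclass
class TruthSet:
    """Simulated insertions plus scenario labels; homozygous by design."""

    records: List[TruthRecord]
    scenario: str = ""
    parameter: str = ""

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        seen = set()
        for r in self.records:
            key = (r.chrom, r.pos)
            if key in seen:
                raise ValueError(f"duplicate insertion position {key}")
            seen.add(key)
            if not r.inserted_seq:
                raise ValueError("truth record with empty inserted sequence")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def build_scenario_suite(n_insertions: int = 200,
                         seed: int = 0,
                         scenarios: Optional[Sequence[str]] = None,
                         sizes: Sequence[int] = SIZE_PARAMS,
                         types: Sequence[str] = TYPE_PARAMS,
                         homologies: Sequence[int] = HOMOLOGY_PARAMS,
                         contexts: Sequence[str] = CONTEXT_PARAMS,
                         reals: Sequence[str] = REAL_PARAMS) -> List[ScenarioSpec]:
    """Enumerate the simulation suite in deterministic order.

    Defaults yield exactly 22 specs: baseline (1) + sizes (3) + types (5) +
    homologies (5) + contexts (5) + real-derived (3).  The non-repeated
    context dataset is the baseline itself (exons are repeat-free), which is
    why the context axis contributes five rather than six datasets.
    """
    wanted = set(scenarios) if scenarios is not None else set(SCENARIOS)
    specs: List[ScenarioSpec] = []
    if "baseline" in wanted:
        specs.append(ScenarioSpec("baseline", None, n_insertions, seed))
    if "size" in wanted:
        specs += [ScenarioSpec("size", p, n_insertions, seed) for p in sizes]
    if "type" in wanted:
        specs += [ScenarioSpec("type", p, n_insertions, seed) for p in types]
    if "homology" in wanted:
        specs += [ScenarioSpec("homology", p, n_insertions, seed) for p in homologies]
    if "context" in wanted:
        specs += [ScenarioSpec("context", p, n_insertions, seed) for p in contexts]
    if "real" in wanted:
        specs += [ScenarioSpec("real", p, n_insertions, seed) for p in reals]
    return specs


def _param_index(spec: ScenarioSpec) -> int:
    order = {
        "baseline": (None,),
        "size": SIZE_PARAMS,
        "type": TYPE_PARAMS,
        "homology": HOMOLOGY_PARAMS,
        "context": CONTEXT_PARAMS,
        "real": REAL_PARAMS,
    }[spec.scenario]
    return order.index(spec.parameter)


def _content_rng(spec: ScenarioSpec) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, SCENARIOS.index(spec.scenario), _param_index(spec)])


def _baseline_sites(genome: GenomeIndex, tracks: AnnotationTrackSet,
                    n: int, seed: int, margin: int = 20,
                    spacing: int = 1_000) -> List[int]:
    """Exonic insertion points, shared by every scenario that keeps the
    baseline locations; deterministic in the suite seed alone."""
    rng = np.random.default_rng([seed, 9_999])
    chrom = genome.chroms()[0]
    exons = [(s, e) for c, s, e in tracks.intervals("exons", chrom)
             if e - s > 2 * margin]
    if not exons:
        raise ValueError("no exon intervals available for baseline sites")
    sites: List[int] = []
    tries = 0
    while len(sites) < n:
        tries += 1
        if tries > 200_000:
            raise ValueError(
                f"insufficient eligible exonic sites: placed {len(sites)} of {n}")
        s, e = exons[int(rng.integers(len(exons)))]
        pos = int(rng.integers(s + margin, e - margin))
        if all(abs(pos - q) >= spacing for q in sites):
            sites.append(pos)
    return sorted(sites)


def _sites_in_intervals(rng: np.random.Generator, ivs: List[Tuple[int, int]],
                        n: int, margin: int = 5, spacing: int = 300,
                        label: str = "") -> List[int]:
    ivs = [(s, e) for s, e in ivs if e - s > 2 * margin]
    if not ivs:
        raise ValueError(f"no eligible intervals for context {label!r}")
    sites: List[int] = []
    tries = 0
    while len(sites) < n:
        tries += 1
        if tries > 200_000:
            raise ValueError(
                f"insufficient eligible sites in context {label!r}: "
                f"placed {len(sites)} of {n}")
        s, e = ivs[int(rng.integers(len(ivs)))]
        pos = int(rng.integers(s + margin, e - margin))
        if all(abs(pos - q) >= spacing for q in sites):
            sites.append(pos)
    return sorted(sites)


def _novel_donor(rng: np.random.Generator, size: int) -> List[str]:
    return list(_random_seq(rng, size, 0.40))


def _pin_homology(rng: np.random.Generator, genome: GenomeIndex, chrom: str,
                  site: int, ins: List[str], homology: int) -> str:
    """Plant ``homology`` bp of right-flank sequence at the start of the
    insertion and pin the designed size with bounding mismatches."""
    if homology > 0:
        ins[:homology] = list(genome.fetch(chrom, site, site + homology))
    _enforce_junction_mismatch(
        rng, ins, genome.fetch(chrom, site - 1, site),
        genome.fetch(chrom, site, site + len(ins)), homology)
    return "".join(ins)


def _me_instance(rng: np.random.Generator, tracks: AnnotationTrackSet,
                 genome: GenomeIndex, chrom: str) -> str:
    """A 200-300 bp cut of an annotated mobile-element instance."""
    ivs = (tracks.intervals("sines", chrom) + tracks.intervals("lines", chrom))
    if not ivs:
        raise ValueError("no annotated mobile elements to draw from")
    size = int(rng.integers(200, 301))
    for _ in range(1_000):
        _, s, e = ivs[int(rng.integers(len(ivs)))]
        if e - s >= size:
            off = int(rng.integers(s, e - size + 1))
            return genome.fetch(chrom, off, off + size)
    raise ValueError("no mobile-element instance long enough")


def _exon_donor_segments(rng: np.random.Generator, tracks: AnnotationTrackSet,
                         genome: GenomeIndex, chrom: str, n: int, size: int,
                         exclude_sites: Sequence[int]) -> List[str]:
    """Segments cut from exons of the same chromosome, avoiding the
    insertion sites themselves (dispersed-duplication donors)."""
    exons = [(s, e) for c, s, e in tracks.intervals("exons", chrom)
             if e - s >= size and not any(s <= q < e for q in exclude_sites)]
    if not exons:
        raise ValueError(f"no exon of length >= {size} free of insertion sites")
    out = []
    for _ in range(n):
        s, e = exons[int(rng.integers(len(exons)))]
        off = int(rng.integers(s, e - size + 1))
        out.append(genome.fetch(chrom, off, off + size))
    return out


def generate_insertions(spec: ScenarioSpec,
                        genome: GenomeIndex,
                        tracks: AnnotationTrackSet,
                        me_library: Dict[str, str],
                        source_callset: Optional[Callset] = None) -> TruthSet:
    """Build the truth set for one scenario.

    Site locations for the baseline, size, type and homology scenarios are
    identical (derived from the suite seed); context scenarios sample fresh
    sites inside the requested annotation class; real scenarios take sites
    and/or sequences from ``source_callset``.
    """
    chrom = genome.chroms()[0]
    rng = _content_rng(spec)
    n = spec.n_insertions
    records: List[TruthRecord] = []

    def add(site: int, seq: str, ins_type: str, hom: Optional[int], ctx: str):
        records.append(TruthRecord(chrom, site, seq, ins_type, hom, ctx,
                                   spec.scenario, str(spec.parameter)))

    if spec.scenario in ("baseline", "size", "type", "homology"):
        sites = _baseline_sites(genome, tracks, n, spec.seed)

    if spec.scenario == "baseline":
        for site in sites:
            seq = _pin_homology(rng, genome, chrom, site,
                                _novel_donor(rng, BASELINE_SIZE), 0)
            add(site, seq, "novel_sequence", 0, "exonic")

    elif spec.scenario == "size":
        size = int(spec.parameter)
        for site in sites:
            seq = _pin_homology(rng, genome, chrom, site,
                                _novel_donor(rng, size), 0)
            add(site, seq, "novel_sequence", 0, "exonic")

    elif spec.scenario == "type":
        if spec.parameter == "dispersed_dup":
            donors = _exon_donor_segments(rng, tracks, genome, chrom, n,
                                          BASELINE_SIZE, sites)
            for site, seq in zip(sites, donors):
                add(site, seq, "dispersed_duplication", None, "exonic")
        elif spec.parameter in ("tr_seed6", "tr_seed25"):
            p = 6 if spec.parameter == "tr_seed6" else 25
            for site in sites:
                motif = genome.fetch(chrom, site - p, site)  # left junction seed
                seq = (motif * (BASELINE_SIZE // p + 2))[:BASELINE_SIZE]
                add(site, seq, "tandem_repeat", None, "exonic")
        elif spec.parameter == "tandem_dup":
            for site in sites:
                seq = genome.fetch(chrom, site, site + BASELINE_SIZE)
                add(site, seq, "tandem_duplication", None, "exonic")
        else:  # mobile_element
            for site in sites:
                seq = _me_instance(rng, tracks, genome, chrom)
                add(site, seq, "mobile_element", None, "exonic")

    elif spec.scenario == "homology":
        x = int(spec.parameter)
        for site in sites:
            seq = _pin_homology(rng, genome, chrom, site,
                                _novel_donor(rng, BASELINE_SIZE), x)
            add(site, seq, "novel_sequence", x, "exonic")

    elif spec.scenario == "context":
        if spec.parameter == "proximal":
            base = _baseline_sites(genome, tracks, (n + 1) // 2, spec.seed,
                                   spacing=1_000)
            for site in base:
                if len(records) >= n:
                    break
                seq = _pin_homology(rng, genome, chrom, site,
                                    _novel_donor(rng, BASELINE_SIZE), 0)
                add(site, seq, "novel_sequence", 0, "proximal")
                if len(records) >= n:
                    break
                gap = int(rng.integers(5, 151))
                site2 = site + gap
                seq2 = _pin_homology(rng, genome, chrom, site2,
                                     _novel_donor(rng, BASELINE_SIZE), 0)
                add(site2, seq2, "novel_sequence", 0, "proximal")
        else:
            track, size_filter = {
                "sine": ("sines", None),
                "line": ("lines", None),
                "simple_repeat_small": ("simple_repeats", lambda s: s < 300),
                "simple_repeat_large": ("simple_repeats", lambda s: s > 300),
            }[spec.parameter]
            ivs = [(s, e) for c, s, e in tracks.intervals(track, chrom)
                   if size_filter is None or size_filter(e - s)]
            sites = _sites_in_intervals(rng, ivs, n, label=str(spec.parameter))
            for site in sites:
                seq = _pin_homology(rng, genome, chrom, site,
                                    _novel_donor(rng, BASELINE_SIZE), 0)
                add(site, seq, "novel_sequence", 0, str(spec.parameter))

    else:  # real
        if source_callset is None:
            raise ValueError("real scenarios require a source callset")
        source = [r for r in source_callset if r.resolved and r.chrom == chrom]
        if not source:
            raise ValueError(f"source callset has no resolved records on {chrom}")
        source = source[:n]
        if spec.parameter == "novel_at_real_sites":
            for r in source:
                seq = "".join(_novel_donor(rng, r.size))
                add(r.zero_based_site, seq, "novel_sequence", None, "real_site")
        elif spec.parameter == "real_in_exons":
            sites = _baseline_sites(genome, tracks, len(source), spec.seed)
            for site, r in zip(sites, source):
                add(site, r.inserted_seq, r.info_tags.get("TYPE", "real"),
                    None, "exonic")
        else:  # real_at_real_sites
            for r in source:
                add(r.zero_based_site, r.inserted_seq,
                    r.info_tags.get("TYPE", "real"), None, "real_site")

    return TruthSet(records, spec.scenario, str(spec.parameter))


def apply_insertions(genome: Union[GenomeIndex, Dict[str, str]],
                     ts: TruthSet) -> Dict[str, str]:
    """Return mutated chromosome sequences with all insertions applied.

    Insertions are applied in descending coordinate order so recorded
    positions stay valid; output length equals input length plus the sum of
    insertion sizes.
    """
    if isinstance(genome, GenomeIndex):
        seqs = {c: genome.sequence(c) for c in genome.chroms()}
    else:
        seqs = {c: s for c, s in genome.items()}
    by_chrom: Dict[str, List[TruthRecord]] = {}
    for r in ts.records:
        if r.chrom not in seqs:
            raise KeyError(f"truth chromosome {r.chrom!r} absent from genome")
        if not 0 <= r.zero_based_site <= len(seqs[r.chrom]):
            raise ValueError(f"insertion point {r.pos} outside {r.chrom}")
        by_chrom.setdefault(r.chrom, []).append(r)
    out = dict(seqs)
    for chrom, recs in by_chrom.items():
        seq = out[chrom]
        for r in sorted(recs, key=lambda x: -x.zero_based_site):
            i = r.zero_based_site
            seq = seq[:i] + r.inserted_seq + seq[i:]
        out[chrom] = seq
    return out


def truth_to_callset(ts: TruthSet, genome: GenomeIndex) -> Callset:
    """View a truth set as a homozygous generic callset (INFO carries the
    scenario labels)."""
    records = []
    for i, r in enumerate(ts.records):
        info = {"SVTYPE": "INS", "SCENARIO": r.scenario or ".",
                "PARAM": r.parameter or ".", "TYPE": r.ins_type,
                "CONTEXT": r.context}
        if r.expected_homology is not None:
            info["HOMLEN"] = str(r.expected_homology)
        anchor = genome.fetch(r.chrom, r.zero_based_site - 1, r.zero_based_site) or "N"
        records.append(InsertionRecord(
            chrom=r.chrom, pos=r.pos, inserted_seq=r.inserted_seq,
            filter_field="PASS", info_tags=info, genotype="1/1",
            record_id=f"sim{i}", ref_anchor=anchor))
    return Callset(records, convention=Convention.generic,
                   source_label=f"{ts.scenario}:{ts.parameter}")


def write_truth_vcf(ts: TruthSet, genome: GenomeIndex, path) -> None:
    """Write the truth set as a homozygous insertion VCF (round-trips
    through the VCF reader)."""
    lengths = {c: genome.length(c) for c in genome.chroms()}
    write_vcf(truth_to_callset(ts, genome), path, contig_lengths=lengths)


def write_fasta(seqs: Dict[str, str], path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=c, description="") for c, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")
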