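"""Reading, filtering and writing sequence-resolved insertion callsets.

Insertions are modelled as :class:`InsertionRecord`: the 1-based position of
the reference base immediately preceding the inserted sequence, plus the
inserted sequence itself.  Internally all other modules use 0-based
half-open coordinates; the VCF convention is converted at I/O only.

Two tag conventions for the discovery technology of each call are
supported: ``chaisson`` (a ``UNION`` INFO key naming the technology that
discovered the variant) and ``giab`` (``Ill`` labels embedded in the
``ExactMatchID`` INFO key, with refinement-only labels not counted as
short-read discoveries).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import pysam

VALID_BASES = set("ACGTN")

#: default "core genome" allow-list: primary human chromosomes
PRIMARY_CHROMS = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
    + [str(i) for i in range(1, 23)] + ["X", "Y"]
)


class Convention(str, Enum):
    chaisson = "chaisson"
    giab = "giab"
    generic = "generic"


class Technology(str, Enum):
    short_read = "short_read"
    other = "other"


@dataclass
class InsertionRecord:
    """One sequence-resolved insertion call.

    ``pos`` is the 1-based coordinate of the reference base immediately
    preceding the insertion; ``inserted_seq`` is empty for symbolic
    (unresolved) records.
    """

    chrom: str
    pos: int
    inserted_seq: str
    filter_field: str = "PASS"
    info_tags: Dict[str, object] = field(default_factory=dict)
    genotype: str = "./."
    record_id: str = "."
    resolved: bool = True
    ref_anchor: str = "N"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        self.inserted_seq = self.inserted_seq.upper()
        if self.resolved:
            bad = set(self.inserted_seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases in inserted sequence: {bad}")
            if not self.inserted_seq:
                raise ValueError("resolved record with empty inserted sequence")

    @property
    def size(self) -> int:
        return len(self.inserted_seq)

    @property
    def zero_based_site(self) -> int:
        """0-based insertion point (the gap after the anchor base)."""
        return self.pos


@dataclass
class Callset:
    records: List[InsertionRecord]
    convention: Convention = Convention.generic
    source_label: str = ""

    def __post_init__(self):
        self.convention = Convention(self.convention)
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class FilterConfig:
    """Gold-standard callset filters.

    ``min_size`` retains records strictly larger than the threshold;
    ``chrom_allowlist`` operationalizes the "core genome" as the primary
    chromosomes; ``parent_support_key`` names the INFO entry carrying
    per-family-member support.
    """

    min_size: int = 50
    require_sequence_resolved: bool = True
    require_parent_support: bool = False
    drop_longhomref: bool = False
    chrom_allowlist: Optional[Tuple[str, ...]] = None
    parent_support_key: str = "PARENTS"

    def __post_init__(self):
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")


class VcfParseError(ValueError):
    pass


def _info_to_tags(rec) -> Dict[str, object]:
    tags: Dict[str, object] = {}
    for k, v in rec.info.items():
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        tags[k] = v
    return tags


def _genotype_string(rec) -> str:
    if not rec.samples:
        return "./."
    sample = rec.samples[0]
    gt = sample.get("GT")
    if gt is None:
        return "./."
    sep = "|" if getattr(sample, "phased", False) else "/"
    return sep.join("." if a is None else str(a) for a in gt)


def read_vcf_insertions(path, convention: Convention = Convention.generic) -> Callset:
    """Read all insertion records from a VCF (gzip-transparent, via pysam).

    Every ALT longer than its REF by at least 1 bp and sharing the REF as an
    anchor prefix yields a resolved :class:`InsertionRecord`; symbolic
    ``<INS>``-style ALTs are retained as unresolved records.  Multi-allelic
    lines are split into one record per insertion ALT.  Non-insertion
    records (SNVs, deletions) are skipped; record-level REF/ALT
    inconsistencies are collected on the returned callset rather than
    aborting the read.
    """
    convention = Convention(convention)
    records: List[InsertionRecord] = []
    errors: List[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        lineno = len(str(vcf.header).rstrip("\n").split("\n"))
        it = iter(vcf)
        while True:
            lineno += 1
            try:
                rec = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise VcfParseError(f"malformed VCF line {lineno}: {exc}") from exc
            ref = (rec.ref or "N").upper()
            filt = ";".join(rec.filter.keys()) or "PASS"
            info_tags = _info_to_tags(rec)
            gt = _genotype_string(rec)
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                suffix = f"_{i}" if len(alts) > 1 else ""
                rec_id = (rec.id if rec.id else f"{rec.chrom}_{rec.pos}") + suffix
                alt = alt.upper()
                if alt.startswith("<"):
                    if alt.startswith("<INS"):
                        records.append(InsertionRecord(
                            chrom=rec.chrom, pos=rec.pos, inserted_seq="",
                            filter_field=filt, info_tags=dict(info_tags),
                            genotype=gt, record_id=rec_id, resolved=False,
                            ref_anchor=ref[:1]))
                    continue
                if not alt or set(alt) - VALID_BASES:
                    errors.append(f"line {lineno}: unparseable ALT {alt!r}")
                    continue
                if len(alt) <= len(ref):
                    continue  # SNV / deletion / same-length substitution
                if not alt.startswith(ref):
                    errors.append(
                        f"line {lineno}: ALT longer than REF but does not extend it "
                        f"(REF={ref}, ALT={alt})")
                    continue
                records.append(InsertionRecord(
                    chrom=rec.chrom, pos=rec.pos, inserted_seq=alt[len(ref):],
                    filter_field=filt, info_tags=dict(info_tags),
                    genotype=gt, record_id=rec_id, resolved=True,
                    ref_anchor=ref[:1]))
    cs = Callset(records, convention=convention, source_label=str(path))
    cs.parse_errors = errors  # type: ignore[attr-defined]
    return cs


def apply_goldstandard_filters(cs: Callset, cfg: FilterConfig) -> Tuple[Callset, Dict[str, int]]:
    """Apply the gold-standard insertion filters; returns (callset, removal counts).

    Filters (in order): core-genome chromosome allow-list, size strictly
    greater than ``min_size``, sequence-resolved, parent support (when
    required and the tag convention carries it), and — for the giab
    convention — absence of the ``LongHomRef`` FILTER label.
    """
    if cs.convention == Convention.giab and any(
            r.filter_field in ("", None) for r in cs.records):
        raise ValueError("giab filtering requires FILTER fields on every record")
    removed = {"core_genome": 0, "size": 0, "unresolved": 0,
               "parent_support": 0, "longhomref": 0}
    allow = cfg.chrom_allowlist if cfg.chrom_allowlist is not None else PRIMARY_CHROMS
    kept: List[InsertionRecord] = []
    for r in cs.records:
        if r.chrom not in allow:
            removed["core_genome"] += 1
            continue
        if not r.resolved:
            if cfg.require_sequence_resolved:
                removed["unresolved"] += 1
                continue
        elif r.size <= cfg.min_size:
            removed["size"] += 1
            continue
        if cfg.require_parent_support:
            support = r.info_tags.get(cfg.parent_support_key)
            if not _has_parent_support(support):
                removed["parent_support"] += 1
                continue
        if cfg.drop_longhomref and "LongHomRef" in (r.filter_field or ""):
            removed["longhomref"] += 1
            continue
        kept.append(r)
    return Callset(kept, convention=cs.convention, source_label=cs.source_label), removed


def _has_parent_support(value) -> bool:
    """True when at least one parental genotype in the tag carries the allele."""
    if value in (None, False, ""):
        return False
    if value is True:
        return True
    return bool(re.search(r"1", str(value)))


#: ExactMatchID method labels that refine rather than discover a call
GIAB_REFINE_PATTERN = re.compile(r"refine", re.IGNORECASE)


def parse_discovery_technology(r: InsertionRecord,
                               convention: Convention,
                               refine_pattern: re.Pattern = GIAB_REFINE_PATTERN,
                               warnings: Optional[List[str]] = None) -> Technology:
    """Classify a record's discovery technology as short-read vs other.

    chaisson: short-read iff the ``UNION`` INFO value equals ``Illumina``.
    giab: short-read iff the ``ExactMatchID`` INFO value carries an ``Ill``
    label attached to a discovery (non-refinement) method.  Missing tags are
    conservatively classified as ``other`` and a warning is collected.
    """
    convention = Convention(convention)
    if convention == Convention.chaisson:
        union = r.info_tags.get("UNION")
        if union is None:
            if warnings is not None:
                warnings.append(f"{r.record_id}: missing UNION tag")
            return Technology.other
        return Technology.short_read if str(union) == "Illumina" else Technology.other
    if convention == Convention.giab:
        emid = r.info_tags.get("ExactMatchID")
        if emid is None:
            if warnings is not None:
                warnings.append(f"{r.record_id}: missing ExactMatchID tag")
            return Technology.other
        for token in re.split(r"[,;]", str(emid)):
            for part in token.split("_"):
                if "Ill" in part and not refine_pattern.search(token):
                    return Technology.short_read
        return Technology.other
    # generic convention: an explicit TECH tag, else other
    tech = r.info_tags.get("TECH")
    if tech is None:
        if warnings is not None:
            warnings.append(f"{r.record_id}: missing TECH tag")
        return Technology.other
    return Technology.short_read if str(tech) == "short_read" else Technology.other


def _format_info(tags: Dict[str, object]) -> str:
    if not tags:
        return "."
    parts = []
    for k, v in tags.items():
        if v is True:
            parts.append(k)
        else:
            parts.append(f"{k}={v}")
    return ";".join(parts)


def write_vcf(cs: Callset, path, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write a callset as VCF 4.2; round-trips through read_vcf_insertions.

    INFO keys present on records are declared as String-typed header lines.
    Output ordering is the callset's (chrom, pos) order, so writing is
    byte-stable.
    """
    info_keys: List[str] = []
    for r in cs.records:
        for k in r.info_tags:
            if k not in info_keys:
                info_keys.append(k)
    chroms: List[str] = []
    for r in cs.records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=inschar"]
    for c in sorted(chroms):
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    for k in info_keys:
        lines.append(f'##INFO=<ID={k},Number=1,Type=String,Description="{k}">')
    filters: List[str] = []
    for r in cs.records:
        for f in (r.filter_field or "").split(";"):
            if f and f not in ("PASS", ".") and f not in filters:
                filters.append(f)
    for f in sorted(filters):
        lines.append(f'##FILTER=<ID={f},Description="{f}">')
    lines.append('##ALT=<ID=INS,Description="Insertion">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")
    for r in cs.records:
        ref = r.ref_anchor or "N"
        alt = ref + r.inserted_seq if r.resolved else "<INS>"
        lines.append("\t".join([
            r.chrom, str(r.pos), r.record_id, ref, alt, ".",
            r.filter_field or ".", _format_info(r.info_tags), "GT", r.genotype,
        ]))
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")
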