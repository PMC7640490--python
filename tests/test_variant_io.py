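import random

import pytest

from inschar import (Callset, Convention, FilterConfig, InsertionRecord,
                     Technology, apply_goldstandard_filters,
                     parse_discovery_technology, read_vcf_insertions,
                     write_vcf)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=PARENTS,Number=1,Type=String,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def _vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


def _rec(pos=100, seq="A" * 60, filt="PASS", chrom="chr1", resolved=True, **kw):
    return InsertionRecord(chrom=chrom, pos=pos, inserted_seq=seq if resolved else "",
                           filter_field=filt, resolved=resolved, **kw)


class TestReadVcf:
    def test_insertion_convention_strips_shared_anchor(self, tmp_path):
        path = _vcf(tmp_path, "chr1\t100\t.\tA\tACGT\t.\tPASS\t.\tGT\t0/1\n")
        cs = read_vcf_insertions(path)
        (r,) = cs.records
        assert (r.pos, r.inserted_seq, r.size) == (100, "CGT", 3)

    def test_empty_body_gives_empty_callset(self, tmp_path):
        cs = read_vcf_insertions(_vcf(tmp_path, ""))
        assert len(cs) == 0

    def test_toy_mix_yields_two_resolved_one_symbolic(self, toy_vcf):
        cs = read_vcf_insertions(toy_vcf, "chaisson")
        resolved = [r for r in cs if r.resolved]
        symbolic = [r for r in cs if not r.resolved]
        assert len(resolved) == 2 and len(symbolic) == 1
        assert {r.record_id for r in resolved} == {"a", "e"}
        assert symbolic[0].record_id == "d" and symbolic[0].inserted_seq == ""

    def test_multiallelic_line_splits_per_insertion_alt(self, tmp_path):
        path = _vcf(tmp_path, "chr1\t100\tm\tA\tACGT,ATTTT\t.\tPASS\t.\tGT\t1/2\n")
        cs = read_vcf_insertions(path)
        assert len(cs) == 2
        assert {r.inserted_seq for r in cs} == {"CGT", "TTTT"}
        assert {r.record_id for r in cs} == {"m_0", "m_1"}

    def test_ref_alt_disagreement_collected_not_fatal(self, tmp_path):
        path = _vcf(tmp_path,
                    "chr1\t100\t.\tA\tACGT\t.\tPASS\t.\tGT\t0/1\n"
                    "chr1\t200\t.\tAC\tGTTTT\t.\tPASS\t.\tGT\t0/1\n")
        cs = read_vcf_insertions(path)
        assert len(cs) == 1
        assert len(cs.parse_errors) == 1


class TestGoldStandardFilters:
    def test_each_removal_rule_counted(self):
        cs = Callset([
            _rec(pos=100, seq="A" * 40),
            _rec(pos=200, seq="C" * 60),
            _rec(pos=300, seq="G" * 60, filt="LongHomRef"),
            _rec(pos=400, resolved=False),
        ], convention=Convention.giab)
        cfg = FilterConfig(min_size=50, require_sequence_resolved=True,
                           drop_longhomref=True)
        out, removed = apply_goldstandard_filters(cs, cfg)
        assert len(out) == 1 and out.records[0].pos == 200
        assert removed["size"] == 1
        assert removed["longhomref"] == 1
        assert removed["unresolved"] == 1

    def test_no_thresholds_is_identity_on_resolved(self):
        cs = Callset([_rec(pos=100, seq="ACGT"), _rec(pos=200, seq="A" * 500)])
        cfg = FilterConfig(min_size=0, require_sequence_resolved=True)
        out, _ = apply_goldstandard_filters(cs, cfg)
        assert [r.pos for r in out] == [100, 200]

    def test_size_threshold_is_strict(self):
        cs = Callset([_rec(pos=1, seq="A" * 50), _rec(pos=60, seq="A" * 51)])
        out, removed = apply_goldstandard_filters(cs, FilterConfig(min_size=50))
        assert [r.pos for r in out] == [60] and removed["size"] == 1

    def test_core_genome_allowlist_drops_alt_contigs(self):
        cs = Callset([_rec(pos=100), _rec(pos=100, chrom="chr1_KI270706v1_random")])
        out, removed = apply_goldstandard_filters(cs, FilterConfig())
        assert len(out) == 1 and removed["core_genome"] == 1

    def test_parent_support_filter(self):
        cs = Callset([
            _rec(pos=100, info_tags={"PARENTS": "0/1,0/0"}),
            _rec(pos=200, info_tags={"PARENTS": "0/0,0/0"}),
            _rec(pos=300),  # tag absent
        ])
        cfg = FilterConfig(require_parent_support=True)
        out, removed = apply_goldstandard_filters(cs, cfg)
        assert [r.pos for r in out] == [100]
        assert removed["parent_support"] == 2

    def test_filtering_is_idempotent(self):
        random.seed(0)
        recs = [_rec(pos=p, seq="A" * random.randint(20, 200),
                     filt=random.choice(["PASS", "LongHomRef"]))
                for p in range(100, 5100, 100)]
        cs = Callset(recs, convention=Convention.giab)
        cfg = FilterConfig(min_size=50, drop_longhomref=True)
        once, _ = apply_goldstandard_filters(cs, cfg)
        twice, removed = apply_goldstandard_filters(once, cfg)
        assert [r.pos for r in twice] == [r.pos for r in once]
        assert all(v == 0 for v in removed.values())


class TestDiscoveryTechnology:
    def test_chaisson_union_values(self):
        assert parse_discovery_technology(
            _rec(info_tags={"UNION": "Illumina"}), "chaisson") is Technology.short_read
        assert parse_discovery_technology(
            _rec(info_tags={"UNION": "Pacbio"}), "chaisson") is Technology.other
        assert parse_discovery_technology(
            _rec(info_tags={"UNION": "Bionano"}), "chaisson") is Technology.other

    def test_giab_discovery_vs_refinement_ill_tokens(self):
        disc = _rec(info_tags={"ExactMatchID": "HG2_Ill_SVasm_77"})
        refine = _rec(info_tags={"ExactMatchID": "HG2_Ill_refine_13"})
        assert parse_discovery_technology(disc, "giab") is Technology.short_read
        assert parse_discovery_technology(refine, "giab") is Technology.other

    def test_missing_tag_classified_other_with_warning(self):
        warnings = []
        tech = parse_discovery_technology(_rec(), "chaisson", warnings=warnings)
        assert tech is Technology.other and len(warnings) == 1

    def test_partition_is_exhaustive_and_disjoint(self, toy_vcf):
        cs = read_vcf_insertions(toy_vcf, "chaisson")
        classes = [parse_discovery_technology(r, cs.convention) for r in cs]
        assert all(c in (Technology.short_read, Technology.other) for c in classes)


class TestWriteVcf:
    def test_round_trip_preserves_fields(self, tmp_path):
        cs = Callset([
            _rec(pos=100, seq="ACGTACGT", filt="PASS", genotype="1/1",
                 record_id="x", info_tags={"TYPE": "novel_sequence"}),
            _rec(pos=500, resolved=False, record_id="y", genotype="0/1"),
        ])
        path = tmp_path / "out.vcf"
        write_vcf(cs, path, {"chr1": 10_000})
        back = read_vcf_insertions(path)
        for a, b in zip(cs.records, back.records):
            assert (a.pos, a.inserted_seq, a.filter_field, a.genotype,
                    a.resolved) == (b.pos, b.inserted_seq, b.filter_field,
                                    b.genotype, b.resolved)

    def test_empty_callset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf(Callset([]), path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []

    def test_output_is_byte_stable(self, tmp_path):
        random.seed(1)
        recs = [_rec(pos=p, seq="".join(random.choice("ACGT") for _ in range(60)),
                     record_id=f"r{p}")
                for p in range(1000, 101000, 1000)]
        cs = Callset(recs)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(cs, p1)
        write_vcf(cs, p2)
        assert p1.read_bytes() == p2.read_bytes()
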