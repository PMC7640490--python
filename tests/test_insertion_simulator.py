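import pytest

from inschar import (ClassifierConfig, MatchConfig, apply_insertions,
                     build_scenario_suite, classify_callset,
                     find_tandem_structure, generate_insertions,
                     junctional_homology_size, match_and_score,
                     read_vcf_insertions, truth_to_callset, write_truth_vcf)
from inschar.insertion_simulator import ScenarioSpec, TruthRecord, TruthSet


class TestSuiteEnumeration:
    def test_default_suite_has_22_datasets(self):
        specs = build_scenario_suite()
        assert len(specs) == 22
        assert all(s.n_insertions == 200 for s in specs)
        assert len({s.name for s in specs}) == 22

    def test_size_scenario_alone_gives_three(self):
        specs = build_scenario_suite(scenarios=["size"])
        assert [s.parameter for s in specs] == [50, 500, 1000]

    def test_single_homology_config(self):
        specs = build_scenario_suite(scenarios=["homology"], homologies=[10])
        assert len(specs) == 1 and specs[0].parameter == 10

    def test_illegal_parameter_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("size", 123)
        with pytest.raises(ValueError):
            ScenarioSpec("noscenario", None)


class TestGenerateInsertions:
    def test_baseline_sites_exonic_sizes_250_homology_zero(self, synth):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec("baseline", None, 25, 5),
                                 genome, tracks, lib)
        assert len(ts) == 25
        assert all(r.size == 250 for r in ts)
        assert all(tracks.overlaps("exons", r.chrom, r.zero_based_site)
                   for r in ts)
        homs = [junctional_homology_size(rec, genome)
                for rec in truth_to_callset(ts, genome).records]
        assert all(h.total_size == 0 for h in homs)

    def test_size_scenario_keeps_baseline_sites(self, synth):
        genome, tracks, lib = synth
        base = generate_insertions(ScenarioSpec("baseline", None, 20, 5),
                                   genome, tracks, lib)
        sized = generate_insertions(ScenarioSpec("size", 500, 20, 5),
                                    genome, tracks, lib)
        assert [r.pos for r in sized] == [r.pos for r in base]
        assert all(r.size == 500 for r in sized)

    def test_tandem_repeat_scenario_is_periodic_and_classified(self, synth):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec("type", "tr_seed6", 15, 5),
                                 genome, tracks, lib)
        for r in ts:
            ann = find_tandem_structure(r.inserted_seq)
            assert ann and ann[0].seed_size == 6
        df = classify_callset(truth_to_callset(ts, genome), genome, lib)
        assert (df["label"] == "tandem_repeat").all()

    def test_type_scenarios_recovered_by_classifier(self, synth):
        genome, tracks, lib = synth
        expected = {"tandem_dup": "tandem_duplication",
                    "mobile_element": "mobile_element",
                    "dispersed_dup": "dispersed_duplication"}
        for param, label in expected.items():
            ts = generate_insertions(ScenarioSpec("type", param, 10, 5),
                                     genome, tracks, lib)
            df = classify_callset(truth_to_callset(ts, genome), genome, lib)
            assert (df["label"] == label).mean() >= 0.99, param

    @pytest.mark.parametrize("x", [10, 20, 50, 100, 150])
    def test_homology_scenario_reports_exactly_x_on_right(self, synth, x):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec("homology", x, 12, 5),
                                 genome, tracks, lib)
        for rec in truth_to_callset(ts, genome).records:
            h = junctional_homology_size(rec, genome)
            assert h.right_size == x
            assert h.total_size == x

    def test_context_scenarios_place_sites_in_requested_class(self, synth):
        genome, tracks, lib = synth
        for param, track, check in [
                ("sine", "sines", None),
                ("line", "lines", None),
                ("simple_repeat_small", "simple_repeats", lambda s: s < 300),
                ("simple_repeat_large", "simple_repeats", lambda s: s > 300)]:
            ts = generate_insertions(ScenarioSpec("context", param, 10, 5),
                                     genome, tracks, lib)
            ivs = [(s, e) for c, s, e in tracks.intervals(track)
                   if check is None or check(e - s)]
            for r in ts:
                assert any(s <= r.zero_based_site < e for s, e in ivs), param

    def test_proximal_scenario_pairs_within_150bp(self, synth):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec("context", "proximal", 20, 5),
                                 genome, tracks, lib)
        assert len(ts) == 20
        gaps = [b.pos - a.pos for a, b in zip(ts.records[::2], ts.records[1::2])]
        assert all(5 <= g <= 150 for g in gaps)

    def test_real_scenarios_use_source_callset(self, synth, labeled):
        genome, tracks, lib = synth
        src, _ = labeled
        at_sites = generate_insertions(ScenarioSpec("real", "real_at_real_sites",
                                                    10, 5),
                                       genome, tracks, lib, src)
        src_keys = {(r.pos, r.inserted_seq) for r in src}
        assert all((r.pos, r.inserted_seq) in src_keys for r in at_sites)
        novel = generate_insertions(ScenarioSpec("real", "novel_at_real_sites",
                                                 10, 5),
                                    genome, tracks, lib, src)
        assert [r.pos for r in novel] == [r.pos for r in at_sites]
        assert all((r.pos, r.inserted_seq) not in src_keys for r in novel)
        with pytest.raises(ValueError):
            generate_insertions(ScenarioSpec("real", "real_in_exons", 10, 5),
                                genome, tracks, lib, None)


class TestApplyInsertions:
    def test_length_conservation_single(self):
        ts = TruthSet([TruthRecord("c", 400, "G" * 250, "novel_sequence", 0, "x")])
        out = apply_insertions({"c": "A" * 1000}, ts)
        assert len(out["c"]) == 1250

    def test_matches_naive_left_to_right_rebuild(self):
        seq = "ACGT" * 250
        recs = [TruthRecord("c", 100, "TTTT", "novel_sequence", 0, "x"),
                TruthRecord("c", 600, "GGGGGG", "novel_sequence", 0, "x")]
        out = apply_insertions({"c": seq}, TruthSet(recs))
        naive = seq[:100] + "TTTT" + seq[100:600] + "GGGGGG" + seq[600:]
        assert out["c"] == naive

    def test_empty_truth_set_is_identity(self):
        out = apply_insertions({"c": "ACGT" * 100}, TruthSet([]))
        assert out["c"] == "ACGT" * 100

    def test_round_trip_extraction_recovers_sequences(self, synth):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec("baseline", None, 15, 5),
                                 genome, tracks, lib)
        chrom = genome.chroms()[0]
        out = apply_insertions(genome, ts)[chrom]
        shift = 0
        for r in ts.records:  # sorted by position
            i = r.zero_based_site + shift
            assert out[i:i + r.size] == r.inserted_seq
            shift += r.size

    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError):
            TruthSet([TruthRecord("c", 100, "AAAA", "t", 0, "x"),
                      TruthRecord("c", 100, "CCCC", "t", 0, "x")])


class TestTruthVcf:
    def test_homozygous_labels_and_round_trip(self, synth, tmp_path):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec("homology", 20, 10, 5),
                                 genome, tracks, lib)
        path = tmp_path / "truth.vcf"
        write_truth_vcf(ts, genome, path)
        back = read_vcf_insertions(path)
        assert len(back) == len(ts)
        for got, want in zip(back.records, ts.records):
            assert got.genotype == "1/1"
            assert got.pos == want.pos
            assert got.inserted_seq == want.inserted_seq
            assert got.info_tags["TYPE"] == want.ins_type
            assert int(got.info_tags["HOMLEN"]) == 20

    def test_byte_identical_for_same_spec_and_seed(self, synth, tmp_path):
        genome, tracks, lib = synth
        spec = ScenarioSpec("baseline", None, 10, 9)
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_truth_vcf(generate_insertions(spec, genome, tracks, lib), genome, a)
        write_truth_vcf(generate_insertions(spec, genome, tracks, lib), genome, b)
        assert a.read_bytes() == b.read_bytes()


class TestSelfConsistency:
    @pytest.mark.parametrize("scenario,param", [
        ("baseline", None), ("type", "tandem_dup"), ("homology", 50),
        ("context", "proximal")])
    def test_truth_as_calls_scores_perfect(self, synth, scenario, param):
        genome, tracks, lib = synth
        ts = generate_insertions(ScenarioSpec(scenario, param, 14, 5),
                                 genome, tracks, lib)
        rep = match_and_score(ts, truth_to_callset(ts, genome),
                              MatchConfig(), genome)
        assert rep.recall_site == 1.0
        assert rep.recall_seq == 1.0
        assert rep.n_fp == 0
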