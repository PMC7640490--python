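import random

import pytest

from inschar import (Callset, GenomeIndex, InsertionRecord, MatchConfig,
                     combine_callsets, filter_calls, match_and_score,
                     resolve_symbolic)
from inschar.insertion_simulator import TruthRecord, TruthSet

MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


def call(pos, seq, filt="PASS", chrom="chr3", rid=None, **kw):
    return InsertionRecord(chrom=chrom, pos=pos, inserted_seq=seq,
                           filter_field=filt,
                           record_id=rid or f"c{pos}", **kw)


def truth_of(*recs):
    return TruthSet([TruthRecord("chr3", p, s, "novel_sequence", 0, "x")
                     for p, s in recs])


class TestFilterCalls:
    def test_pass_and_size_rules(self):
        cs = Callset([call(100, "A" * 60), call(300, "A" * 40),
                      call(500, "A" * 60, filt="LowQual")])
        kept = filter_calls(cs, MatchConfig())
        assert [r.pos for r in kept] == [100]

    def test_disabling_pass_only_keeps_low_quality(self):
        cs = Callset([call(100, "A" * 60), call(300, "A" * 40),
                      call(500, "A" * 60, filt="LowQual")])
        kept = filter_calls(cs, MatchConfig(pass_only=False))
        assert [r.pos for r in kept] == [100, 500]

    def test_empty(self):
        assert len(filter_calls(Callset([]), MatchConfig())) == 0


@pytest.fixture(scope="module")
def ref():
    rng = random.Random(0)
    return GenomeIndex({"chr3": rand_seq(rng, 10_000)})


class TestResolveSymbolic:

    def test_duplicated_copy_coordinates_resolve_sequence(self, ref):
        c = InsertionRecord(chrom="chr3", pos=100, inserted_seq="",
                            resolved=False,
                            info_tags={"DUP_CHROM": "chr3", "DUP_START": "2001",
                                       "DUP_END": "2250"})
        out = resolve_symbolic(c, ref)
        assert out.resolved and out.size == 250
        assert out.inserted_seq == ref.fetch("chr3", 2000, 2250)

    def test_malformed_coordinates_stay_unresolved(self, ref):
        c = InsertionRecord(chrom="chr3", pos=100, inserted_seq="",
                            resolved=False,
                            info_tags={"DUP_CHROM": "chr3", "DUP_START": "xx",
                                       "DUP_END": "2250"})
        assert not resolve_symbolic(c, ref).resolved

    def test_resolved_symbolic_counts_as_sequence_tp(self, ref):
        seq = ref.fetch("chr3", 2000, 2250)
        truth = truth_of((5000, seq))
        sym = InsertionRecord(chrom="chr3", pos=5000, inserted_seq="",
                              resolved=False,
                              info_tags={"DUP_CHROM": "chr3",
                                         "DUP_START": "2001",
                                         "DUP_END": "2250"})
        rep = match_and_score(truth, Callset([sym]), MatchConfig(), ref)
        assert rep.n_tp_seq == 1


class TestMatchAndScore:
    def test_site_margin_boundary(self):
        rng = random.Random(1)
        seq = rand_seq(rng, 250)
        truth = truth_of((1000, seq))
        inside = match_and_score(truth, Callset([call(1010, seq)]))
        outside = match_and_score(truth, Callset([call(1011, seq)]))
        assert inside.n_tp_site == 1 and inside.n_fp == 0
        assert outside.n_tp_site == 0 and outside.n_fp == 1

    def test_size_tolerance_boundary(self):
        rng = random.Random(2)
        seq = rand_seq(rng, 250)
        truth = truth_of((1000, seq))
        ok = match_and_score(truth, Callset([call(1000, seq + rand_seq(rng, 25))]))
        too_big = match_and_score(truth,
                                  Callset([call(1000, seq + rand_seq(rng, 26))]))
        assert ok.n_tp_seq == 1
        assert too_big.n_tp_seq == 0 and too_big.n_tp_site == 1

    def test_identity_boundary_at_090(self):
        rng = random.Random(3)
        seq = rand_seq(rng, 250)
        truth = truth_of((1000, seq))
        at = list(seq)
        for i in rng.sample(range(250), 25):
            at[i] = MUT[at[i]]
        below = list(seq)
        for i in rng.sample(range(250), 26):
            below[i] = MUT[below[i]]
        assert match_and_score(truth, Callset([call(1000, "".join(at))])).n_tp_seq == 1
        assert match_and_score(truth, Callset([call(1000, "".join(below))])).n_tp_seq == 0

    def test_truth_fed_as_calls_is_perfect(self):
        rng = random.Random(4)
        recs = [(p, rand_seq(rng, 250)) for p in range(1000, 11000, 1000)]
        truth = truth_of(*recs)
        calls = Callset([call(p, s) for p, s in recs])
        rep = match_and_score(truth, calls)
        assert rep.recall_site == rep.recall_seq == 1.0
        assert rep.n_fp == 0

    def test_one_to_one_matching_no_double_counting(self):
        rng = random.Random(5)
        seq = rand_seq(rng, 250)
        truth = truth_of((1000, seq), (1008, seq))
        calls = Callset([call(1004, seq)])
        rep = match_and_score(truth, calls)
        assert rep.n_tp_site == 1  # one call cannot validate two truths

    def test_chromosome_mismatch_raises(self):
        rng = random.Random(6)
        truth = truth_of((1000, rand_seq(rng, 250)))
        calls = Callset([call(1000, rand_seq(rng, 250), chrom="chrX")])
        with pytest.raises(ValueError, match="chromosome"):
            match_and_score(truth, calls)

    def test_stable_under_call_permutation(self):
        rng = random.Random(7)
        recs = [(p, rand_seq(rng, 100)) for p in range(1000, 6000, 1000)]
        truth = truth_of(*recs)
        calls = [call(p + rng.randrange(-8, 9), s, rid=f"r{i}")
                 for i, (p, s) in enumerate(recs)]
        a = match_and_score(truth, Callset(list(calls)))
        b = match_and_score(truth, Callset(list(reversed(calls))))
        assert a.tp_site_truth_indices == b.tp_site_truth_indices


@pytest.fixture(scope="module")
def noisy():
    rng = random.Random(8)
    recs = [(p, rand_seq(rng, 200)) for p in range(1000, 41000, 1000)]
    truth = truth_of(*recs)
    calls = []
    for i, (p, s) in enumerate(recs):
        mutated = list(s)
        for j in rng.sample(range(200), rng.randrange(0, 40)):
            mutated[j] = MUT[mutated[j]]
        calls.append(call(p + rng.randrange(-15, 16), "".join(mutated),
                          filt=rng.choice(["PASS", "LowQual"]), rid=f"r{i}"))
    return truth, Callset(calls)


class TestMonotonicityInvariants:

    def test_recall_seq_never_exceeds_recall_site(self, noisy):
        truth, calls = noisy
        rep = match_and_score(truth, calls)
        assert rep.recall_seq <= rep.recall_site

    def test_disabling_pass_only_never_decreases_recall(self, noisy):
        truth, calls = noisy
        strict = match_and_score(truth, calls, MatchConfig(pass_only=True))
        loose = match_and_score(truth, calls, MatchConfig(pass_only=False))
        assert loose.recall_site >= strict.recall_site
        assert loose.recall_seq >= strict.recall_seq

    def test_widening_margin_never_decreases_site_recall(self, noisy):
        truth, calls = noisy
        recalls = [match_and_score(truth, calls,
                                   MatchConfig(site_margin=m)).recall_site
                   for m in (0, 5, 10, 20)]
        assert recalls == sorted(recalls)

    def test_tightening_identity_never_increases_seq_recall(self, noisy):
        truth, calls = noisy
        recalls = [match_and_score(truth, calls,
                                   MatchConfig(min_identity=x)).recall_seq
                   for x in (0.80, 0.90, 0.99)]
        assert recalls == sorted(recalls, reverse=True)


class TestCombineCallsets:
    def _truth_and_calls(self):
        rng = random.Random(9)
        recs = [(p, rand_seq(rng, 150)) for p in range(1000, 4000, 1000)]
        truth = truth_of(*recs)
        full = [call(p, s, rid=f"r{p}") for p, s in recs]
        return truth, recs, full

    def test_identical_callsets_union_equals_intersection(self):
        truth, _, full = self._truth_and_calls()
        rep = combine_callsets({"a": Callset(list(full)),
                                "b": Callset(list(full)),
                                "c": Callset(list(full))}, truth)
        assert rep.union_count == rep.intersection_count == 3
        assert rep.k_of_n == {3: 3}

    def test_disjoint_tp_sets(self):
        truth, recs, full = self._truth_and_calls()
        rep = combine_callsets({"a": Callset([full[0]]),
                                "b": Callset([full[1]]),
                                "c": Callset([full[2]])}, truth)
        assert rep.intersection_count == 0
        assert rep.union_count == 3
        assert rep.k_of_n == {1: 3}

    def test_subset_union_equals_superset(self):
        truth, recs, full = self._truth_and_calls()
        rep = combine_callsets({"a": Callset([full[0]]),
                                "b": Callset(list(full))}, truth)
        assert rep.union_count == 3
        assert rep.per_tool["b"].n_tp_site == 3

    def test_requires_two_callsets(self):
        truth, _, full = self._truth_and_calls()
        with pytest.raises(ValueError):
            combine_callsets({"a": Callset(full)}, truth)
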