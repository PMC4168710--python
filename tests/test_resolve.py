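import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxmerge.kmer import build_kmer_table
from ctxmerge.resolve import (
    ContextVote,
    MergeParams,
    collect_context_votes,
    context_pass,
    decide,
    quality_pass,
)
from oracles import brute_force_context_windows


def test_default_params():
    p = MergeParams()
    assert (p.k, p.omega, p.gamma, p.delta) == (17, 10, 0.5, 19)
    assert p.quality_weighted_vote is False


@pytest.mark.parametrize(
    "bad",
    [dict(k=0), dict(omega=0), dict(gamma=1.5), dict(gamma=-0.1), dict(delta=-1)],
)
def test_param_validation(bad):
    with pytest.raises(ValueError):
        MergeParams(**bad)


class TestQualityPass:
    def test_decisive_forward_quality_overwrites(self):
        x, qx = list("ACGT"), [40, 40, 40, 40]
        y, qy = list("ACGA"), [10, 10, 10, 10]
        quality_pass(x, qx, y, qy, 1, delta=19)
        assert "".join(y) == "ACGT" and qy[3] == 40

    def test_difference_exactly_delta_is_left_for_context(self):
        x, qx = list("A"), [30]
        y, qy = list("C"), [11]
        quality_pass(x, qx, y, qy, 1, delta=19)
        assert (x[0], y[0]) == ("A", "C")

    def test_decisive_reverse_quality_overwrites(self):
        x, qx = list("A"), [5]
        y, qy = list("C"), [40]
        quality_pass(x, qx, y, qy, 1, delta=19)
        assert (x[0], qx[0]) == ("C", 40)

    def test_one_sided_n_is_always_informative(self):
        x, qx = list("N"), [40]
        y, qy = list("C"), [2]
        quality_pass(x, qx, y, qy, 1, delta=19)
        assert (x[0], qx[0]) == ("C", 2)

    def test_double_n_is_skipped(self):
        x, qx = list("N"), [0]
        y, qy = list("N"), [0]
        quality_pass(x, qx, y, qy, 1, delta=19)
        assert (x[0], y[0]) == ("N", "N")

    def test_matching_bases_untouched(self):
        x, qx = list("AC"), [40, 5]
        y, qy = list("AC"), [2, 40]
        quality_pass(x, qx, y, qy, 1, delta=19)
        assert qx == [40, 5] and qy == [2, 40]


class TestContextVotes:
    def test_k1_degenerate_single_base_window(self):
        table = build_kmer_table(["A", "A", "C"], 1)
        votes = collect_context_votes("A", "C", 1, 1, table)
        assert len(votes) == 1
        assert votes[0] == ContextVote(1, 2, 1, "forward")

    def test_downstream_mismatch_stops_scan_after_j1(self):
        # mismatch at position 1; position 2 also mismatches -> only j=1 window
        table = build_kmer_table(["AT", "CG"], 2)
        # mismatch at i=2; x(3) != y(3) so j=2 breaks and only j=1 survives
        votes = collect_context_votes("GAT", "GCG", 2, 2, table)
        assert [v.j for v in votes] == [1]

    def test_left_boundary_skip_keeps_later_windows(self):
        # constructed 12 bp example: Y's window underruns for small j
        x = "ACGTACGTACGT"
        y = "GTACGTACGT"
        i, i_prime, k = 5, 3, 4
        table = build_kmer_table([x, y], k)
        votes = collect_context_votes(x, y, i, i_prime, table)
        surviving = brute_force_context_windows(x, y, i, i_prime, k)
        assert [v.j for v in votes] == [j for j, _, _ in surviving]
        assert all(j > 1 for j, _, _ in surviving)  # j=1 underran Y's left end

    def test_windows_match_bruteforce_enumerator_on_random_mismatches(self):
        rng = random.Random(3)
        k = 4
        for _ in range(300):
            n = rng.randint(k, 20)
            x = "".join(rng.choice("ACGT") for _ in range(n))
            y = "".join(rng.choice("ACGT") for _ in range(n))
            i = rng.randint(1, n)
            i_prime = rng.randint(1, n)
            table = build_kmer_table([x, y], k)
            votes = collect_context_votes(x, y, i, i_prime, table)
            expected = brute_force_context_windows(x, y, i, i_prime, k)
            assert [(v.j, v.forward_count, v.reverse_count) for v in votes] == [
                (j, table.lookup(wx), table.lookup(wy)) for j, wx, wy in expected
            ]


class TestDecide:
    def _votes(self, labels):
        return [ContextVote(j + 1, 0, 0, v) for j, v in enumerate(labels)]

    def test_majority_forward(self):
        assert decide(self._votes(["forward", "forward", "reverse"])) == "forward"

    def test_tie_goes_to_reverse(self):
        assert decide(self._votes(["forward", "reverse"])) == "reverse"

    def test_empty_goes_to_reverse(self):
        assert decide([]) == "reverse"

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from(["forward", "reverse"]), min_size=1, max_size=17))
    def test_equivalent_to_mean_threshold_when_all_votes_cast(self, votes):
        # linear-opinion-pool identity: forward wins iff mean(d_j) > 1/2
        d = [1 if v == "forward" else 0 for v in votes]
        pool = "forward" if sum(d) / len(d) > 0.5 else "reverse"
        assert decide(self._votes(votes)) == pool


class TestContextPass:
    def test_lone_error_loses_every_vote(self):
        fragment = "ACGTACGTACGT"
        clean = [fragment] * 5
        x = list("ACGAACGTACGT")  # error at position 4 (T -> A)
        y = list(fragment)
        table = build_kmer_table(clean + ["".join(x), "".join(y)], 3)
        qx, qy = [20] * 12, [20] * 12
        context_pass(x, qx, y, qy, 1, table, MergeParams(k=3))
        assert "".join(x) == fragment and "".join(y) == fragment

    def test_left_to_right_resolution_unlocks_later_windows(self):
        fragment = "ACGTACGTACGT"
        clean = [fragment] * 5
        x = list("ACAAACGTACGT")  # two adjacent errors at positions 3 and 4
        y = list(fragment)
        table = build_kmer_table(clean + ["".join(x), fragment], 3)
        qx, qy = [20] * 12, [20] * 12
        log = []
        context_pass(x, qx, y, qy, 1, table, MergeParams(k=3), decision_log=log)
        assert "".join(x) == fragment
        # second mismatch saw more than the single j=1 window once the first
        # was corrected
        assert len(log) == 2
        assert len(log[1][2]) > 1

    def test_huge_delta_sends_everything_to_context(self):
        x, qx = list("ACGT"), [41, 41, 41, 41]
        y, qy = list("ACGA"), [2, 2, 2, 2]
        quality_pass(x, qx, y, qy, 1, delta=1000)
        assert "".join(y) == "ACGA"  # quality pass was a no-op
        table = build_kmer_table(["ACGT"] * 3 + ["ACGA"], 2)
        context_pass(x, qx, y, qy, 1, table, MergeParams(k=2, delta=1000))
        assert "".join(x) == "".join(y)

    def test_completeness_and_idempotence(self, rng):
        # after the two passes every overlap position matches or is double-N;
        # a second context pass changes nothing
        for _ in range(50):
            n = rng.randint(6, 20)
            x = [rng.choice("ACGTN") for _ in range(n)]
            y = [rng.choice("ACGTN") for _ in range(n)]
            qx = [rng.randint(0, 41) for _ in range(n)]
            qy = [rng.randint(0, 41) for _ in range(n)]
            b = rng.randint(1, n)
            table = build_kmer_table(["".join(x), "".join(y)], 3)
            params = MergeParams(k=3)
            quality_pass(x, qx, y, qy, b, params.delta)
            context_pass(x, qx, y, qy, b, table, params)
            length = min(n - b + 1, n)
            for t in range(length):
                assert x[b - 1 + t] == y[t] or (x[b - 1 + t] == "N" and y[t] == "N")
            snapshot = (list(x), list(qx), list(y), list(qy))
            context_pass(x, qx, y, qy, b, table, params)
            assert (x, qx, y, qy) == snapshot


class TestQualityWeightedVote:
    def test_differs_only_when_counts_within_quality_ratio(self):
        # forward count 3 vs reverse 2: unweighted vote is forward; the
        # weighted vote flips only because the quality ratio exceeds 2/3
        table = build_kmer_table(["AA"] * 3 + ["AC"] * 2, 2)
        plain = collect_context_votes("AA", "AC", 2, 2, table)
        weighted = collect_context_votes(
            "AA", "AC", 2, 2, table, q_x_i=40, q_y_i=10, quality_weighted=True
        )
        assert plain[0].vote == "forward"
        # forward weight 1e-4, reverse 1e-1: 3e-4 < 2e-1 -> reverse
        assert weighted[0].vote == "reverse"

    def test_agrees_when_quality_equal(self):
        table = build_kmer_table(["AA"] * 3 + ["AC"] * 2, 2)
        plain = collect_context_votes("AA", "AC", 2, 2, table)
        weighted = collect_context_votes(
            "AA", "AC", 2, 2, table, q_x_i=30, q_y_i=30, quality_weighted=True
        )
        assert plain[0].vote == weighted[0].vote
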