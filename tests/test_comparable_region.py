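"""LCS anchoring, extension strategies and alignment modes."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcfkit.comparable_region import (
    ComparableRegion,
    LcsCandidate,
    apply_mode,
    comparable_region,
    extend,
    find_lcs,
    select_lcs,
)

from conftest import make_string, random_string_pair


def brute_force_maximal_runs(a, b):
    """Independent oracle: enumerate all (i, j, l) triples and keep the
    inextensible common runs."""
    runs = set()
    for i in range(len(a)):
        for j in range(len(b)):
            l = 0
            while i + l < len(a) and j + l < len(b) and a[i + l] == b[j + l]:
                l += 1
            if l == 0:
                continue
            left_ext = i > 0 and j > 0 and a[i - 1] == b[j - 1]
            if not left_ext:
                runs.add((i, j, l))
    return runs


class TestFindLcs:
    def test_single_forward_run(self):
        A = make_string("A", ["KS", "AT", "KR", "ACP"])
        B = make_string("B", ["C", "A", "KS", "AT", "KR", "PCP"])
        candidates = find_lcs(A, B)
        forward = [c for c in candidates if not c.reverse]
        best = max(forward, key=lambda c: c.length)
        assert (best.a_start, best.b_start, best.length) == (0, 2, 3)

    def test_reversed_match(self):
        A = make_string("A", ["X", "Y", "Z"])
        B = make_string("B", ["Z", "Y", "X"])
        candidates = find_lcs(A, B)
        rev = [c for c in candidates if c.reverse]
        assert max(c.length for c in rev) == 3

    def test_no_common_token_gives_zero_candidate(self):
        A = make_string("A", ["X"])
        B = make_string("B", ["Q"])
        candidates = find_lcs(A, B)
        assert candidates == [LcsCandidate(0, 0, 0, False, False)]

    def test_empty_string_rejected(self):
        A = make_string("A", ["X"])
        E = make_string("E", [])
        with pytest.raises(ValueError):
            find_lcs(A, E)

    def test_core_flag_from_either_record(self):
        A = make_string("A", ["KS", "AT"], core=[False, False])
        B = make_string("B", ["KS", "AT"], core=[True, False])
        (cand,) = [c for c in find_lcs(A, B) if not c.reverse and c.length == 2]
        assert cand.contains_core

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_bruteforce_enumeration(self, data):
        alphabet = ["a", "b", "c", "d", "e"]
        a = data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=12))
        b = data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=12))
        A, B = make_string("A", a), make_string("B", b)
        got_fwd = {
            (c.a_start, c.b_start, c.length)
            for c in find_lcs(A, B)
            if not c.reverse and c.length > 0
        }
        assert got_fwd == brute_force_maximal_runs(a, b)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_reversal_consistency(self, data):
        alphabet = ["a", "b", "c"]
        a = data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=10))
        b = data.draw(st.lists(st.sampled_from(alphabet), min_size=1, max_size=10))
        A, B = make_string("A", a), make_string("B", b)
        B_rev = make_string("B", b[::-1])
        rev_cands = {
            (c.a_start, c.b_start, c.length)
            for c in find_lcs(A, B)
            if c.reverse and c.length > 0
        }
        fwd_on_reversed = {
            (c.a_start, c.b_start, c.length)
            for c in find_lcs(A, B_rev)
            if not c.reverse and c.length > 0
        }
        assert rev_cands == fwd_on_reversed


class TestSelectLcs:
    def test_core_preferred_over_longer_noncore(self):
        noncore = LcsCandidate(0, 0, 4, False, False)
        core = LcsCandidate(5, 5, 3, True, False)
        assert select_lcs([noncore, core]) == core

    def test_single_candidate_is_identity(self):
        c = LcsCandidate(1, 2, 3, False, False)
        assert select_lcs([c]) == c

    def test_central_candidate_wins_ties(self):
        # record A of length 20: run at 9 is more central than run at 0
        edge = LcsCandidate(0, 0, 3, True, False)
        central = LcsCandidate(9, 5, 3, True, False)
        assert select_lcs([edge, central], a_len=20) == central

    def test_forward_preferred_over_reverse(self):
        fwd = LcsCandidate(0, 0, 3, False, False)
        rev = LcsCandidate(0, 0, 3, False, True)
        assert select_lcs([fwd, rev], a_len=6) == fwd


class TestExtend:
    A_TOKENS = ["X", "KS", "AT", "Y", "TE"]
    B_TOKENS = ["KS", "AT", "Q", "TE"]
    LCS = LcsCandidate(1, 0, 2, False, False)  # the KS,AT run

    def test_identical_strings_full_region(self):
        tokens = ["KS", "AT", "KR", "ACP"]
        A, B = make_string("A", tokens), make_string("B", tokens)
        lcs = select_lcs(find_lcs(A, B), a_len=4)
        for strategy in ("legacy", "simple_match", "greedy"):
            region = extend(A, B, lcs, strategy)
            assert (region.a_start, region.a_stop) == (0, 4)
            assert (region.b_start, region.b_stop) == (0, 4)

    def test_greedy_extends_to_outermost_shared_token(self):
        A = make_string("A", self.A_TOKENS)
        B = make_string("B", self.B_TOKENS)
        region = extend(A, B, self.LCS, "greedy")
        assert (region.a_start, region.a_stop) == (1, 5)
        assert (region.b_start, region.b_stop) == (0, 4)

    def test_simple_match_walk(self):
        # right walk on A: Y -> -3, TE -> +5; running max +2 at TE => include both
        A = make_string("A", self.A_TOKENS)
        B = make_string("B", self.B_TOKENS)
        region = extend(A, B, self.LCS, "simple_match")
        assert (region.a_start, region.a_stop) == (1, 5)
        assert (region.b_start, region.b_stop) == (0, 4)

    def test_legacy_charges_gaps(self):
        # A right arm [Z, TE]: TE consumes B's TE at index 3, skipping Q:
        # score = -3 (Z) + 5 (TE) - 2 (one skipped) = 0, not > 0 => no extension
        A = make_string("A", ["KS", "AT", "Z", "TE"])
        B = make_string("B", ["KS", "AT", "Q", "TE"])
        lcs = LcsCandidate(0, 0, 2, False, False)
        region = extend(A, B, lcs, "legacy")
        # B's own walk: Q -> -3, TE -> +5 with one skip (Z) = 0: also no move
        assert (region.a_stop, region.b_stop) == (2, 2)
        # simple_match ignores the gap charge and extends
        region_sm = extend(A, B, lcs, "simple_match")
        assert (region_sm.a_stop, region_sm.b_stop) == (4, 4)

    def test_zero_length_lcs_degenerate(self):
        A = make_string("A", ["X"])
        B = make_string("B", ["Q"])
        region = extend(A, B, LcsCandidate(0, 0, 0, False, False), "legacy")
        assert region.is_empty


class TestApplyMode:
    def region(self, *args, reverse=False):
        return ComparableRegion(*args, reverse=reverse)

    def test_global_ignores_region(self):
        A = make_string("A", ["X"] * 7)
        B = make_string("B", ["X"] * 5)
        out = apply_mode(A, B, self.region(2, 3, 1, 2), "global")
        assert (out.a_start, out.a_stop, out.b_start, out.b_stop) == (0, 7, 0, 5)

    def test_local_unchanged(self):
        A = make_string("A", ["X"] * 7)
        B = make_string("B", ["X"] * 5)
        r = self.region(2, 3, 1, 2)
        assert apply_mode(A, B, r, "local") == r

    def test_glocal_extends_shorter_arm(self):
        # left arms: A has 2 remaining, B has 5 -> extend A only on the left
        A = make_string("A", ["X"] * 10)
        B = make_string("B", ["X"] * 10)
        out = apply_mode(A, B, self.region(2, 10, 5, 10), "glocal")
        assert out.a_start == 0
        assert out.b_start == 5

    def test_glocal_fallback_to_global_when_degenerate(self):
        A = make_string("A", ["X", "Y"])
        B = make_string("B", ["Q"])
        degenerate = self.region(0, 0, 0, 0)
        out = apply_mode(A, B, degenerate, "glocal")
        assert (out.a_start, out.a_stop, out.b_start, out.b_stop) == (0, 2, 0, 1)

    def test_no_shared_tokens_local_empty(self):
        A = make_string("A", ["X"])
        B = make_string("B", ["Q"])
        out = apply_mode(A, B, self.region(0, 0, 0, 0), "local")
        assert out.is_empty


class TestContainmentChain:
    """LCS span ⊆ local ⊆ glocal ⊆ global, per record and per side."""

    @pytest.mark.parametrize("strategy", ["legacy", "simple_match", "greedy"])
    def test_containment_and_strategy_ordering(self, strategy):
        rng = random.Random(11)
        for _ in range(120):
            A, B = random_string_pair(rng)
            anchor = select_lcs(find_lcs(A, B), a_len=len(A))
            local = apply_mode(A, B, extend(A, B, anchor, strategy), "local")
            glocal = apply_mode(A, B, extend(A, B, anchor, strategy), "glocal")
            if anchor.length > 0:
                assert local.a_start <= anchor.a_start
                assert local.a_stop >= anchor.a_start + anchor.length
                assert glocal.a_start <= local.a_start <= local.a_stop <= glocal.a_stop
                assert glocal.b_start <= local.b_start <= local.b_stop <= glocal.b_stop
            assert 0 <= glocal.a_start <= glocal.a_stop <= len(A)
            assert 0 <= glocal.b_start <= glocal.b_stop <= len(B)

    def test_greedy_at_least_as_wide_as_simple_match(self):
        rng = random.Random(13)
        for _ in range(120):
            A, B = random_string_pair(rng)
            anchor = select_lcs(find_lcs(A, B), a_len=len(A))
            if anchor.length == 0:
                continue
            greedy = extend(A, B, anchor, "greedy")
            simple = extend(A, B, anchor, "simple_match")
            assert (greedy.a_stop - greedy.a_start) >= (simple.a_stop - simple.a_start)
            assert (greedy.b_stop - greedy.b_start) >= (simple.b_stop - simple.b_start)
            assert (simple.a_stop - simple.a_start) >= anchor.length


def test_full_pipeline_identical_records():
    tokens = ["KS", "AT", "KR", "ACP", "TE"]
    A = make_string("A", tokens)
    B = make_string("B", tokens)
    for mode in ("global", "glocal", "local"):
        region = comparable_region(A, B, mode=mode)
        assert (region.a_start, region.a_stop) == (0, 5)
        assert (region.b_start, region.b_stop) == (0, 5)
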