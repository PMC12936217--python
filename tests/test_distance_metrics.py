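"""Distance components (JC, AI, DSS) and their weighted combination."""

import random

import pytest

from gcfkit.comparable_region import ComparableRegion
from gcfkit.distance_metrics import (
    MIX_WEIGHTS,
    WeightScheme,
    adjacency_index,
    combined_distance,
    compute_edge,
    domain_identity,
    dss,
    jaccard_index,
    pairwise_distances,
)
from gcfkit.domain_annotation import DomainHit
from gcfkit.records_io import TopologicalLink

from conftest import make_string, random_string_pair


def hit(acc, sub):
    return DomainHit(acc, 0, 0, len(sub), 50.0, sub)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A"}, {"A"}, 1.0),
            ({"A"}, {"B"}, 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard_index(a, b) == expected

    def test_both_empty_defined_zero(self):
        assert jaccard_index(set(), set()) == 0.0


class TestAdjacencyIndex:
    def test_identical_slices(self):
        assert adjacency_index(["A", "B", "C"], ["A", "B", "C"]) == 1.0

    def test_orientation_invariance(self):
        # unordered pairs {A,B},{B,C} are shared between the two orders
        assert adjacency_index(["A", "B", "C"], ["C", "B", "A"]) == 1.0

    def test_disjoint_pairs(self):
        assert adjacency_index(["A", "B"], ["A", "C"]) == 0.0

    def test_single_tokens_no_pairs(self):
        assert adjacency_index(["A"], ["A"]) == 0.0


class TestDomainIdentity:
    def test_identical(self):
        assert domain_identity(hit("X", "AAAA"), hit("X", "AAAA")) == 1.0

    def test_three_quarters(self):
        assert domain_identity(hit("X", "AAAA"), hit("X", "AAAT")) == 0.75

    def test_fully_diverged(self):
        assert domain_identity(hit("X", "AAAA"), hit("X", "TTTT")) == 0.0

    def test_different_accessions_rejected(self):
        with pytest.raises(ValueError):
            domain_identity(hit("X", "AAAA"), hit("Y", "AAAA"))

    def test_gap_columns_count_unmatched(self):
        # best alignment matches the common prefix; the extra residues are
        # gap columns
        assert domain_identity(hit("X", "AAAA"), hit("X", "AAAATT")) == pytest.approx(
            4 / 6
        )


class TestModelAnchoredIdentity:
    @pytest.fixture(scope="class")
    def motif_hmm(self):
        import pyhmmer

        alphabet = pyhmmer.easel.Alphabet.amino()
        seqs_txt = [
            "MKLVINGKQWVAEFDTPEGARQAVELLNK",
            "MKLVINGKEWVAEFDSPEGARKAVELLNK",
            "MKLVVNGKQWVAEFDTPDGARQAVEMLNK",
        ]
        seqs = [
            pyhmmer.easel.TextSequence(name=f"s{i}", sequence=s).digitize(alphabet)
            for i, s in enumerate(seqs_txt)
        ]
        msa = pyhmmer.easel.DigitalMSA(alphabet, name="MOTIF", sequences=seqs)
        hmm, _, _ = pyhmmer.plan7.Builder(alphabet).build_msa(
            msa, pyhmmer.plan7.Background(alphabet)
        )
        return hmm, seqs_txt[0]

    def test_identical_sequences(self, motif_hmm):
        hmm, seq = motif_hmm
        assert domain_identity(hit("MOTIF", seq), hit("MOTIF", seq), hmm=hmm) == 1.0

    def test_substitutions_counted_over_match_columns(self, motif_hmm):
        hmm, seq = motif_hmm
        mutated = seq[:5] + "AAA" + seq[8:]
        value = domain_identity(hit("MOTIF", seq), hit("MOTIF", mutated), hmm=hmm)
        assert value == pytest.approx(26 / 29)

    def test_insertions_do_not_penalize_match_columns(self, motif_hmm):
        hmm, seq = motif_hmm
        inserted = seq[:10] + "GGGG" + seq[10:]
        value = domain_identity(hit("MOTIF", seq), hit("MOTIF", inserted), hmm=hmm)
        assert value == 1.0


class TestDss:
    def test_identical_slices(self):
        a = [hit("KS", "A" * 20), hit("AT", "C" * 20)]
        assert dss(a, list(a)) == 1.0

    def test_unpaired_copy_dilutes(self):
        # two A-copies vs one: identities 0.9 and 0.5 -> best pairing 0.9
        # over max(2,1)=2 slots
        a = [hit("X", "A" * 9 + "C"), hit("X", "A" * 5 + "C" * 5)]
        b = [hit("X", "A" * 10)]
        assert dss(a, b) == pytest.approx(0.45)

    def test_disjoint_types(self):
        assert dss([hit("X", "AAAA")], [hit("Y", "CCCC")]) == 0.0

    def test_anchor_boost_weighting(self):
        # anchor type identical (1.0), non-anchor fully diverged (0.0):
        # DSS = (2*1*1 + 1*0) / (2*1 + 1) = 2/3
        a = [hit("ANC", "A" * 10), hit("X", "C" * 10)]
        b = [hit("ANC", "A" * 10), hit("X", "D" * 10)]
        value = dss(a, b, anchors={"ANC"}, anchor_boost=2.0)
        assert value == pytest.approx(2 / 3)

    def test_pairing_matches_exhaustive_assignment(self):
        """Greedy/exhaustive pairing equals the optimal assignment for
        copy counts <= 4 (scipy linear_sum_assignment as oracle)."""
        import numpy as np
        from scipy.optimize import linear_sum_assignment

        from gcfkit.distance_metrics import _best_pairing_score

        rng = random.Random(5)
        for _ in range(200):
            na, nb = rng.randint(1, 4), rng.randint(1, 4)
            mat = [[rng.random() for _ in range(nb)] for _ in range(na)]
            cost = -np.array(mat)
            rows, cols = linear_sum_assignment(cost)
            expected = -cost[rows, cols].sum()
            assert _best_pairing_score(mat) == pytest.approx(expected)


class TestCombinedDistance:
    def test_extremes(self):
        assert combined_distance(1, 1, 1, MIX_WEIGHTS) == 0.0
        assert combined_distance(0, 0, 0, MIX_WEIGHTS) == 1.0

    def test_arithmetic(self):
        w = WeightScheme(0.2, 0.05, 0.75)
        assert combined_distance(0.5, 0.0, 0.8, w) == pytest.approx(0.3)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            WeightScheme(0.5, 0.5, 0.5)


class TestComputeEdge:
    def test_identical_records_distance_zero_all_modes(self):
        tokens = ["KS", "AT", "KR", "ACP"]
        A = make_string("A", tokens)
        B = make_string("B", tokens)
        for mode in ("global", "glocal", "local"):
            edge = compute_edge(A, B, mode=mode)
            assert edge.distance == pytest.approx(0.0, abs=1e-12)

    def test_no_shared_tokens_local_is_maximal(self):
        A = make_string("A", ["X", "Y"])
        B = make_string("B", ["Q", "R"])
        edge = compute_edge(A, B, mode="local")
        assert edge.distance == 1.0
        assert edge.region.is_empty

    def test_symmetry_and_range_across_modes_and_strategies(self):
        rng = random.Random(3)
        for _ in range(40):
            A, B = random_string_pair(rng)
            for mode in ("global", "glocal", "local"):
                for strategy in ("legacy", "simple_match", "greedy"):
                    e1 = compute_edge(A, B, mode=mode, strategy=strategy)
                    e2 = compute_edge(B, A, mode=mode, strategy=strategy)
                    assert abs(e1.distance - e2.distance) < 1e-9
                    for value in (e1.jc, e1.ai, e1.dss, e1.distance):
                        assert 0.0 <= value <= 1.0

    def test_edge_invariant_weighted_sum(self):
        rng = random.Random(9)
        for _ in range(30):
            A, B = random_string_pair(rng)
            edge = compute_edge(A, B)
            if edge.region.is_empty:
                assert edge.distance == 1.0
                continue
            expected = 1 - (
                MIX_WEIGHTS.w_jc * edge.jc
                + MIX_WEIGHTS.w_ai * edge.ai
                + MIX_WEIGHTS.w_dss * edge.dss
            )
            assert edge.distance == pytest.approx(max(0.0, expected), abs=1e-9)

    def test_monotonicity_in_sequence_identity(self):
        """Improving one matched pair's identity never increases distance."""
        base = ["KS", "AT", "KR"]
        seqs_low = ["A" * 10, "C" * 5 + "A" * 5, "D" * 10]
        seqs_high = ["A" * 10, "C" * 2 + "A" * 8, "D" * 10]
        B = make_string("B", base, subseqs=["A" * 10, "A" * 10, "D" * 10])
        low = compute_edge(make_string("A", base, subseqs=seqs_low), B)
        high = compute_edge(make_string("A", base, subseqs=seqs_high), B)
        assert high.distance <= low.distance + 1e-12


class TestPairwiseDistances:
    def test_edge_count_one_bin(self):
        strings = {f"r{i}": make_string(f"r{i}", ["KS", "AT"]) for i in range(5)}
        edges = pairwise_distances(strings)
        assert len(edges) == 10  # C(5,2)

    def test_topological_links_skipped(self):
        strings = {f"r{i}": make_string(f"r{i}", ["KS", "AT"]) for i in range(3)}
        links = [TopologicalLink("r0", "r1", "parent")]
        edges = pairwise_distances(strings, links=links)
        pairs = {frozenset((e.record_a, e.record_b)) for e in edges}
        assert frozenset(("r0", "r1")) not in pairs
        assert len(edges) == 2

    def test_unknown_bin_falls_back_to_mix(self, caplog):
        strings = {"a": make_string("a", ["KS"]), "b": make_string("b", ["KS"])}
        bins = {"a": ["weird"], "b": ["weird"]}
        edges = pairwise_distances(strings, bins=bins)
        assert len(edges) == 1
        assert edges[0].bin_label == "weird"

    def test_multi_bin_dedup(self):
        strings = {"a": make_string("a", ["KS"]), "b": make_string("b", ["KS"])}
        bins = {"a": ["mix", "PKS1"], "b": ["mix", "PKS1"]}
        edges = pairwise_distances(strings, bins=bins)
        assert len(edges) == 2  # one per shared bin, not four
        assert {e.bin_label for e in edges} == {"mix", "PKS1"}
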