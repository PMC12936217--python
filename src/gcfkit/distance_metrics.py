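"""Pairwise distances between gene cluster records.

Three components are measured over the comparable region of a record pair:

* JC — Jaccard index of the domain-type sets (domain content),
* AI — adjacency index over unordered consecutive-domain pairs (synteny),
* DSS — domain sequence similarity, from per-domain amino-acid identities
  of type-matched hit pairs, with unpaired copies counting as identity 0
  and anchor domain types up-weighted.

The combined distance is ``1 − (w_jc·JC + w_ai·AI + w_dss·DSS)`` with a
per-bin weight scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

from Bio import Align

from gcfkit.comparable_region import (
    ALIGNMENT_MODES,
    DEFAULT_EXTEND_SCORES,
    EXTEND_STRATEGIES,
    ComparableRegion,
    comparable_region,
)
from gcfkit.domain_annotation import DomainHit, DomainString
from gcfkit.records_io import TopologicalLink

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightScheme:
    """Relative weights of the three distance components for one bin."""

    w_jc: float
    w_ai: float
    w_dss: float
    anchor_boost: float = 2.0

    def __post_init__(self) -> None:
        total = self.w_jc + self.w_ai + self.w_dss
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        if min(self.w_jc, self.w_ai, self.w_dss) < 0:
            raise ValueError("component weights must be non-negative")
        if self.anchor_boost < 1:
            raise ValueError("anchor_boost must be >= 1")


#: Default scheme used for the "mix" bin and as fallback for unknown bins.
MIX_WEIGHTS = WeightScheme(w_jc=0.2, w_ai=0.05, w_dss=0.75, anchor_boost=2.0)

#: Per-legacy-class weight table (config asset; users may override any bin).
DEFAULT_WEIGHTS: dict[str, WeightScheme] = {
    "mix": MIX_WEIGHTS,
    "PKS1": WeightScheme(0.22, 0.02, 0.76),
    "PKSOther": WeightScheme(0.0, 0.32, 0.68),
    "NRPS": WeightScheme(0.0, 0.0, 1.0),
    "NRPS-PKS-hybrid": WeightScheme(0.0, 0.22, 0.78),
    "RiPP": WeightScheme(0.28, 0.01, 0.71),
    "Saccharide": WeightScheme(0.0, 1.0, 0.0),
    "Terpene": WeightScheme(0.2, 0.05, 0.75),
    "Others": WeightScheme(0.01, 0.02, 0.97),
}


@dataclass
class DistanceEdge:
    """One computed pairwise distance with its components and provenance."""

    record_a: str
    record_b: str
    jc: float
    ai: float
    dss: float
    distance: float
    bin_label: str
    region: ComparableRegion
    mode: str
    strategy: str


def jaccard_index(types_a: set[str], types_b: set[str]) -> float:
    """|A ∩ B| / |A ∪ B| over domain-type sets."""
    union = types_a | types_b
    if not union:
        logger.warning("Jaccard of two empty domain-type sets; defined as 0.0")
        return 0.0
    return len(types_a & types_b) / len(union)


def _adjacency_pairs(tokens: Sequence[str]) -> set[frozenset[str]]:
    # a self-adjacency (t, t) collapses to the singleton frozenset {t},
    # which cannot collide with any two-token pair
    return {frozenset((t1, t2)) for t1, t2 in zip(tokens, tokens[1:])}


def adjacency_index(slice_a: Sequence[str], slice_b: Sequence[str]) -> float:
    """Jaccard over the sets of unordered consecutive-token pairs.

    Unordered pairs make the measure insensitive to whole-slice
    orientation: [A,B,C] and [C,B,A] produce identical pair sets.
    """
    pa, pb = _adjacency_pairs(slice_a), _adjacency_pairs(slice_b)
    union = pa | pb
    if not union:
        return 0.0
    return len(pa & pb) / len(union)


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-0.1,
    extend_gap_score=-0.1,
)


@lru_cache(maxsize=200_000)
def _aligned_identity(seq_a: str, seq_b: str) -> float:
    """Matched columns / aligned columns of a global pairwise alignment
    (match +1, mismatch 0, small linear gap penalty; gapped columns count
    as unmatched)."""
    if seq_a == seq_b:
        return 1.0
    if not seq_a or not seq_b:
        return 0.0
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    matched = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            columns += 1
            if x == y:
                matched += 1
    # gap columns: positions of either sequence not covered by aligned blocks
    covered_a = sum(a1 - a0 for a0, a1 in alignment.aligned[0])
    covered_b = sum(b1 - b0 for b0, b1 in alignment.aligned[1])
    columns += (len(seq_a) - covered_a) + (len(seq_b) - covered_b)
    if columns == 0:
        return 0.0
    return matched / columns


def _model_anchored_identity(seq_a: str, seq_b: str, hmm) -> float:
    """Identity over shared match columns of a profile-anchored alignment.

    Both envelope subsequences are aligned to the profile's match states
    (hmmalign); identity is computed only over consensus columns where
    both sequences place a residue.  Falls back to 0 when the sequences
    share no occupied match column.
    """
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    block = pyhmmer.easel.DigitalSequenceBlock(
        alphabet,
        [
            pyhmmer.easel.TextSequence(name="a", sequence=seq_a).digitize(alphabet),
            pyhmmer.easel.TextSequence(name="b", sequence=seq_b).digitize(alphabet),
        ],
    )
    msa = pyhmmer.hmmer.hmmalign(hmm, block, trim=True, all_consensus_cols=True)
    row_a, row_b = msa.alignment
    matched = 0
    shared = 0
    for x, y in zip(row_a, row_b):
        # a2m convention: match columns are uppercase residues or '-',
        # insert columns lowercase or '.'
        if x.islower() or y.islower() or x == "." or y == ".":
            continue  # insert column
        if x == "-" or y == "-":
            continue  # match state unoccupied in one sequence
        shared += 1
        if x == y:
            matched += 1
    if shared == 0:
        return 0.0
    return matched / shared


def domain_identity(hit_a: DomainHit, hit_b: DomainHit, hmm=None) -> float:
    """Amino-acid identity of two hits of the same domain type.

    With a profile (``pyhmmer.plan7.HMM``) for the domain, identity is
    model-anchored (both envelopes aligned to the match states); without
    one it comes from a direct global pairwise alignment.
    """
    if hit_a.domain_acc != hit_b.domain_acc:
        raise ValueError(
            f"cannot compare hits of different types: "
            f"{hit_a.domain_acc} vs {hit_b.domain_acc}"
        )
    if hmm is not None:
        return _model_anchored_identity(hit_a.subseq, hit_b.subseq, hmm)
    return _aligned_identity(hit_a.subseq, hit_b.subseq)


def _best_pairing_score(identity: list[list[float]]) -> float:
    """Maximum summed identity over one-to-one pairings of the copies of a
    domain type.  Exhaustive over permutations when the smaller side has at
    most four copies, greedy best-first beyond that."""
    na, nb = len(identity), len(identity[0]) if identity else 0
    if na == 0 or nb == 0:
        return 0.0
    transposed = False
    if na > nb:
        identity = [[identity[i][j] for i in range(na)] for j in range(nb)]
        na, nb = nb, na
        transposed = True
    if na <= 4:
        best = 0.0
        for perm in permutations(range(nb), na):
            best = max(best, sum(identity[i][perm[i]] for i in range(na)))
        return best
    # greedy best-first on remaining rows/columns
    cells = sorted(
        ((identity[i][j], i, j) for i in range(na) for j in range(nb)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    for score, i, j in cells:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += score
        if len(used_a) == na:
            break
    return total


def dss(
    a_hits: Sequence[DomainHit],
    b_hits: Sequence[DomainHit],
    anchors: set[str] = frozenset(),
    anchor_boost: float = 2.0,
    hmms: Mapping[str, object] | None = None,
) -> float:
    """Domain sequence similarity over two comparable-region slices.

    Copies of each domain type are paired one-to-one to maximize summed
    identity; unpaired copies contribute 0.  Each type occupies
    ``max(copies_a, copies_b)`` slots.  Anchor and non-anchor types form
    separate partitions whose scores are combined with the anchor partition
    weighted by ``anchor_boost``.
    """
    by_type_a: dict[str, list[DomainHit]] = {}
    by_type_b: dict[str, list[DomainHit]] = {}
    for h in a_hits:
        by_type_a.setdefault(h.domain_acc, []).append(h)
    for h in b_hits:
        by_type_b.setdefault(h.domain_acc, []).append(h)

    sums = {True: 0.0, False: 0.0}  # keyed by is_anchor
    slots = {True: 0, False: 0}
    for acc in sorted(set(by_type_a) | set(by_type_b)):
        ca = by_type_a.get(acc, [])
        cb = by_type_b.get(acc, [])
        part = acc in anchors
        slots[part] += max(len(ca), len(cb))
        if ca and cb:
            hmm = hmms.get(acc) if hmms else None
            if hmm is not None:
                identity = [
                    [_model_anchored_identity(x.subseq, y.subseq, hmm) for y in cb]
                    for x in ca
                ]
            else:
                identity = [
                    [_aligned_identity(x.subseq, y.subseq) for y in cb] for x in ca
                ]
            sums[part] += _best_pairing_score(identity)

    s_anchor, s_non = slots[True], slots[False]
    if s_anchor == 0 and s_non == 0:
        return 0.0
    num = anchor_boost * sums[True] + sums[False]
    den = anchor_boost * s_anchor + s_non
    return num / den


def combined_distance(jc: float, ai: float, dss_value: float, w: WeightScheme) -> float:
    """1 − weighted similarity, clamped to [0, 1]."""
    d = 1.0 - (w.w_jc * jc + w.w_ai * ai + w.w_dss * dss_value)
    return min(1.0, max(0.0, d))


def _slice_hits(
    ds: DomainString, start: int, stop: int, reverse: bool = False
) -> list[DomainHit]:
    hits = ds.hits
    if reverse:
        hits = hits[::-1]
    return list(hits[start:stop])


def compute_edge(
    A: DomainString,
    B: DomainString,
    bin_label: str = "mix",
    mode: str = "glocal",
    strategy: str = "legacy",
    weights: WeightScheme = MIX_WEIGHTS,
    anchors: set[str] = frozenset(),
    scores: tuple[float, float, float] = DEFAULT_EXTEND_SCORES,
    hmms: Mapping[str, object] | None = None,
) -> DistanceEdge:
    """Distance edge for one record pair under one (mode, strategy, bin).

    The pair is canonicalized by record id before alignment so that the
    result does not depend on argument order even when the anchor
    selection has to break ties; the reported region is mirrored back into
    the caller's orientation.
    """
    if A.record_id > B.record_id:
        edge = compute_edge(
            B, A, bin_label=bin_label, mode=mode, strategy=strategy,
            weights=weights, anchors=anchors, scores=scores, hmms=hmms,
        )
        r = edge.region
        if r.reverse:
            # swap roles: the A-span maps into reversed-B coordinates and
            # vice versa
            mirrored = ComparableRegion(
                len(A) - r.b_stop, len(A) - r.b_start,
                len(B) - r.a_stop, len(B) - r.a_start, True,
            )
        else:
            mirrored = ComparableRegion(
                r.b_start, r.b_stop, r.a_start, r.a_stop, False
            )
        return DistanceEdge(
            A.record_id, B.record_id, edge.jc, edge.ai, edge.dss,
            edge.distance, bin_label, mirrored, mode, strategy,
        )
    region = comparable_region(A, B, mode=mode, strategy=strategy, scores=scores)
    if region.is_empty:
        # no shared domain token in local mode: maximal distance by convention
        return DistanceEdge(
            A.record_id, B.record_id, 0.0, 0.0, 0.0, 1.0, bin_label, region,
            mode, strategy,
        )
    a_slice = _slice_hits(A, region.a_start, region.a_stop)
    b_slice = _slice_hits(B, region.b_start, region.b_stop, reverse=region.reverse)
    jc = jaccard_index(
        {h.domain_acc for h in a_slice}, {h.domain_acc for h in b_slice}
    )
    ai = adjacency_index(
        [h.domain_acc for h in a_slice], [h.domain_acc for h in b_slice]
    )
    dss_value = dss(
        a_slice, b_slice, anchors=anchors, anchor_boost=weights.anchor_boost,
        hmms=hmms,
    )
    distance = combined_distance(jc, ai, dss_value, weights)
    return DistanceEdge(
        A.record_id, B.record_id, jc, ai, dss_value, distance, bin_label, region,
        mode, strategy,
    )


def pairwise_distances(
    strings: Mapping[str, DomainString],
    bins: Mapping[str, list[str]] | None = None,
    mode: str = "glocal",
    strategy: str = "legacy",
    weights: Mapping[str, WeightScheme] | None = None,
    links: Iterable[TopologicalLink] = (),
    anchors: set[str] = frozenset(),
    scores: tuple[float, float, float] = DEFAULT_EXTEND_SCORES,
    hmms: Mapping[str, object] | None = None,
) -> list[DistanceEdge]:
    """All within-bin pairwise distance edges.

    ``bins`` maps record_id → list of bin labels (default: everything in
    "mix").  Pairs joined by a topological link (same parent region) are
    skipped.  Records appearing in several bins are compared once per
    shared bin.  Unknown bin labels fall back to the "mix" weight scheme.
    """
    if mode not in ALIGNMENT_MODES:
        raise ValueError(f"unknown alignment mode {mode!r}")
    if strategy not in EXTEND_STRATEGIES:
        raise ValueError(f"unknown extension strategy {strategy!r}")
    if bins is None:
        bins = {rid: ["mix"] for rid in strings}
    weight_table = dict(DEFAULT_WEIGHTS)
    if weights:
        weight_table.update(weights)
    linked = {frozenset((l.record_a, l.record_b)) for l in links}

    by_bin: dict[str, list[str]] = {}
    for rid in sorted(strings):
        for label in bins.get(rid, []):
            by_bin.setdefault(label, []).append(rid)

    edges: list[DistanceEdge] = []
    seen: set[tuple[frozenset[str], str]] = set()
    for label in sorted(by_bin):
        if label in weight_table:
            scheme = weight_table[label]
        else:
            logger.warning("no weight scheme for bin %r; using 'mix'", label)
            scheme = weight_table["mix"]
        for rid_a, rid_b in combinations(by_bin[label], 2):
            pair = frozenset((rid_a, rid_b))
            if pair in linked or (pair, label) in seen:
                continue
            seen.add((pair, label))
            edges.append(
                compute_edge(
                    strings[rid_a],
                    strings[rid_b],
                    bin_label=label,
                    mode=mode,
                    strategy=strategy,
                    weights=scheme,
                    anchors=anchors,
                    scores=scores,
                    hmms=hmms,
                )
            )
    return edges
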