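"""Similarity networks and family calling.

Distances below a cutoff form an undirected similarity network whose
connected components are clustered independently with affinity propagation
(exemplar-based message passing).  Tightly connected components — graph
density at or above a configurable threshold (default 0.85) — are clustered
with a fixed, strongly negative preference (default −5) to penalize the
founding of new families; all other components use the median off-diagonal
similarity as preference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from gcfkit.distance_metrics import DistanceEdge, WeightScheme, compute_edge
from gcfkit.domain_annotation import DomainString

logger = logging.getLogger(__name__)


@dataclass
class ComponentSummary:
    """One connected component of the thresholded similarity network."""

    cc_id: int
    members: list[str]
    n_edges: int
    density: float


@dataclass
class FamilyAssignment:
    """Membership of one record in one family at one cutoff."""

    record_id: str
    cutoff: float
    family_id: str
    cc_id: int | None = None
    singleton: bool = False


@dataclass
class ClusteringConfig:
    """Tunable parameters of networking and family calling."""

    cutoffs: list[float] = field(default_factory=lambda: [0.3])
    density_threshold: float = 0.85
    dense_preference: float = -5.0
    default_preference: float | str = "median_similarity"
    damping: float = 0.9
    max_iter: int = 1000
    convergence_iter: int = 200
    include_singletons: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must lie strictly between 0 and 1")
        if not 0 <= self.density_threshold <= 1:
            raise ValueError("density_threshold must lie in [0, 1]")
        for c in self.cutoffs:
            if not 0 < c <= 1:
                raise ValueError("cutoffs must lie in (0, 1]")


def build_network(
    edges: Iterable[DistanceEdge],
    cutoff: float,
    all_records: Iterable[str] = (),
) -> nx.Graph:
    """Undirected graph of exactly the edges with distance ≤ cutoff.

    ``all_records`` seeds isolated nodes so singletons survive
    thresholding.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sorted(all_records))
    for edge in edges:
        if edge.distance <= cutoff:
            graph.add_edge(edge.record_a, edge.record_b, distance=edge.distance)
    return graph


def connected_components(graph: nx.Graph) -> list[ComponentSummary]:
    """Maximal connected node sets with their graph densities.

    Density is ``2·edges / (n·(n−1))``; a singleton component has density 0
    by definition.
    """
    summaries = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for cc_id, nodes in enumerate(components):
        members = sorted(nodes)
        sub = graph.subgraph(nodes)
        n, m = len(members), sub.number_of_edges()
        density = 2 * m / (n * (n - 1)) if n >= 2 else 0.0
        summaries.append(ComponentSummary(cc_id, members, m, density))
    return summaries


def affinity_propagation(
    similarity: np.ndarray,
    preference: float,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Exemplar-based clustering by responsibility/availability message
    passing (Frey & Dueck).

    The preference is placed on the diagonal of the similarity matrix; no
    random noise is added, so the procedure is fully deterministic.
    Returns (exemplar indices, per-point labels as indices into the
    exemplar array, converged flag).
    """
    n = similarity.shape[0]
    S = similarity.astype(float).copy()
    np.fill_diagonal(S, preference)
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)

    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first = np.max(AS, axis=1)
        first_idx = np.argmax(AS, axis=1)
        AS[idx, first_idx] = -np.inf
        second = np.max(AS, axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_idx] = S[idx, first_idx] - second
        R = damping * R + (1 - damping) * Rnew

        # availabilities
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = col[None, :] - Rp
        diag = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0)
        np.fill_diagonal(Anew, diag)
        A = damping * A + (1 - damping) * Anew

        exemplars = np.flatnonzero((A + R).diagonal() > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= convergence_iter and len(exemplars) > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = np.flatnonzero((A + R).diagonal() > 0)
    if len(exemplars) == 0:
        # fully degenerate state (e.g. all similarities and the preference
        # equal): no diagonal rises above zero; fall back to a single
        # exemplar at the largest diagonal evidence (ties -> lowest index)
        exemplars = np.array([int(np.argmax((A + R).diagonal()))])

    labels = np.argmax(similarity[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))
    # exemplar refinement: within each cluster pick the member maximizing
    # summed intra-cluster similarity, then re-assign
    refined = []
    for k in range(len(exemplars)):
        members = np.flatnonzero(labels == k)
        scores = similarity[np.ix_(members, members)].sum(axis=0)
        refined.append(members[int(np.argmax(scores))])
    exemplars = np.array(sorted(refined), dtype=int)
    labels = np.argmax(similarity[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))
    return exemplars, labels, converged


def _similarity_matrix(
    members: Sequence[str], edges: Iterable[DistanceEdge]
) -> np.ndarray:
    """Intra-component similarity (1 − distance); missing pairs are 0."""
    index = {rid: i for i, rid in enumerate(members)}
    n = len(members)
    S = np.zeros((n, n))
    np.fill_diagonal(S, 1.0)
    for edge in edges:
        if edge.record_a in index and edge.record_b in index:
            i, j = index[edge.record_a], index[edge.record_b]
            S[i, j] = S[j, i] = 1.0 - edge.distance
    return S


def select_preference(cc: ComponentSummary, S: np.ndarray, config: ClusteringConfig) -> float:
    """Dense components get the penalizing preference; the rest the default."""
    if cc.density >= config.density_threshold:
        return config.dense_preference
    if config.default_preference == "median_similarity":
        off = S[~np.eye(S.shape[0], dtype=bool)]
        return float(np.median(off)) if off.size else 0.0
    return float(config.default_preference)


def call_families(
    cc: ComponentSummary,
    edges: Iterable[DistanceEdge],
    config: ClusteringConfig,
    cutoff: float,
    preference_log: dict[int, float] | None = None,
) -> list[FamilyAssignment]:
    """Family assignments for one connected component.

    Components of size 1 become their own family.  Non-converged message
    passing collapses the whole component into one family under its
    highest-degree member (logged), never an error.
    """
    members = sorted(cc.members)
    if len(members) == 1:
        return [
            FamilyAssignment(members[0], cutoff, members[0], cc.cc_id, singleton=True)
        ]
    edges = [
        e
        for e in edges
        if e.record_a in set(members) and e.record_b in set(members)
    ]
    S = _similarity_matrix(members, edges)
    preference = select_preference(cc, S, config)
    if preference_log is not None:
        preference_log[cc.cc_id] = preference
    exemplars, labels, converged = affinity_propagation(
        S,
        preference,
        damping=config.damping,
        max_iter=config.max_iter,
        convergence_iter=config.convergence_iter,
    )
    if len(exemplars) == 0:
        degree: dict[str, int] = {m: 0 for m in members}
        for e in edges:
            degree[e.record_a] += 1
            degree[e.record_b] += 1
        head = max(members, key=lambda m: (degree[m], m))
        logger.warning(
            "message passing did not converge for cc %d (%d members); "
            "collapsing into one family under %s",
            cc.cc_id,
            len(members),
            head,
        )
        return [FamilyAssignment(m, cutoff, head, cc.cc_id) for m in members]
    if not converged:
        logger.warning(
            "message passing reached max_iter on cc %d; using final state", cc.cc_id
        )
    return [
        FamilyAssignment(m, cutoff, members[exemplars[labels[i]]], cc.cc_id)
        for i, m in enumerate(members)
    ]


def families_at_cutoff(
    edges: Sequence[DistanceEdge],
    cutoff: float,
    config: ClusteringConfig,
    all_records: Iterable[str] = (),
    preference_log: dict[int, float] | None = None,
) -> tuple[list[FamilyAssignment], list[ComponentSummary]]:
    """Threshold, decompose and cluster: the full family-calling pass."""
    records = set(all_records)
    if not records:
        for e in edges:
            records.update((e.record_a, e.record_b))
    graph = build_network(edges, cutoff, all_records=records if config.include_singletons else ())
    summaries = connected_components(graph)
    assignments: list[FamilyAssignment] = []
    for cc in summaries:
        assignments.extend(
            call_families(cc, edges, config, cutoff, preference_log=preference_log)
        )
    return assignments, summaries


def query_one_vs_all(
    query: DomainString,
    refs: Mapping[str, DomainString],
    cutoff: float = 1.0,
    mode: str = "glocal",
    strategy: str = "legacy",
    weights: WeightScheme | None = None,
    anchors: set[str] = frozenset(),
    hmms: Mapping[str, object] | None = None,
) -> list[DistanceEdge]:
    """Distances of one query record against every reference, ascending,
    restricted to distance ≤ cutoff."""
    if len(query) == 0:
        raise ValueError("query domain string is empty")
    from gcfkit.distance_metrics import MIX_WEIGHTS

    scheme = weights or MIX_WEIGHTS
    rows = []
    for rid in sorted(refs):
        ds = refs[rid]
        if len(ds) == 0:
            continue
        edge = compute_edge(
            query, ds, bin_label="query", mode=mode, strategy=strategy,
            weights=scheme, anchors=anchors, hmms=hmms,
        )
        if edge.distance <= cutoff:
            rows.append(edge)
    rows.sort(key=lambda e: (e.distance, e.record_b))
    return rows
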