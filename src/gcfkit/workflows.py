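"""Workflow orchestration: cluster, query, dereplicate, benchmark.

Each workflow is a thin pipeline over the library modules, reading GenBank
inputs, writing TSV reports into an output directory and mirroring its
results into a single-file SQLite database.  The database allows reruns of
the cluster workflow with different cutoffs to reuse stored pairwise
distances: networking and family calling are recomputed, distance
computation is skipped for pairs already present.
"""

from __future__ import annotations

import csv
import fnmatch
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from gcfkit import records_io
from gcfkit.benchmark_eval import (
    Labeling,
    load_labeling_tsv,
    sweep_and_select,
    write_report,
)
from gcfkit.comparable_region import DEFAULT_EXTEND_SCORES, ComparableRegion
from gcfkit.dereplication import dereplicate
from gcfkit.distance_metrics import (
    DEFAULT_WEIGHTS,
    DistanceEdge,
    WeightScheme,
    compute_edge,
    pairwise_distances,
)
from gcfkit.domain_annotation import (
    DEFAULT_MAX_OVERLAP_FRAC,
    DomainString,
    build_domain_string,
    load_precomputed_hits,
    scan_domains,
)
from gcfkit.network_families import (
    ClusteringConfig,
    families_at_cutoff,
    query_one_vs_all,
)
from gcfkit.records_io import GeneClusterRecord, topological_links

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one workflow run."""

    inputs: Sequence[str | Path] = ()
    output_dir: str | Path = "gcfkit_output"
    record_type: str = "region"
    classify_scheme: str = "none"
    mix: bool = False
    force_gbk: bool = False
    include_gbk: Sequence[str] = ("*",)
    exclude_gbk: Sequence[str] = ()
    alignment_mode: str = "glocal"
    extend_strategy: str = "legacy"
    extend_scores: tuple[float, float, float] = DEFAULT_EXTEND_SCORES
    hmm_db: str | Path | None = None
    hits_table: str | Path | None = None
    anchors: frozenset[str] = frozenset()
    weights: Mapping[str, WeightScheme] = field(default_factory=dict)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    vector_threshold: float = 0.4
    dereplicate_k: int = 10
    dereplicate_scaled: int = 100
    dereplicate_threshold: float = 0.9
    query_path: str | Path | None = None
    curated_tsv: str | Path | None = None
    computed_tsvs: Mapping[float, str | Path] = field(default_factory=dict)
    db_path: str | Path | None = None
    seed: int = 0


@dataclass
class ClusterResult:
    records: list[GeneClusterRecord]
    strings: dict[str, DomainString]
    edges: list[DistanceEdge]
    families: dict[float, list]
    counters: dict[str, int]
    preference_log: dict[float, dict[int, float]]
    output_dir: Path


# --------------------------------------------------------------------------
# SQLite persistence

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    run_id INTEGER PRIMARY KEY AUTOINCREMENT,
    workflow TEXT, mode TEXT, strategy TEXT, classify TEXT);
CREATE TABLE IF NOT EXISTS records (
    record_id TEXT PRIMARY KEY, source_path TEXT, record_type TEXT,
    nt_start INTEGER, nt_stop INTEGER, parent_region_id TEXT,
    products TEXT, categories TEXT, minimal INTEGER);
CREATE TABLE IF NOT EXISTS hits (
    record_id TEXT, cds_ordinal INTEGER, domain_acc TEXT,
    aa_start INTEGER, aa_stop INTEGER, bitscore REAL, subseq TEXT);
CREATE TABLE IF NOT EXISTS edges (
    record_a TEXT, record_b TEXT, bin TEXT, mode TEXT, strategy TEXT,
    jc REAL, ai REAL, dss REAL, distance REAL,
    a_start INTEGER, a_stop INTEGER, b_start INTEGER, b_stop INTEGER,
    reverse INTEGER,
    PRIMARY KEY (record_a, record_b, bin, mode, strategy));
CREATE TABLE IF NOT EXISTS components (
    cutoff REAL, cc_id INTEGER, size INTEGER, n_edges INTEGER, density REAL);
CREATE TABLE IF NOT EXISTS families (
    cutoff REAL, record_id TEXT, family_id TEXT, cc_id INTEGER,
    singleton INTEGER);
CREATE TABLE IF NOT EXISTS links (
    record_a TEXT, record_b TEXT, parent_region_id TEXT);
"""


def _open_db(path: str | Path) -> sqlite3.Connection:
    conn = sqlite3.connect(str(path))
    conn.executescript(_SCHEMA)
    return conn


def _load_stored_edges(
    conn: sqlite3.Connection, mode: str, strategy: str
) -> dict[tuple[str, str, str], DistanceEdge]:
    out: dict[tuple[str, str, str], DistanceEdge] = {}
    rows = conn.execute(
        "SELECT record_a, record_b, bin, jc, ai, dss, distance, "
        "a_start, a_stop, b_start, b_stop, reverse FROM edges "
        "WHERE mode = ? AND strategy = ?",
        (mode, strategy),
    )
    for ra, rb, bin_label, jc, ai, dss_v, dist, a0, a1, b0, b1, rev in rows:
        out[(ra, rb, bin_label)] = DistanceEdge(
            ra, rb, jc, ai, dss_v, dist, bin_label,
            ComparableRegion(a0, a1, b0, b1, bool(rev)), mode, strategy,
        )
    return out


def _store_edges(
    conn: sqlite3.Connection, edges: Sequence[DistanceEdge]
) -> None:
    conn.executemany(
        "INSERT OR REPLACE INTO edges VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
        [
            (
                e.record_a, e.record_b, e.bin_label, e.mode, e.strategy,
                e.jc, e.ai, e.dss, e.distance,
                e.region.a_start, e.region.a_stop,
                e.region.b_start, e.region.b_stop, int(e.region.reverse),
            )
            for e in edges
        ],
    )
    conn.commit()


# --------------------------------------------------------------------------
# shared pipeline stages

def collect_gbk_files(cfg: RunConfig) -> list[Path]:
    """Expand input paths (files or directories) with include/exclude globs,
    sorted for input-order invariance."""
    files: list[Path] = []
    for item in cfg.inputs:
        p = Path(item)
        if p.is_dir():
            files.extend(sorted(p.glob("*.gbk")) + sorted(p.glob("*.gb")))
        else:
            files.append(p)
    chosen = []
    for f in files:
        if not any(fnmatch.fnmatch(f.name, pat) for pat in cfg.include_gbk):
            continue
        if any(fnmatch.fnmatch(f.name, pat) for pat in cfg.exclude_gbk):
            continue
        chosen.append(f)
    return sorted(set(chosen))


def parse_inputs(cfg: RunConfig) -> list[GeneClusterRecord]:
    records: list[GeneClusterRecord] = []
    for path in collect_gbk_files(cfg):
        records.extend(
            records_io.parse_genbank(
                path, record_type=cfg.record_type, force_minimal=cfg.force_gbk
            )
        )
    records.sort(key=lambda r: r.record_id)
    return records


def annotate(
    cfg: RunConfig, records: Sequence[GeneClusterRecord]
) -> dict[str, DomainString]:
    """Domain strings for every record with at least one domain hit."""
    if cfg.hits_table is not None:
        hits = load_precomputed_hits(cfg.hits_table)
    elif cfg.hmm_db is not None:
        hits = scan_domains(records, cfg.hmm_db)
    else:
        raise ValueError("cluster workflow needs either hits_table or hmm_db")
    strings: dict[str, DomainString] = {}
    for rec in records:
        ds = build_domain_string(
            rec, hits.get(rec.record_id, []), DEFAULT_MAX_OVERLAP_FRAC
        )
        if len(ds) == 0:
            logger.warning(
                "record %s has no domain hits; excluded from comparisons",
                rec.record_id,
            )
            continue
        strings[rec.record_id] = ds
    return strings


def load_profiles(hmm_db: str | Path | None) -> dict[str, object] | None:
    """Profiles by name, for model-anchored per-domain identity."""
    if hmm_db is None:
        return None
    import pyhmmer

    with pyhmmer.plan7.HMMFile(str(hmm_db)) as fh:
        return {hmm.name: hmm for hmm in fh}


def bin_records(
    cfg: RunConfig, records: Sequence[GeneClusterRecord]
) -> dict[str, list[str]]:
    bins: dict[str, list[str]] = {}
    for rec in records:
        labels = records_io.classify(rec, cfg.classify_scheme)
        if cfg.mix and "mix" not in labels:
            labels = labels + ["mix"]
        bins[rec.record_id] = labels
    return bins


# --------------------------------------------------------------------------
# workflows

def run_cluster(cfg: RunConfig) -> ClusterResult:
    """Parse → annotate → bin → distances → per-cutoff networks/families.

    Distances already present in the run database (same pair, bin, mode
    and strategy) are reused; the ``distances_computed`` counter reports
    only newly computed edges.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db_path = Path(cfg.db_path) if cfg.db_path else out_dir / "gcfkit.sqlite"
    conn = _open_db(db_path)
    counters = {"records_parsed": 0, "distances_computed": 0,
                "distances_reused": 0}

    records = parse_inputs(cfg)
    counters["records_parsed"] = len(records)
    strings = annotate(cfg, records)
    records_with_domains = [r for r in records if r.record_id in strings]
    bins = bin_records(cfg, records_with_domains)
    links = topological_links(records_with_domains)

    conn.executemany(
        "INSERT OR REPLACE INTO records VALUES (?,?,?,?,?,?,?,?,?)",
        [
            (r.record_id, r.source_path, r.record_type, r.nt_start, r.nt_stop,
             r.parent_region_id, ",".join(r.products), ",".join(r.categories),
             int(r.minimal))
            for r in records
        ],
    )
    conn.executemany(
        "INSERT OR REPLACE INTO links VALUES (?,?,?)",
        [(l.record_a, l.record_b, l.parent_region_id) for l in links],
    )
    conn.commit()

    stored = _load_stored_edges(conn, cfg.alignment_mode, cfg.extend_strategy)
    hmms = load_profiles(cfg.hmm_db)
    weight_table = dict(DEFAULT_WEIGHTS)
    weight_table.update(cfg.weights)
    linked = {frozenset((l.record_a, l.record_b)) for l in links}

    by_bin: dict[str, list[str]] = {}
    for rid in sorted(strings):
        for label in bins.get(rid, []):
            by_bin.setdefault(label, []).append(rid)

    edges: list[DistanceEdge] = []
    new_edges: list[DistanceEdge] = []
    from itertools import combinations

    for label in sorted(by_bin):
        scheme = weight_table.get(label, weight_table["mix"])
        for rid_a, rid_b in combinations(by_bin[label], 2):
            if frozenset((rid_a, rid_b)) in linked:
                continue
            key = (rid_a, rid_b, label)
            if key in stored:
                edges.append(stored[key])
                counters["distances_reused"] += 1
                continue
            edge = compute_edge(
                strings[rid_a], strings[rid_b], bin_label=label,
                mode=cfg.alignment_mode, strategy=cfg.extend_strategy,
                weights=scheme, anchors=cfg.anchors, scores=cfg.extend_scores,
                hmms=hmms,
            )
            edges.append(edge)
            new_edges.append(edge)
            counters["distances_computed"] += 1
    if new_edges:
        _store_edges(conn, new_edges)

    families: dict[float, list] = {}
    preference_log: dict[float, dict[int, float]] = {}
    conn.execute("DELETE FROM families")
    conn.execute("DELETE FROM components")
    for cutoff in cfg.clustering.cutoffs:
        log: dict[int, float] = {}
        assignments, summaries = families_at_cutoff(
            edges, cutoff, cfg.clustering, all_records=strings.keys(),
            preference_log=log,
        )
        families[cutoff] = assignments
        preference_log[cutoff] = log
        _write_cutoff_outputs(out_dir, cutoff, assignments, summaries, edges)
        conn.executemany(
            "INSERT INTO families VALUES (?,?,?,?,?)",
            [(cutoff, a.record_id, a.family_id, a.cc_id, int(a.singleton))
             for a in assignments],
        )
        conn.executemany(
            "INSERT INTO components VALUES (?,?,?,?,?)",
            [(cutoff, s.cc_id, len(s.members), s.n_edges, s.density)
             for s in summaries],
        )
    conn.commit()

    with open(out_dir / "links.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_a", "record_b", "parent_region_id"])
        for link in links:
            writer.writerow([link.record_a, link.record_b, link.parent_region_id])
    conn.close()
    logger.info(
        "cluster workflow: %d records, %d computed / %d reused distances",
        counters["records_parsed"], counters["distances_computed"],
        counters["distances_reused"],
    )
    return ClusterResult(records, strings, edges, families, counters,
                         preference_log, out_dir)


def _write_cutoff_outputs(out_dir, cutoff, assignments, summaries, edges) -> None:
    tag = f"{cutoff:g}"
    with open(out_dir / f"families_{tag}.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "family_id", "cc_id", "singleton"])
        for a in assignments:
            writer.writerow([a.record_id, a.family_id, a.cc_id, int(a.singleton)])
    with open(out_dir / f"components_{tag}.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["cc_id", "size", "n_edges", "density"])
        for s in summaries:
            writer.writerow([s.cc_id, len(s.members), s.n_edges, f"{s.density:.6f}"])
    with open(out_dir / f"network_{tag}.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["record_a", "record_b", "bin", "jc", "ai", "dss", "distance",
             "a_start", "a_stop", "b_start", "b_stop", "reverse", "mode",
             "strategy"]
        )
        for e in edges:
            if e.distance <= cutoff:
                writer.writerow(
                    [e.record_a, e.record_b, e.bin_label,
                     f"{e.jc:.6f}", f"{e.ai:.6f}", f"{e.dss:.6f}",
                     f"{e.distance:.6f}", e.region.a_start, e.region.a_stop,
                     e.region.b_start, e.region.b_stop, int(e.region.reverse),
                     e.mode, e.strategy]
                )


def run_query(cfg: RunConfig) -> list[DistanceEdge]:
    """One-vs-all comparison of a query record against all inputs."""
    if cfg.query_path is None:
        raise ValueError("query workflow needs query_path")
    records = parse_inputs(cfg)
    strings = annotate(cfg, records)
    query_records = records_io.parse_genbank(
        cfg.query_path, record_type=cfg.record_type, force_minimal=cfg.force_gbk
    )
    if not query_records:
        raise ValueError(f"no records parsed from query {cfg.query_path}")
    query_cfg = RunConfig(
        inputs=[cfg.query_path], record_type=cfg.record_type,
        force_gbk=cfg.force_gbk, hits_table=cfg.hits_table, hmm_db=cfg.hmm_db,
    )
    query_strings = annotate(query_cfg, query_records)
    if not query_strings:
        raise ValueError("query record has no domain hits")
    query_ds = query_strings[sorted(query_strings)[0]]
    refs = {rid: ds for rid, ds in strings.items() if rid != query_ds.record_id}
    cutoff = max(cfg.clustering.cutoffs)
    rows = query_one_vs_all(
        query_ds, refs, cutoff=cutoff, mode=cfg.alignment_mode,
        strategy=cfg.extend_strategy, anchors=cfg.anchors,
        hmms=load_profiles(cfg.hmm_db),
    )
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "query_results.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query", "reference", "jc", "ai", "dss", "distance"])
        for e in rows:
            writer.writerow(
                [e.record_a, e.record_b, f"{e.jc:.6f}", f"{e.ai:.6f}",
                 f"{e.dss:.6f}", f"{e.distance:.6f}"]
            )
    return rows


def run_dereplicate(cfg: RunConfig) -> tuple[list[str], dict[str, str]]:
    """Sequence-based redundancy filtering of the input records."""
    records = parse_inputs(cfg)
    kept, dropped = dereplicate(
        records, k=cfg.dereplicate_k, scaled=cfg.dereplicate_scaled,
        threshold=cfg.dereplicate_threshold,
    )
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "representatives.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id"])
        for rid in kept:
            writer.writerow([rid])
    with open(out_dir / "dereplication_map.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["dropped_id", "representative_id"])
        for rid in sorted(dropped):
            writer.writerow([rid, dropped[rid]])
    return kept, dropped


def run_benchmark(cfg: RunConfig):
    """Congruence analysis of computed family TSVs against a curated TSV."""
    if cfg.curated_tsv is None or not cfg.computed_tsvs:
        raise ValueError("benchmark workflow needs curated_tsv and computed_tsvs")
    curated = load_labeling_tsv(cfg.curated_tsv)
    runs: dict[float, Labeling] = {
        cutoff: load_labeling_tsv(path)
        for cutoff, path in cfg.computed_tsvs.items()
    }
    results, selected = sweep_and_select(curated, runs)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(results, selected, out_dir / "benchmark.tsv")
    return results, selected
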