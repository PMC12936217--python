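"""Super-linear family calling on domain-count vectors.

Records are represented as counts of domain types, L2-normalized so that
Euclidean distance between rows becomes a cosine-like metric
(``‖u−v‖² = 2(1−u·v)`` for unit rows), and grouped by a deterministic
single-pass threshold-radius clustering in the style of BIRCH: a row joins
the nearest existing subcluster when the merged subcluster's radius stays
within the threshold, otherwise it founds a new one.  New records can be
placed onto a fitted model by nearest-centroid assignment.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from gcfkit.domain_annotation import DomainString

#: Default radius threshold on L2-normalized count vectors.
DEFAULT_THRESHOLD = 0.4


@dataclass
class FeatureMatrix:
    """Records × domain-vocabulary count matrix."""

    record_ids: list[str]
    vocab: list[str]
    counts: np.ndarray
    normalized: bool = False
    zero_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.record_ids), len(self.vocab)):
            raise ValueError("counts shape does not match ids × vocab")
        # zero rows are a property of the data; always derive them
        self.zero_rows = [
            rid for r, rid in enumerate(self.record_ids)
            if not np.any(self.counts[r])
        ]


@dataclass
class CentroidModel:
    """Fitted centroids with training assignments."""

    centroids: np.ndarray
    threshold: float
    vocab: list[str]
    assignments: dict[str, int | None]
    distances: dict[str, float]

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def vectorize(
    strings: Mapping[str, DomainString], vocab: Sequence[str] | str = "auto"
) -> FeatureMatrix:
    """Count matrix of domain hits per record, restricted to a vocabulary.

    ``vocab="auto"`` uses every observed accession, sorted
    lexicographically.  Rows with no vocabulary hit are flagged as zero
    rows and excluded from clustering downstream.
    """
    record_ids = sorted(strings)
    if vocab == "auto":
        observed: set[str] = set()
        for rid in record_ids:
            observed.update(strings[rid].tokens)
        vocab_list = sorted(observed)
    else:
        vocab_list = list(vocab)
    col = {acc: i for i, acc in enumerate(vocab_list)}
    counts = np.zeros((len(record_ids), len(vocab_list)))
    for r, rid in enumerate(record_ids):
        for token in strings[rid].tokens:
            c = col.get(token)
            if c is not None:
                counts[r, c] += 1
    zero_rows = [rid for r, rid in enumerate(record_ids) if not counts[r].any()]
    return FeatureMatrix(record_ids, vocab_list, counts, False, zero_rows)


def l2_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Divide every non-zero row by its Euclidean norm (zero rows pass
    through and stay flagged)."""
    if m.normalized:
        raise ValueError("matrix is already normalized")
    norms = np.linalg.norm(m.counts, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return FeatureMatrix(
        list(m.record_ids), list(m.vocab), m.counts / safe, True, list(m.zero_rows)
    )


class _Subcluster:
    __slots__ = ("n", "ls", "ss")

    def __init__(self, row: np.ndarray) -> None:
        self.n = 1
        self.ls = row.copy()  # linear sum
        self.ss = float(row @ row)  # squared sum

    def centroid(self) -> np.ndarray:
        return self.ls / self.n

    def radius_if_added(self, row: np.ndarray) -> float:
        n = self.n + 1
        ls = self.ls + row
        ss = self.ss + float(row @ row)
        # mean squared distance of members to the merged centroid
        var = ss / n - float(ls @ ls) / n**2
        return math.sqrt(max(var, 0.0))

    def add(self, row: np.ndarray) -> None:
        self.n += 1
        self.ls += row
        self.ss += float(row @ row)


def birch_cluster(m: FeatureMatrix, threshold: float = DEFAULT_THRESHOLD) -> CentroidModel:
    """Single-pass threshold-radius clustering of normalized rows.

    Rows are inserted in record-id order (deterministic; the usual
    order-sensitivity of single-pass clustering is accepted).  Final
    centroids are subcluster means renormalized to unit length; training
    assignments are nearest-centroid on the normalized rows.
    """
    if not m.normalized:
        raise ValueError("birch_cluster requires a normalized matrix")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    zero = set(m.zero_rows)
    subclusters: list[_Subcluster] = []
    for r, rid in enumerate(m.record_ids):
        if rid in zero:
            continue
        row = m.counts[r]
        if subclusters:
            dists = [np.linalg.norm(row - sc.centroid()) for sc in subclusters]
            nearest = int(np.argmin(dists))
            if subclusters[nearest].radius_if_added(row) <= threshold:
                subclusters[nearest].add(row)
                continue
        subclusters.append(_Subcluster(row))

    if not subclusters:
        return CentroidModel(
            np.zeros((0, len(m.vocab))), threshold, list(m.vocab),
            {rid: None for rid in m.record_ids},
            {rid: math.inf for rid in m.record_ids},
        )
    centroids = np.stack([sc.centroid() for sc in subclusters])
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    centroids = centroids / np.where(norms == 0, 1.0, norms)
    model = CentroidModel(centroids, threshold, list(m.vocab), {}, {})
    assignments, distances = assign_to_centroids(m, model)
    model.assignments = assignments
    model.distances = distances
    return model


def assign_to_centroids(
    m: FeatureMatrix, model: CentroidModel
) -> tuple[dict[str, int | None], dict[str, float]]:
    """Nearest-centroid placement of (new) normalized rows.

    Ties go to the lower centroid index; zero rows and an empty model map
    to ``None`` with distance +inf.
    """
    if not m.normalized:
        raise ValueError("assign_to_centroids requires a normalized matrix")
    if list(m.vocab) != list(model.vocab):
        missing = sorted(set(model.vocab) - set(m.vocab))
        extra = sorted(set(m.vocab) - set(model.vocab))
        raise ValueError(
            f"vocabulary mismatch: missing columns {missing}, unexpected {extra}"
        )
    zero = set(m.zero_rows)
    assignments: dict[str, int | None] = {}
    distances: dict[str, float] = {}
    for r, rid in enumerate(m.record_ids):
        if model.k == 0 or rid in zero:
            assignments[rid] = None
            distances[rid] = math.inf
            continue
        d = np.linalg.norm(model.centroids - m.counts[r], axis=1)
        best = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
        assignments[rid] = best
        distances[rid] = float(d[best])
    return assignments, distances


def export_tsv(
    m: FeatureMatrix,
    model: CentroidModel,
    out_dir: str | Path,
    metadata: Mapping[str, Mapping[str, object]] | None = None,
) -> dict[str, Path]:
    """Write record metadata, the feature matrix and memberships as TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out_dir / "records.tsv",
        "features": out_dir / "features.tsv",
        "membership": out_dir / "membership.tsv",
    }
    meta_cols = sorted({k for v in (metadata or {}).values() for k in v})
    with open(paths["metadata"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", *meta_cols])
        for rid in m.record_ids:
            row = (metadata or {}).get(rid, {})
            writer.writerow([rid, *[row.get(c, "") for c in meta_cols]])
    with open(paths["features"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", *m.vocab])
        for r, rid in enumerate(m.record_ids):
            writer.writerow([rid, *[format(x, "g") for x in m.counts[r]]])
    with open(paths["membership"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "centroid", "distance"])
        for rid in m.record_ids:
            centroid = model.assignments.get(rid)
            if centroid is None:
                continue
            writer.writerow([rid, centroid, format(model.distances[rid], "g")])
    return paths


def load_feature_tsv(path: str | Path) -> FeatureMatrix:
    """Re-import a feature matrix written by :func:`export_tsv`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        vocab = header[1:]
        record_ids = []
        rows = []
        for row in reader:
            record_ids.append(row[0])
            rows.append([float(x) for x in row[1:]])
    counts = np.array(rows) if rows else np.zeros((0, len(vocab)))
    zero = [rid for rid, row in zip(record_ids, counts) if not np.any(row)]
    return FeatureMatrix(record_ids, vocab, counts, False, zero)
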