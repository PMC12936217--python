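"""Congruence analysis between curated and computed family assignments.

The agreement between two labelings of the same record set is summarized
by the V-measure: the harmonic mean of homogeneity (computed families are
pure in curated families) and completeness (curated families stay together
in computed families), both derived from natural-log entropies of the
contingency table.  Because the V-measure is not adjusted for chance,
sweeps over cutoffs are compared at the cutoff whose number of computed
families is closest to the curated count.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)


class BenchmarkError(ValueError):
    """Raised when two labelings cannot be compared."""


@dataclass
class Labeling:
    """record_id → family label."""

    assignment: dict[str, str]

    @property
    def n_labels(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class BenchmarkResult:
    cutoff: float
    homogeneity: float
    completeness: float
    v_measure: float
    n_computed_gcfs: int
    n_curated_gcfs: int


def load_labeling_tsv(path: str | Path) -> Labeling:
    """Two-column TSV (record_id, family label), with or without a header."""
    assignment: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in ("record_id", "record", "bgc"):
                continue
            assignment[row[0]] = row[1]
    return Labeling(assignment)


def contingency(
    curated: Labeling, computed: Labeling
) -> dict[str, dict[str, int]]:
    """Counts n[curated label][computed label] over the shared record set.

    Records present in only one labeling are dropped with a logged count.
    """
    shared = set(curated.assignment) & set(computed.assignment)
    dropped = (len(curated.assignment) - len(shared)) + (
        len(computed.assignment) - len(shared)
    )
    if not shared:
        raise BenchmarkError("curated and computed labelings share no record ids")
    if dropped:
        logger.warning(
            "benchmark restricted to %d shared records (%d dropped)",
            len(shared),
            dropped,
        )
    table: dict[str, dict[str, int]] = {}
    for rid in shared:
        c = curated.assignment[rid]
        k = computed.assignment[rid]
        table.setdefault(c, {}).setdefault(k, 0)
        table[c][k] += 1
    return table


def v_measure(table: Mapping[str, Mapping[str, int]]) -> tuple[float, float, float]:
    """(homogeneity, completeness, V) from a contingency table.

    With C the curated and K the computed labeling and natural-log
    entropies, ``h = 1 − H(C|K)/H(C)`` (1 when H(C)=0) and
    ``c = 1 − H(K|C)/H(K)`` (1 when H(K)=0); V is their harmonic mean
    (0 when both are 0).
    """
    n = sum(v for row in table.values() for v in row.values())
    if n < 1:
        raise BenchmarkError("empty contingency table")
    curated_marginal: dict[str, int] = {}
    computed_marginal: dict[str, int] = {}
    for c, row in table.items():
        for k, cnt in row.items():
            curated_marginal[c] = curated_marginal.get(c, 0) + cnt
            computed_marginal[k] = computed_marginal.get(k, 0) + cnt

    def entropy(marginal: Mapping[str, int]) -> float:
        return -sum(
            (cnt / n) * math.log(cnt / n) for cnt in marginal.values() if cnt > 0
        )

    h_c = entropy(curated_marginal)
    h_k = entropy(computed_marginal)
    # conditional entropies from joint counts
    h_c_given_k = 0.0
    h_k_given_c = 0.0
    for c, row in table.items():
        for k, cnt in row.items():
            if cnt == 0:
                continue
            p = cnt / n
            h_c_given_k -= p * math.log(cnt / computed_marginal[k])
            h_k_given_c -= p * math.log(cnt / curated_marginal[c])

    homogeneity = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    completeness = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if homogeneity + completeness == 0:
        v = 0.0
    else:
        v = 2 * homogeneity * completeness / (homogeneity + completeness)
    return homogeneity, completeness, v


def evaluate(curated: Labeling, computed: Labeling, cutoff: float = 0.0) -> BenchmarkResult:
    """One benchmark row: V-measure of computed vs curated at a cutoff."""
    table = contingency(curated, computed)
    h, c, v = v_measure(table)
    shared = set(curated.assignment) & set(computed.assignment)
    n_curated = len({curated.assignment[r] for r in shared})
    n_computed = len({computed.assignment[r] for r in shared})
    return BenchmarkResult(cutoff, h, c, v, n_computed, n_curated)


def sweep_and_select(
    curated: Labeling, runs: Mapping[float, Labeling]
) -> tuple[list[BenchmarkResult], float]:
    """Evaluate every swept cutoff; select the cutoff whose computed family
    count is closest to the curated count (ties to the lower cutoff)."""
    if not runs:
        raise BenchmarkError("no runs to benchmark")
    results = [
        evaluate(curated, labeling, cutoff)
        for cutoff, labeling in sorted(runs.items())
    ]
    selected = min(
        results, key=lambda r: (abs(r.n_computed_gcfs - r.n_curated_gcfs), r.cutoff)
    )
    return results, selected.cutoff


def write_report(
    results: Sequence[BenchmarkResult], selected: float, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["cutoff", "homogeneity", "completeness", "v_measure",
             "n_computed", "n_curated", "selected"]
        )
        for r in results:
            writer.writerow(
                [r.cutoff, f"{r.homogeneity:.6f}", f"{r.completeness:.6f}",
                 f"{r.v_measure:.6f}", r.n_computed_gcfs, r.n_curated_gcfs,
                 int(r.cutoff == selected)]
            )
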