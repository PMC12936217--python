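"""Protein-domain annotation of gene cluster records.

Each record is compressed into an ordered string of profile-HMM domain hits
(its "domain string"), the substrate for alignment and distance
computation.  Hits come either from scanning CDS translations against a
HMMER3 profile database (via pyhmmer) or from a precomputed tab-separated
hit table, and are deduplicated with an overlap filter before the string is
built.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from gcfkit.records_io import GeneClusterRecord, InputError

logger = logging.getLogger(__name__)

#: Reporting floor used when a profile lacks curated thresholds.
DEFAULT_BITSCORE_FLOOR = 20.0
#: Maximum tolerated overlap between two surviving hits, as a fraction of
#: the shorter hit.
DEFAULT_MAX_OVERLAP_FRAC = 0.1

HIT_TABLE_COLUMNS = (
    "record_id",
    "cds_ordinal",
    "domain_acc",
    "aa_start",
    "aa_stop",
    "bitscore",
    "subseq",
)


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM hit inside a CDS translation (envelope coordinates)."""

    domain_acc: str
    cds_ordinal: int
    aa_start: int
    aa_stop: int
    bitscore: float
    subseq: str

    def __post_init__(self) -> None:
        if self.aa_start >= self.aa_stop:
            raise ValueError(
                f"hit envelope must be non-empty: [{self.aa_start}, {self.aa_stop})"
            )

    @property
    def length(self) -> int:
        return self.aa_stop - self.aa_start


@dataclass
class DomainString:
    """Ordered protein-domain hits of one record, with per-hit core flags."""

    record_id: str
    hits: list[DomainHit]
    core_flags: list[bool]

    def __post_init__(self) -> None:
        if len(self.hits) != len(self.core_flags):
            raise ValueError("hits and core_flags must be parallel lists")

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def tokens(self) -> list[str]:
        return [h.domain_acc for h in self.hits]


def scan_domains(
    records: Sequence[GeneClusterRecord],
    hmm_db: str | Path,
    bitscore_floor: float = DEFAULT_BITSCORE_FLOOR,
) -> dict[str, list[DomainHit]]:
    """Scan every CDS translation against a HMMER3 profile database.

    Profiles with curated trusted cutoffs are reported at those cutoffs;
    profiles without them use ``bitscore_floor``.  Hits carry envelope
    coordinates and the envelope subsequence.
    """
    import pyhmmer

    hmm_db = Path(hmm_db)
    try:
        with pyhmmer.plan7.HMMFile(str(hmm_db)) as fh:
            hmms = list(fh)
    except Exception as exc:
        raise InputError(f"cannot read profile database {hmm_db}: {exc}") from exc

    alphabet = pyhmmer.easel.Alphabet.amino()
    sequences = []
    seq_owner: dict[str, tuple[str, int]] = {}
    for rec in records:
        for cds in rec.cds:
            if not cds.translation:
                continue
            name = f"{rec.record_id}\t{cds.ordinal}"
            seq_owner[name] = (rec.record_id, cds.ordinal)
            sequences.append(
                pyhmmer.easel.TextSequence(
                    name=name, sequence=cds.translation
                ).digitize(alphabet)
            )

    hits_by_record: dict[str, list[DomainHit]] = {r.record_id: [] for r in records}
    if not sequences:
        return hits_by_record

    translations = {
        (r.record_id, c.ordinal): c.translation for r in records for c in r.cds
    }
    for top_hits in pyhmmer.hmmsearch(hmms, sequences, cpus=1):
        query = top_hits.query
        hmm_name = query.name
        cutoff = None
        if query.cutoffs.trusted is not None:
            cutoff = query.cutoffs.trusted[0]
        floor = cutoff if cutoff is not None else bitscore_floor
        for hit in top_hits:
            record_id, ordinal = seq_owner[hit.name]
            translation = translations[(record_id, ordinal)]
            for dom in hit.domains:
                if dom.score < floor:
                    continue
                start = dom.env_from - 1  # 1-based inclusive -> 0-based half-open
                stop = dom.env_to
                hits_by_record[record_id].append(
                    DomainHit(
                        domain_acc=hmm_name,
                        cds_ordinal=ordinal,
                        aa_start=start,
                        aa_stop=stop,
                        bitscore=float(dom.score),
                        subseq=translation[start:stop],
                    )
                )
    for hit_list in hits_by_record.values():
        hit_list.sort(key=lambda h: (h.cds_ordinal, h.aa_start, h.domain_acc))
    return hits_by_record


def load_precomputed_hits(table: str | Path) -> dict[str, list[DomainHit]]:
    """Load a precomputed domain-hit table (TSV with a header row).

    Expected columns: record_id, cds_ordinal, domain_acc, aa_start, aa_stop,
    bitscore, subseq.  Rows violating hit invariants raise :class:`InputError`
    with the offending line number.
    """
    table = Path(table)
    out: dict[str, list[DomainHit]] = {}
    with open(table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        missing = set(HIT_TABLE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise InputError(f"{table}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                hit = DomainHit(
                    domain_acc=row["domain_acc"],
                    cds_ordinal=int(row["cds_ordinal"]),
                    aa_start=int(row["aa_start"]),
                    aa_stop=int(row["aa_stop"]),
                    bitscore=float(row["bitscore"]),
                    subseq=row["subseq"],
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise InputError(f"{table}:{lineno}: malformed row ({exc})") from exc
            out.setdefault(row["record_id"], []).append(hit)
    for hit_list in out.values():
        hit_list.sort(key=lambda h: (h.cds_ordinal, h.aa_start, h.domain_acc))
    return out


def filter_overlaps(
    hits: Iterable[DomainHit],
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
) -> list[DomainHit]:
    """Resolve competing domain calls within one CDS.

    Hits are admitted in order of descending bitscore (ties: lower
    aa_start, then accession); a hit is dropped when it overlaps an already
    admitted hit by more than ``max_overlap_frac`` of the shorter of the
    two.  The result is order-independent for a fixed input set.
    """
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.aa_start, h.domain_acc))
    kept: list[DomainHit] = []
    for cand in ranked:
        ok = True
        for winner in kept:
            overlap = min(cand.aa_stop, winner.aa_stop) - max(
                cand.aa_start, winner.aa_start
            )
            if overlap <= 0:
                continue
            shorter = min(cand.length, winner.length)
            if overlap / shorter > max_overlap_frac:
                ok = False
                break
        if ok:
            kept.append(cand)
    kept.sort(key=lambda h: (h.cds_ordinal, h.aa_start, h.domain_acc))
    return kept


def build_domain_string(
    record: GeneClusterRecord,
    hits: Sequence[DomainHit],
    max_overlap_frac: float | None = None,
) -> DomainString:
    """Order a record's (filtered) hits into its domain string.

    Hits are grouped per CDS, overlap-filtered when ``max_overlap_frac`` is
    given, and ordered by (CDS genomic order, position within translation).
    Domains on reverse-strand CDSs keep their translation-coordinate order;
    whole-record inversions are handled downstream by the reverse pass of
    the LCS search, not here.
    """
    by_cds: dict[int, list[DomainHit]] = {}
    for hit in hits:
        by_cds.setdefault(hit.cds_ordinal, []).append(hit)
    core_by_ordinal = {c.ordinal: c.is_core for c in record.cds}
    ordered: list[DomainHit] = []
    for ordinal in sorted(by_cds):
        cds_hits = by_cds[ordinal]
        if max_overlap_frac is not None:
            cds_hits = filter_overlaps(cds_hits, max_overlap_frac)
        ordered.extend(sorted(cds_hits, key=lambda h: (h.aa_start, h.domain_acc)))
    flags = [core_by_ordinal.get(h.cds_ordinal, False) for h in ordered]
    return DomainString(record_id=record.record_id, hits=ordered, core_flags=flags)


def export_domain_strings(
    strings: Mapping[str, DomainString], path: str | Path
) -> None:
    """Write per-record domain strings as TSV (record_id, position, acc, core)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "position", "domain_acc", "core_flag"])
        for record_id in sorted(strings):
            ds = strings[record_id]
            for pos, (hit, core) in enumerate(zip(ds.hits, ds.core_flags)):
                writer.writerow([record_id, pos, hit.domain_acc, int(core)])
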