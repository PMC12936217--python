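"""Redundancy removal by fractional min-hash sketching of protein k-mers.

Each record's concatenated CDS translations are decomposed into amino-acid
k-mers; a deterministic 64-bit hash keeps the fraction of k-mers whose
hash falls below ``2**64 / scaled`` (a FracMinHash sketch).  Max
containment between two sketches estimates the containment of the smaller
record in the larger, and a greedy longest-first pass keeps one
representative per group of near-identical records.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

from gcfkit.records_io import GeneClusterRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 10
DEFAULT_SCALED = 100
DEFAULT_THRESHOLD = 0.9

_HASH_SEED = b"gcfkit-fracminhash-v1"
_MAX_HASH = 2**64


@dataclass
class Sketch:
    """FracMinHash sketch of a record's protein k-mers."""

    record_id: str
    k: int
    scaled: int
    hashes: frozenset[int]


def _hash_kmer(kmer: str) -> int:
    digest = hashlib.blake2b(
        kmer.encode(), digest_size=8, key=_HASH_SEED
    ).digest()
    return int.from_bytes(digest, "little")


def sketch(record: GeneClusterRecord, k: int = DEFAULT_K, scaled: int = DEFAULT_SCALED) -> Sketch:
    """Sketch the record's concatenated CDS translations.

    Every k-mer of every translation is hashed; hashes below
    ``2**64 / scaled`` are retained, so the expected sketch size is the
    number of distinct k-mers divided by ``scaled``.
    """
    if k < 1 or scaled < 1:
        raise ValueError("k and scaled must be positive")
    ceiling = _MAX_HASH // scaled
    hashes: set[int] = set()
    any_long_enough = False
    for cds in record.cds:
        seq = cds.translation
        if len(seq) < k:
            continue
        any_long_enough = True
        for i in range(len(seq) - k + 1):
            h = _hash_kmer(seq[i : i + k])
            if h < ceiling:
                hashes.add(h)
    if not any_long_enough:
        logger.warning(
            "record %s has no translation of length >= %d; empty sketch",
            record.record_id,
            k,
        )
    return Sketch(record.record_id, k, scaled, frozenset(hashes))


def max_containment(a: Sketch, b: Sketch) -> float:
    """|A ∩ B| / min(|A|, |B|); 0 when either sketch is empty."""
    if a.k != b.k or a.scaled != b.scaled:
        raise ValueError(
            f"sketch parameter mismatch: (k={a.k}, scaled={a.scaled}) vs "
            f"(k={b.k}, scaled={b.scaled})"
        )
    if not a.hashes or not b.hashes:
        return 0.0
    inter = len(a.hashes & b.hashes)
    return inter / min(len(a.hashes), len(b.hashes))


def dereplicate(
    records: Sequence[GeneClusterRecord],
    k: int = DEFAULT_K,
    scaled: int = DEFAULT_SCALED,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first redundancy filtering.

    Records are visited by descending total translation length (ties by
    record id); a record is kept iff its max containment against every
    already kept record stays below ``threshold``, otherwise it is dropped
    and mapped to the first kept record exceeding the threshold.  Keeping
    the longest first retains the most complete record of each redundant
    group.
    """
    sketches = {r.record_id: sketch(r, k=k, scaled=scaled) for r in records}

    def total_len(r: GeneClusterRecord) -> int:
        return sum(len(c.translation) for c in r.cds)

    ordered = sorted(records, key=lambda r: (-total_len(r), r.record_id))
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for rec in ordered:
        s = sketches[rec.record_id]
        representative = None
        for kept_id in kept:
            if max_containment(s, sketches[kept_id]) >= threshold:
                representative = kept_id
                break
        if representative is None:
            kept.append(rec.record_id)
        else:
            dropped[rec.record_id] = representative
    return kept, dropped
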