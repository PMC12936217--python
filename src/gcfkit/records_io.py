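"""Parsing of gene cluster GenBank files into hierarchical records.

Two input dialects are supported: antiSMASH-style GenBank files carrying
``region`` / ``cand_cluster`` / ``protocluster`` / ``proto_core`` features
with ``product`` / ``category`` / ``gene_kind`` qualifiers, and minimal
GenBank files with only CDS features ("forced" mode), which yield a single
unannotated region per sequence.

Coordinates are 1-based inclusive on disk (GenBank convention) and 0-based
half-open internally; Biopython already performs that conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.SeqFeature import SeqFeature

logger = logging.getLogger(__name__)

RECORD_TYPES = ("region", "cand_cluster", "protocluster", "proto_core")

#: Legacy class labels of the eight-way classification scheme.
LEGACY_CLASSES = (
    "PKS1",
    "PKSOther",
    "NRPS",
    "NRPS-PKS-hybrid",
    "RiPP",
    "Saccharide",
    "Terpene",
    "Others",
)


class InputError(ValueError):
    """Raised when an input file cannot be parsed."""


class ClassificationError(ValueError):
    """Raised when a classification scheme cannot be applied to a record."""


@dataclass(frozen=True)
class CdsFeature:
    """One protein-coding feature attached to a gene cluster record.

    ``is_core`` is true iff the CDS carries a core-biosynthetic annotation
    (``gene_kind`` = ``biosynthetic``), i.e. it is one of the CDSs
    responsible for detection of the cluster.
    """

    ordinal: int
    nt_start: int
    nt_stop: int
    strand: int
    translation: str
    is_core: bool = False

    def __post_init__(self) -> None:
        if self.nt_start >= self.nt_stop:
            raise ValueError(
                f"CDS span must be non-empty: [{self.nt_start}, {self.nt_stop})"
            )

    @property
    def midpoint(self) -> float:
        return (self.nt_start + self.nt_stop) / 2


@dataclass
class GeneClusterRecord:
    """One comparable unit: a region, cand_cluster, protocluster or proto_core."""

    record_id: str
    source_path: str
    record_type: str
    nt_start: int
    nt_stop: int
    parent_region_id: str | None = None
    products: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)
    cds: list[CdsFeature] = field(default_factory=list)
    contig_edge: bool = False
    minimal: bool = False

    def __post_init__(self) -> None:
        if self.record_type not in RECORD_TYPES:
            raise ValueError(f"unknown record type {self.record_type!r}")
        if self.record_type != "region" and self.parent_region_id is None:
            raise ValueError("non-region records require a parent_region_id")


@dataclass(frozen=True)
class TopologicalLink:
    """Two records derived from the same parent region (reported, not compared)."""

    record_a: str
    record_b: str
    parent_region_id: str

    def __post_init__(self) -> None:
        if self.record_a == self.record_b:
            raise ValueError("a record cannot be topologically linked to itself")


def _qualifier(feature: SeqFeature, key: str) -> list[str]:
    return list(feature.qualifiers.get(key, []))


def _feature_span(feature: SeqFeature) -> tuple[int, int]:
    return int(feature.location.start), int(feature.location.end)


def _cds_features(seq_record, *, skip_untranslatable: bool = True) -> list[CdsFeature]:
    """Extract CDS features in genomic order, translating from sequence if needed."""
    out: list[CdsFeature] = []
    raw = [f for f in seq_record.features if f.type == "CDS"]
    raw.sort(key=lambda f: (int(f.location.start), int(f.location.end)))
    ordinal = 0
    for feat in raw:
        translations = _qualifier(feat, "translation")
        if translations:
            translation = translations[0]
        else:
            try:
                translation = str(feat.extract(seq_record.seq).translate(to_stop=True))
            except Exception:
                translation = ""
            if not translation:
                if skip_untranslatable:
                    logger.warning(
                        "skipping CDS at %s in %s: no translation available",
                        feat.location,
                        seq_record.id,
                    )
                    continue
                translation = ""
        is_core = "biosynthetic" in _qualifier(feat, "gene_kind")
        start, stop = _feature_span(feat)
        out.append(
            CdsFeature(
                ordinal=ordinal,
                nt_start=start,
                nt_stop=stop,
                strand=feat.location.strand or 1,
                translation=translation,
                is_core=is_core,
            )
        )
        ordinal += 1
    return out


def _assign_cds(
    record_span: tuple[int, int], all_cds: Sequence[CdsFeature]
) -> list[CdsFeature]:
    """CDSs whose midpoint falls inside the record span, re-numbered locally.

    Midpoint containment gives each CDS a unique owner even when
    neighbouring records overlap.
    """
    start, stop = record_span
    chosen = [c for c in all_cds if start <= c.midpoint < stop]
    return [
        CdsFeature(
            ordinal=i,
            nt_start=c.nt_start,
            nt_stop=c.nt_stop,
            strand=c.strand,
            translation=c.translation,
            is_core=c.is_core,
        )
        for i, c in enumerate(chosen)
    ]


def parse_genbank(
    path: str | Path,
    record_type: str = "region",
    force_minimal: bool = False,
) -> list[GeneClusterRecord]:
    """Parse one GenBank file into gene cluster records of the requested type.

    In forced (minimal) mode the whole sequence becomes a single region-type
    record with no products/categories and ``minimal=True``.  Otherwise one
    record per feature of the requested type is returned; non-region records
    carry the id of the region feature that spans them, and each CDS is
    attached to the record containing its midpoint.

    Raises
    ------
    InputError
        If the file cannot be parsed as GenBank.
    """
    path = Path(path)
    if record_type not in RECORD_TYPES:
        raise ValueError(f"unknown record type {record_type!r}")
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise InputError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not seq_records:
        raise InputError(f"no GenBank records found in {path}")

    out: list[GeneClusterRecord] = []
    for seq_index, seq_record in enumerate(seq_records):
        all_cds = _cds_features(seq_record)
        if force_minimal:
            span = (0, len(seq_record.seq))
            out.append(
                GeneClusterRecord(
                    record_id=f"{path.name}::region::{seq_index}",
                    source_path=str(path),
                    record_type="region",
                    nt_start=span[0],
                    nt_stop=span[1],
                    cds=_assign_cds(span, all_cds),
                    minimal=True,
                )
            )
            continue

        regions = [f for f in seq_record.features if f.type == "region"]
        wanted = [f for f in seq_record.features if f.type == record_type]
        if not wanted:
            logger.warning(
                "no %r features in %s record %s", record_type, path, seq_record.id
            )
            continue
        wanted.sort(key=lambda f: _feature_span(f))

        def parent_region_id(span: tuple[int, int]) -> str | None:
            for i, reg in enumerate(regions):
                rs, re = _feature_span(reg)
                if rs <= span[0] and span[1] <= re:
                    return f"{path.name}::region::{seq_index}.{i}"
            return None

        for feat_index, feat in enumerate(wanted):
            span = _feature_span(feat)
            products = _qualifier(feat, "product")
            categories = _qualifier(feat, "category")
            if not products and record_type != "region":
                # proto_core/cand_cluster features sometimes carry product only
                # on the enclosing protocluster; fall back to it.
                for f in seq_record.features:
                    if f.type == "protocluster":
                        ps, pe = _feature_span(f)
                        if ps <= span[0] and span[1] <= pe:
                            products = _qualifier(f, "product")
                            categories = categories or _qualifier(f, "category")
                            break
            record_id = f"{path.name}::{record_type}::{seq_index}.{feat_index}"
            parent = (
                None if record_type == "region" else parent_region_id(span)
            )
            if record_type != "region" and parent is None:
                parent = f"{path.name}::region::{seq_index}.0"
            contig_edge = _qualifier(feat, "contig_edge") == ["True"]
            out.append(
                GeneClusterRecord(
                    record_id=record_id,
                    source_path=str(path),
                    record_type=record_type,
                    nt_start=span[0],
                    nt_stop=span[1],
                    parent_region_id=parent,
                    products=products,
                    categories=categories,
                    cds=_assign_cds(span, all_cds),
                    contig_edge=contig_edge,
                )
            )
    return out


def _load_legacy_map() -> dict[str, str]:
    from importlib.resources import files

    text = files("gcfkit").joinpath("data/legacy_classes.yml").read_text()
    return yaml.safe_load(text)


_LEGACY_MAP: dict[str, str] | None = None


def legacy_class_map(override: dict[str, str] | None = None) -> dict[str, str]:
    """The product → legacy-class mapping (shipped default, user-overridable)."""
    global _LEGACY_MAP
    if _LEGACY_MAP is None:
        _LEGACY_MAP = _load_legacy_map()
    table = dict(_LEGACY_MAP)
    if override:
        table.update(override)
    return table


def _legacy_label(products: Iterable[str], table: dict[str, str]) -> str:
    mapped = {table.get(p, "Others") for p in products}
    if not mapped:
        return "Others"
    if len(mapped) == 1:
        return next(iter(mapped))
    pks = {"PKS1", "PKSOther"}
    if "NRPS" in mapped and mapped & pks and mapped <= (pks | {"NRPS"}):
        return "NRPS-PKS-hybrid"
    if "NRPS-PKS-hybrid" in mapped:
        return "NRPS-PKS-hybrid"
    return "Others"


def classify(
    record: GeneClusterRecord,
    scheme: str = "none",
    legacy_override: dict[str, str] | None = None,
) -> list[str]:
    """Bin labels for a record under a classification scheme.

    ``none`` puts every record in a single "mix" bin.  ``class`` joins the
    record's sorted product types into one composite label, ``category``
    does the same with antiSMASH categories, and ``legacy`` maps products
    onto the eight legacy classes (PKS1, PKSOther, NRPS, NRPS-PKS-hybrid,
    RiPP, Saccharide, Terpene, Others).
    """
    if scheme == "none":
        return ["mix"]
    if record.minimal:
        raise ClassificationError(
            f"record {record.record_id} was parsed in forced mode and has no "
            "annotations; use classification scheme 'none'"
        )
    if scheme == "class":
        return [".".join(sorted(set(record.products))) or "unknown"]
    if scheme == "category":
        return [".".join(sorted(set(record.categories))) or "unknown"]
    if scheme == "legacy":
        return [_legacy_label(record.products, legacy_class_map(legacy_override))]
    raise ValueError(f"unknown classification scheme {scheme!r}")


def topological_links(records: Sequence[GeneClusterRecord]) -> list[TopologicalLink]:
    """One link per unordered pair of records sharing a parent region.

    Region-type records have no parent and therefore yield no links.
    """
    by_parent: dict[str, list[GeneClusterRecord]] = {}
    for rec in records:
        if rec.parent_region_id is not None:
            by_parent.setdefault(rec.parent_region_id, []).append(rec)
    links: list[TopologicalLink] = []
    for parent, members in sorted(by_parent.items()):
        for a, b in combinations(sorted(members, key=lambda r: r.record_id), 2):
            links.append(TopologicalLink(a.record_id, b.record_id, parent))
    return links
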