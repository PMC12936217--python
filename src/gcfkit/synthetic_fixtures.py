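"""Synthetic antiSMASH-style GenBank fixtures with planted family structure.

Each planted family is defined by a template string of domain tokens and,
per domain token, a family-specific ancestral peptide.  Members are
mutated copies of the template: token substitutions, indels, segment
translocations, whole-record inversions and arm truncations at
configurable rates, with each member's per-domain amino-acid sequences
diverging from the family ancestor at a rate proportional to the token
substitution rate so that sequence-identity-based distances carry family
signal.  Members are rendered as GenBank records in the antiSMASH feature
dialect (region / protocluster / proto_core features, ``product`` /
``category`` / ``gene_kind`` qualifiers, one CDS per domain) together with
a matching precomputed domain-hit table and the ground-truth family
labeling, all fully reproducible from the seed.

What this emulates — and what it does not: planted families mimic the
structure of curated family-assignment datasets (clear within-family
homology, token-level divergence between families) but not real Pfam
domain architectures, taxonomic structure or intergenic context.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from gcfkit.benchmark_eval import Labeling

#: Token alphabet: biosynthetic-looking domain names; the first group is
#: flagged core (lives in gene_kind=biosynthetic CDSs).
DEFAULT_CORE_TOKENS = (
    "KS", "AT", "KR", "ACP", "C", "A", "PCP", "TE", "DH", "ER",
    "CY", "OX", "LANC", "LANM", "YCAO", "TFH", "TS", "PT",
)
DEFAULT_ACCESSORY_TOKENS = (
    "MT", "GT", "P450", "FAD", "SDR", "ABC", "MFS", "REG", "TETR",
    "PERM", "KIN", "PHOS", "HYD", "AMT", "EST", "LIP", "RED", "DEH",
    "ISO", "EPI", "SUF", "THI",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one unambiguous codon per amino acid for deterministic back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: family products cycle through these so every legacy class is exercised
_FAMILY_PRODUCTS = (
    ("T1PKS", "PKS"),
    ("NRPS", "NRPS"),
    ("terpene", "terpene"),
    ("lanthipeptide-class-i", "RiPP"),
    ("T2PKS", "PKS"),
    ("lassopeptide", "RiPP"),
    ("oligosaccharide", "saccharide"),
    ("NRPS-like", "NRPS"),
)


@dataclass
class FixtureSpec:
    """Parameters of the planted-family generator.

    Mutation rates are per-position (``p_sub``, ``p_indel``) or per-member
    (``p_shuffle``, ``p_invert``, ``p_truncate``) probabilities.
    """

    n_families: int = 5
    family_sizes: Sequence[int] | None = None  # default: 8 members each
    core_tokens: Sequence[str] = DEFAULT_CORE_TOKENS
    accessory_tokens: Sequence[str] = DEFAULT_ACCESSORY_TOKENS
    template_length: tuple[int, int] = (8, 14)
    peptide_length: tuple[int, int] = (40, 60)
    p_sub: float = 0.05
    p_indel: float = 0.05
    p_shuffle: float = 0.1
    p_invert: float = 0.0
    p_truncate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_indel", "p_shuffle", "p_invert", "p_truncate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.family_sizes is None:
            self.family_sizes = [8] * self.n_families
        if len(self.family_sizes) != self.n_families:
            raise ValueError("family_sizes length must equal n_families")
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")

    @property
    def vocab(self) -> list[str]:
        return list(self.core_tokens) + list(self.accessory_tokens)


@dataclass
class FixtureSet:
    """Paths and truth produced by :func:`generate`."""

    out_dir: Path
    gbk_files: list[Path]
    hits_tsv: Path
    truth_tsv: Path
    truth: Labeling
    hit_rows: list[tuple] = field(default_factory=list)


@dataclass
class _Family:
    index: int
    template: list[str]
    peptides: dict[str, str]  # token -> ancestral peptide
    product: str
    category: str


def _random_peptide(rng: random.Random, spec: FixtureSpec) -> str:
    length = rng.randint(*spec.peptide_length)
    return "".join(rng.choice(_AA) for _ in range(length))


def _mutate_peptide(rng: random.Random, peptide: str, rate: float) -> str:
    out = []
    for aa in peptide:
        if rng.random() < rate:
            out.append(rng.choice(_AA.replace(aa, "")))
        else:
            out.append(aa)
    return "".join(out)


def _make_family(rng: random.Random, index: int, spec: FixtureSpec) -> _Family:
    length = rng.randint(*spec.template_length)
    n_core = max(2, length // 3)
    core = rng.sample(list(spec.core_tokens), min(n_core, len(spec.core_tokens)))
    accessory = rng.sample(
        list(spec.accessory_tokens),
        min(length - len(core), len(spec.accessory_tokens)),
    )
    template = core + accessory
    rng.shuffle(template)
    # keep at least one core token mid-template so core-preferred anchoring
    # has something central to find
    peptides = {tok: _random_peptide(rng, spec) for tok in sorted(set(template))}
    product, category = _FAMILY_PRODUCTS[index % len(_FAMILY_PRODUCTS)]
    return _Family(index, template, peptides, product, category)


def _mutate_template(
    rng: random.Random, family: _Family, spec: FixtureSpec
) -> list[str]:
    vocab = spec.vocab
    tokens = list(family.template)
    # per-position substitutions
    tokens = [
        rng.choice(vocab) if rng.random() < spec.p_sub else tok for tok in tokens
    ]
    # indels
    out: list[str] = []
    for tok in tokens:
        roll = rng.random()
        if roll < spec.p_indel / 2:
            continue  # deletion
        out.append(tok)
        if roll > 1 - spec.p_indel / 2:
            out.append(rng.choice(vocab))  # insertion
    tokens = out or [family.template[0]]
    # segment translocation
    if len(tokens) > 3 and rng.random() < spec.p_shuffle:
        seg_len = rng.randint(1, max(1, len(tokens) // 3))
        start = rng.randint(0, len(tokens) - seg_len)
        segment = tokens[start : start + seg_len]
        rest = tokens[:start] + tokens[start + seg_len :]
        insert_at = rng.randint(0, len(rest))
        tokens = rest[:insert_at] + segment + rest[insert_at:]
    # arm truncation
    if len(tokens) > 3 and rng.random() < spec.p_truncate:
        cut = rng.randint(1, max(1, len(tokens) // 4))
        tokens = tokens[cut:] if rng.random() < 0.5 else tokens[:-cut]
    # whole-record inversion
    if rng.random() < spec.p_invert:
        tokens = tokens[::-1]
    return tokens


def _member_peptide(
    rng: random.Random, family: _Family, token: str, spec: FixtureSpec
) -> str:
    ancestor = family.peptides.get(token)
    if ancestor is None:  # substituted-in token foreign to the family
        return _random_peptide(rng, spec)
    return _mutate_peptide(rng, ancestor, spec.p_sub)


_GAP_NT = 30  # intergenic spacer


def _render_member(
    name: str,
    tokens: Sequence[str],
    peptides: Sequence[str],
    core_tokens: set[str],
    product: str,
    category: str,
    extra_features: Sequence[SeqFeature] = (),
) -> SeqRecord:
    """One antiSMASH-style GenBank record: a region feature spanning the
    sequence and one CDS per domain token."""
    pos = _GAP_NT
    cds_spans: list[tuple[int, int, str, str]] = []
    for token, peptide in zip(tokens, peptides):
        nt_len = 3 * len(peptide) + 3  # codons + stop
        cds_spans.append((pos, pos + nt_len, token, peptide))
        pos += nt_len + _GAP_NT
    total = pos
    seq = ["N"] * total
    for start, stop, _, peptide in cds_spans:
        nt = "".join(_CODON[aa] for aa in peptide) + "TAA"
        seq[start:stop] = nt
    record = SeqRecord(
        Seq("".join(seq)),
        id=name,
        name=name[:16],
        description="synthetic gene cluster fixture",
        annotations={"molecule_type": "DNA", "date": "01-JAN-1980",
                     "data_file_division": "BCT"},
    )
    region = SeqFeature(
        FeatureLocation(0, total),
        type="region",
        qualifiers={
            "product": [product],
            "category": [category],
            "contig_edge": ["False"],
        },
    )
    record.features.append(region)
    record.features.extend(extra_features)
    for start, stop, token, peptide in cds_spans:
        qualifiers = {
            "translation": [peptide],
            "locus_tag": [f"{name}_{token}_{start}"],
        }
        if token in core_tokens:
            qualifiers["gene_kind"] = ["biosynthetic"]
        record.features.append(
            SeqFeature(FeatureLocation(start, stop, strand=1), type="CDS",
                       qualifiers=qualifiers)
        )
    return record


def generate(spec: FixtureSpec, out_dir: str | Path) -> FixtureSet:
    """Write the planted dataset: GenBank files, hit table and truth labels.

    One GenBank file per member; the parser-visible record id of member m
    of family f is ``F<f>M<m>.gbk::region::0.0``.
    """
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    families = [_make_family(rng, i, spec) for i in range(spec.n_families)]
    core_set = set(spec.core_tokens)

    gbk_files: list[Path] = []
    truth: dict[str, str] = {}
    hit_rows: list[tuple] = []
    for family in families:
        for member in range(spec.family_sizes[family.index]):
            name = f"F{family.index}M{member}"
            tokens = _mutate_template(rng, family, spec)
            peptides = [
                _member_peptide(rng, family, tok, spec) for tok in tokens
            ]
            record = _render_member(
                name, tokens, peptides, core_set, family.product, family.category
            )
            path = out_dir / f"{name}.gbk"
            with open(path, "w") as fh:
                SeqIO.write([record], fh, "genbank")
            gbk_files.append(path)
            record_id = f"{name}.gbk::region::0.0"
            truth[record_id] = f"family_{family.index}"
            for ordinal, (tok, pep) in enumerate(zip(tokens, peptides)):
                hit_rows.append(
                    (record_id, ordinal, tok, 0, len(pep), 100.0, pep)
                )

    hits_tsv = out_dir / "hits.tsv"
    with open(hits_tsv, "w") as fh:
        fh.write("record_id\tcds_ordinal\tdomain_acc\taa_start\taa_stop\t"
                 "bitscore\tsubseq\n")
        for row in hit_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    truth_tsv = out_dir / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("record_id\tfamily\n")
        for rid in sorted(truth):
            fh.write(f"{rid}\t{truth[rid]}\n")

    return FixtureSet(out_dir, gbk_files, hits_tsv, truth_tsv, Labeling(truth),
                      hit_rows)


def make_region_with_protoclusters(
    n_proto: int, spec: FixtureSpec, out_path: str | Path
) -> Path:
    """One GenBank file whose single region contains ``n_proto``
    protoclusters (each with a proto_core), drawn from different planted
    families; exercises record-type slicing and topological links."""
    if n_proto < 1:
        raise ValueError("n_proto must be >= 1")
    rng = random.Random(spec.seed)
    families = [_make_family(rng, i, spec) for i in range(max(n_proto, spec.n_families))]
    core_set = set(spec.core_tokens)

    tokens: list[str] = []
    peptides: list[str] = []
    proto_bounds: list[tuple[int, int, str, str]] = []  # domain-index spans
    for p in range(n_proto):
        family = families[p]
        member_tokens = _mutate_template(rng, family, spec)
        start = len(tokens)
        tokens.extend(member_tokens)
        peptides.extend(
            _member_peptide(rng, family, tok, spec) for tok in member_tokens
        )
        proto_bounds.append((start, len(tokens), family.product, family.category))

    # map domain indices to nucleotide spans (mirrors _render_member layout)
    nt_spans: list[tuple[int, int]] = []
    pos = _GAP_NT
    for pep in peptides:
        length = 3 * len(pep) + 3
        nt_spans.append((pos, pos + length))
        pos += length + _GAP_NT

    extra: list[SeqFeature] = []
    region_products = sorted({p for _, _, p, _ in proto_bounds})
    region_categories = sorted({c for _, _, _, c in proto_bounds})
    extra.append(
        SeqFeature(
            FeatureLocation(0, pos),
            type="cand_cluster",
            qualifiers={"product": region_products, "category": region_categories},
        )
    )
    for d_start, d_stop, product, category in proto_bounds:
        nt_start = max(0, nt_spans[d_start][0] - _GAP_NT // 2)
        nt_stop = min(pos, nt_spans[d_stop - 1][1] + _GAP_NT // 2)
        extra.append(
            SeqFeature(
                FeatureLocation(nt_start, nt_stop),
                type="protocluster",
                qualifiers={"product": [product], "category": [category]},
            )
        )
        core_idx = [
            i for i in range(d_start, d_stop) if tokens[i] in core_set
        ] or list(range(d_start, d_stop))
        extra.append(
            SeqFeature(
                FeatureLocation(nt_spans[core_idx[0]][0], nt_spans[core_idx[-1]][1]),
                type="proto_core",
                qualifiers={"product": [product], "category": [category]},
            )
        )

    name = Path(out_path).stem[:10].upper() or "MERGED"
    record = _render_member(
        name, tokens, peptides, core_set,
        product=".".join(region_products), category=".".join(region_categories),
        extra_features=extra,
    )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        SeqIO.write([record], fh, "genbank")
    return out_path
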