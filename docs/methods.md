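# Methods

This note documents the models and procedures implemented in `gcfkit`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and the limits of what the synthetic test data can
show.

## Records and classification

GenBank coordinates are 1-based inclusive on disk and converted to
0-based half-open at parse time (Biopython does this conversion), so all
span arithmetic is uniform. A CDS is attached to the innermost requested
record whose span contains the CDS *midpoint*: antiSMASH neighbourhoods
overlap, and midpoint containment gives every CDS a unique owner. Records
parsed in forced mode (minimal GenBank, no antiSMASH features) become a
single region covering the sequence, carry no products or categories, and
are only usable with the `none` classification scheme.

Classification schemes: `none` puts everything in one `mix` bin; `class`
and `category` join the record's sorted product/category labels into a
composite bin label (e.g. `NRPS.T1PKS`) — the composite-label syntax is
this package's convention; `legacy` maps products onto the eight-way
legacy scheme via a shipped YAML table (`data/legacy_classes.yml`,
user-overridable). Hybrids mapping to both an NRPS and a PKS class become
`NRPS-PKS-hybrid`; other mixed mappings become `Others`. For a
`cand_cluster` spanning protoclusters with conflicting products the same
composite/hybrid rules apply — the underlying tools do not define this
case, so it is a package convention.

Records whose domain string is empty are excluded from all comparisons
(logged): all three distance components are undefined on empty strings.

## Domain annotation

Domain hits come from `pyhmmer.hmmsearch` over CDS translations, reported
at each profile's trusted cutoff when present, else at a bitscore floor
of 20.0 (permissive and explicit; configurable). Competing hits within a
CDS are resolved greedily by descending bitscore (ties: lower start, then
accession): a hit is dropped when it overlaps an already accepted hit by
more than 10% of the shorter of the two. The overlap rule is a
conventional choice — the tools this package models presume clean domain
strings without printing their rule. The filter's output is a function of
the input *set*, not its order.

Within a CDS, domains are ordered by translation coordinate regardless of
strand; whole-record inversions are handled by the reverse pass of the
anchor search, not by flipping per-CDS domain order, so there is exactly
one inversion mechanism and it is testable in isolation.

## Comparable region

The anchor ("LCS") is implemented as the longest common **contiguous
run** of domain tokens, computed for the partner string forward and
reversed. The published wording ("longest common subsequence") admits
both a contiguous and a gapped reading; the contiguous-run semantics
follows the predecessor implementation lineage, and a gapped-subsequence
variant is exposed behind `find_lcs(..., variant="subsequence")` without
any claim of equivalence. All *maximal* (inextensible) runs are
candidates; runs containing a core-flagged position in either record are
preferred, then longer runs, with ties broken towards forward
orientation, the run most central on the first record, then smaller
start indices. Because centrality is measured on the first argument,
tie-breaking is not symmetric in the pair; `compute_edge` therefore
canonicalizes every pair by record id and mirrors the resulting region
back, which makes the unordered-pair distance exactly symmetric.

Extension scores default to (match +5, mismatch −3, gap −2),
configurable; the penalty scheme is named but its constants are not
printed in the literature this follows, so the defaults follow the
predecessor's convention. Per side and per record:

* **greedy** extends to the outermost position whose token occurs
  anywhere in the partner record, including everything in between;
* **simple_match** walks outward one position at a time, scoring +match
  when the token is still available in the partner's outward arm
  (a multiset, each occurrence consumable once, nearest occurrence
  consumed first) and +mismatch otherwise; the boundary lands at the
  running-score maximum if positive, else stays at the anchor edge, and
  the partner's boundary is pushed outward to cover the farthest
  occurrence consumed before that maximum;
* **legacy** is simple_match plus a gap charge per partner position
  skipped between consecutive consumed occurrences.

Both records walk independently on each side; the final boundary per
record is the outermost of its own walk and the partner's coverage push.

Modes: `local` keeps the extended region; `global` is the full span pair;
`glocal` additionally extends, per side independently, whichever
record(s) have the shorter remaining arm to their end (ties extend both).
A pair sharing no token at all has an empty comparable region: distance
1.0 by convention under `local` (no evidence of relatedness), full global
spans under `glocal`.

## Distance

Components are computed on the comparable-region slices (`local`/
`glocal`) or the full strings (`global`); JC uses the slice type-sets —
whether the published tools slice JC in glocal mode is not stated, and
slicing is this package's choice, consistent with "define the region,
then measure". AI uses unordered consecutive-token pairs, which makes it
orientation-insensitive by construction (a reversed slice produces the
same pair set). DSS pairs the copies of each domain type one-to-one to
maximize summed amino-acid identity — exhaustively over permutations when
the smaller side has ≤ 4 copies, greedy best-first beyond — with unpaired
copies contributing 0 over `max(copies_a, copies_b)` slots per type.
Anchor domain types (user-supplied accession list; shipped default empty)
form a separate partition up-weighted by `anchor_boost` (default 2).

Per-domain identity is matched columns over aligned columns of a global
pairwise alignment with match +1, mismatch 0 and a small linear gap
penalty (−0.1 per gapped column, which only serves to suppress gratuitous
gaps; gapped columns count as unmatched). Identities are cached on the
subsequence pair, which is what keeps the all-vs-all stage fast. When a
profile database is supplied, identity is model-anchored instead: both
envelope subsequences are aligned to the profile's match states
(hmmalign) and identity is computed over the consensus columns occupied
by both, so insertions relative to the model carry no penalty.

The default weight scheme for the `mix` bin is
(w_JC, w_AI, w_DSS, anchor_boost) = (0.2, 0.05, 0.75, 2.0); a per-class
table ships as a config asset users can edit. The per-class calibration
itself is treated as configuration, not re-derived.

## Networks and family calling

Distances ≤ cutoff (inclusive) form the network; isolated records are
retained as singleton families when `include_singletons`. Each connected
component is clustered with affinity propagation implemented here as
plain responsibility/availability message passing with damping 0.9,
max 1000 iterations, and convergence declared after 200 iterations of a
stable exemplar set — stable defaults for small dense matrices, exposed
in config. No random noise is added, so clustering is deterministic;
after convergence the exemplar of each cluster is refined to the member
maximizing summed intra-cluster similarity (the standard finalization).
If the message-passing state is fully degenerate (no positive diagonal,
e.g. all similarities equal), the component collapses into a single
family; genuine non-convergence collapses the component under its
highest-degree member and is logged, never raised.

The preference is −5 for components with graph density ≥ 0.85 (both
configurable in `config.yml` terms), else the median off-diagonal
similarity — the standard default; only the dense case is prescribed by
the method this implements. Missing intra-component pairs (possible when
bins overlap) are filled with similarity 0: absence of evidence is
treated as dissimilarity.

## Vector path

Domain-count vectors over a pluggable vocabulary (default: all observed
accessions, sorted) are L2-normalized so Euclidean distance becomes a
cosine-like metric. Clustering is a deliberately minimal BIRCH-style
single pass: rows are inserted in record-id order; a row joins the
nearest subcluster if the merged subcluster's radius (root mean squared
distance to the merged centroid) stays ≤ the threshold, else it founds a
new subcluster. No CF-tree branching or node splitting is implemented —
at the scales this package targets the flat pass is exact enough and
deterministic; the insertion-order sensitivity inherent to single-pass
clustering is accepted and pinned by the sorted order. The default
threshold is 0.4 on normalized vectors; benchmark sweeps use a grid over
(0, 1.2]. Final centroids are subcluster means renormalized to unit
length; assignment (for training rows and for placing new records onto a
fitted model) is nearest-centroid by Euclidean distance, ties to the
lower centroid index.

## Benchmarking

Homogeneity, completeness and V use natural-log entropies (the measures
are base-invariant) and the unweighted harmonic mean (β = 1). Records
present in only one labeling are dropped with a logged count rather than
erroring, since compared tools may legitimately drop records. Because V
is not chance-adjusted, sweeps are compared at the cutoff whose computed
family count is closest to the curated count (ties to the lower cutoff).

## Dereplication

Protein k-mers (k = 10) of the concatenated CDS translations are hashed
with a fixed-key 64-bit blake2b; hashes below 2⁶⁴/scaled (scaled = 100)
form the sketch, so the expected sketch size is the distinct-k-mer count
divided by `scaled`. Max containment |A∩B|/min(|A|,|B|) ≥ 0.9 marks
redundancy. The greedy pass visits records longest-first so the most
complete record of each redundant group is kept and fragments map to
their fuller representative. All three parameters are explicit
configuration: the near-identical regime is the target, and no published
threshold is reproduced.

## Synthetic data

The generator plants `n_families` templates of 8–14 domain tokens drawn
from a 40-token alphabet (18 core-flagged, 22 accessory), with a
family-specific ancestral peptide (40–60 aa) per token. Members mutate
the template with per-position token substitution (`p_sub`, default
0.05) and indels (`p_indel`, 0.05), per-member segment translocation
(`p_shuffle`, 0.1), whole-record inversion (`p_invert`, 0) and arm
truncation (`p_truncate`, 0); member peptides diverge from the family
ancestor at rate `p_sub`, so sequence-identity distances carry the same
family signal as token content. Default study conditions are 5 families
× 8 members. Everything is driven by one `random.Random(seed)` stream,
and outputs are byte-identical across runs.

What passing tests show: the pipeline recovers planted structure whose
within-family divergence is token- and residue-level noise around a
template. What they do not show: behavior on real Pfam architectures,
shared domains between genuinely different families at realistic rates,
taxonomic correlation structure, or contig-break artifacts.

## Problem sizes

The default test and acceptance runs use 40-record datasets (780 pairwise
comparisons) over 10 seeds for recovery, 500 random pairs for the
alignment oracle, 500 random labelings for the V-measure oracle, and a
40-node component grid (possible densities spaced 1/780 apart) for the
density-trigger scan — sizes chosen so the whole suite runs in well under
a minute on one CPU while still exercising every code path.

## Known limitations

* The contiguous-run anchor is single-block: multi-segment rearrangements
  are handled only through the extension strategies' tolerance, not by
  multi-block comparable regions.
* Reverse matching considers one whole-record flip, not per-segment
  inversions.
* Model-anchored identities are computed per pair on demand and are not
  cached across pairs, so profile-based runs are slower than
  hit-table-based runs.
* BIRCH order sensitivity is pinned, not eliminated.
* The run database reuses distances keyed by (pair, bin, mode, strategy);
  changing extension scores or weights without changing those keys will
  reuse stale edges — delete the database when changing scoring config.
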