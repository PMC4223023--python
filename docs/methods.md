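# Methods

## Problem and model

Syntenic regions — pairs of chromosomal intervals of common evolutionary
origin in two species — are produced by macro-rearrangement analyses at
maximal length, deliberately ignoring small internal reorderings. This
package refines such pre-computed regions into *blocks of perfectly
conserved gene order* and, in doing so, identifies every
micro-rearrangement that separates the two genomes within a region:

* **internal translocation** — a run of genes relocated within its region,
* **inversion** — a run whose gene order (and typically strand) is
  reversed,
* **external translocation** — a run of genes moved from one syntenic
  region into another.

The unit of comparison is the *syntenic one-to-one ortholog pair*. Raw
orthology calls contain one-to-many and many-to-many co-ortholog groups;
a pre-processing stage reduces them to one pair per gene before any order
analysis.

## Ortholog resolution

Within one region, orthology links whose two endpoints both lie in the
region form a bipartite graph; its connected components are the ortholog
groups. Resolution proceeds per group:

1. **One-to-many** groups keep the single link with the highest combined
   identity (mean of the two directional percent identities); all other
   member genes are removed. Ties are broken by the smaller genomic rank
   distance between the two genes within their regions, then
   lexicographic gene id, so the result is deterministic.
2. **Asymmetric many-to-many** groups (n x m, n != m) are trimmed to
   symmetry: the |n - m| genes on the larger side with the lowest average
   identity to their linked partners are removed (ascending ranking;
   id-based tie-break).
3. **Symmetric groups** are split positionally: each side is sorted by
   genomic position and the i-th gene of one species is paired with the
   i-th of the other. Gene order, not link identity, decides — the goal is
   the positionally equivalent copy, so an emitted pair need not
   correspond to an input link.

Genes without any link are set aside (they are invisible to order
analysis), and genes overlapping another gene of the same species in
coordinates are excluded outright — all participants of an overlap, since
there is no principled way to keep one. Genes whose links all point into
*different* regions are deferred to external detection. Genes with both
internal and external links resolve on their internal links only; their
external links are discarded with a log message (this mixed class is rare
in real data and never generated by the synthetic fixtures).

Region membership itself is decided by the gene's midpoint: a gene
belongs to the region whose interval contains its midpoint on the
matching chromosome. Genes straddling a boundary thereby get one
deterministic home; genes in no region are reported as
syntenic-block-free.

## Breakpoints, strips and block peeling

Order pairs by coordinate in species A and let `pi[i]` be the rank of
pair i's partner among the region's B-genes. A **breakpoint** sits after
position i whenever `|pi[i+1] - pi[i]| != 1`: two neighbours in A whose
partners are not neighbours in B. Maximal breakpoint-free runs
("strips") are contiguous in both species with consecutive monotone
ranks; they are the candidate blocks and backbone pieces. When a segment
relocates, exactly two breakpoints appear, one at each end, so strips and
rearranged segments coincide.

Peeling iterates to a fixpoint:

1. **Orientation rule.** The backbone must run in the region's annotated
   orientation (ascending ranks for same-orientation regions, descending
   for opposite; unannotated regions default to "same"). Any multi-pair
   strip running counter to it is an inversion block and is extracted
   outright, shortest first. This is what lets an inversion covering the
   majority of a region — or the whole of it — be recognised as a block
   rather than be mistaken for backbone, and it is the reason a region
   whose genes are almost all reversed yields one large inversion block
   and a small (possibly empty) backbone.
2. **Shorter-segment rule.** Among co-oriented strips, each breakpoint
   proposes the shorter of its two flanking segments (segments being
   delimited by the adjacent breakpoints, with the region ends as
   reference points); the globally smallest proposal is extracted as a
   translocation block. Choosing globally rather than at the first
   breakpoint keeps the procedure symmetric in the two species: the same
   translocated segment is found whichever genome is used as the
   reference, because strips are species-symmetric objects and the
   smallest proposal is the same from either side.
3. Ranks are recomputed over the surviving pairs and the process repeats
   until no breakpoint remains. Each extraction removes at least one
   pair, so at most n iterations occur. The final backbone permutation is
   strictly monotone; blocks extracted in later iterations are
   consecutive monotone runs *in the ranks current at extraction time*
   (recorded on each block), which is the natural reading of the block
   invariant under fixpoint peeling. Re-ranking also lets nested
   structure emerge: a small block peeled early can sit inside the
   coordinate span of a larger block peeled later; the nesting parent is
   assigned afterwards by smallest strict A-span containment.

Ties in the shorter-segment comparison are broken by fewer spanned base
pairs in A, then by preferring the downstream segment; the global
choice among proposals orders by pair count, A-span, then A-position.
These tie-breaks only matter for symmetric configurations (e.g. equal
flanks around a moved segment) and make the output deterministic.

**Classification.** A multi-pair block is an inversion iff its ranks
descend; gene strands are checked against the order-based call and a
disagreement is logged, with order winning — strand annotations are
noisier than order. A single-pair block cannot show order reversal, so it
is classified by strands: an inversion iff its strand relation
(strand_A == strand_B) differs from the backbone's dominant relation.

**Limitations of the shorter-segment rule.** When a moved segment is as
long as, or longer than, the backbone pieces flanking it, the rule
attributes the wrong side (this is inherent to the definition, not to
the implementation). The synthetic generator therefore keeps planted
translocations strictly shorter than every backbone segment of their
region — shorter than half the region in aggregate — mirroring the
method's own asymmetry assumption. A stray single backbone gene isolated
between two rearrangements is likewise indistinguishable from a
single-gene translocation.

## External translocations

After internal resolution, a gene with no ortholog inside its own region
whose link partner (a) lies in a different region and (b) is itself
internally unpaired forms an external pair; both endpoints must be
unpaired, which preserves the one-pair-per-gene invariant. A gene
eligible for several partners takes the highest combined identity
(logged). Maximal runs of consecutive external pairs joining the same
two regions with consistent order are merged into one external region,
so a run of genes moved together is reported as a single event. External
regions take the A-side (source) region as parent; derived regions of
one parent — internal and external alike — are numbered
`<parent>_<k>` in A-coordinate order and span their member genes in each
species.

## Track comparison

For a positional feature track (BED3, or BED4 with a numeric weight),
each gene receives one value over its full annotated span: the covered
fraction of its base pairs (unweighted) or the length-weighted average
signal with uncovered bases contributing zero (weighted). The weighted
denominator is the full gene length — not the covered length — so the
weighted case degenerates exactly to the unweighted one at weight 1.
Overlapping track elements stack additively.

Per species the value vector over the ortholog pairs is standardised
(population SD, fixed for determinism; at genome scale the choice is
immaterial; a constant vector yields zeros with a warning), and each
pair scores `d_i = |z_A,i - z_B,i|`, with the vector mean as the track
pair's similarity summary. Standardising both sides makes the measure
symmetric in the species and invariant to positive rescaling of either
track. For two unrelated tracks `d_i` behaves like |Z1 - Z2| for
independent standard normals, with expectation `2/sqrt(pi) ~ 1.1284` —
the natural null anchor. Significance against a randomized track (same
per-chromosome element counts and length multiset, uniform starts,
overlaps permitted) uses a one-sided two-sample rank-sum test
(normal approximation with tie correction) for "real differences are
smaller than random".

## k-mer sequence distance

Two sequences are compared via their overlapping k-mer occurrence
profiles (k = 6 by default, counted case-insensitively in one pass;
windows containing non-ACGT symbols are dropped and counted). The
distance is the Manhattan distance between the two count profiles over
the union of observed k-mers. Raw counts, not frequencies, are used, so
length differences contribute to the distance by design; an optional
post-hoc normalization by the combined window count is available and off
by default. A dictionary profile is equivalent to the depth-k trie
traversal formulation and keeps the single-pass linear-time contract.

## Synthetic data generator

The generator emulates the shape of a mammalian genome-pair comparison:
two species with one chromosome each, regions laid out sequentially,
every gene with one ortholog whose percent identities are drawn in
[60, 100], and gene lengths log-normal around 45-60 kb (cosmetic — the
detector sees only order). Species B starts as a collinear mirror of A
and events are planted by rewriting B's gene order: translocations
relocate a run (1 up to `max_block_genes` genes), inversions reverse a
run of >= 2 genes in place and flip its strands (a single-gene in-place
inversion leaves no order signal and is excluded by construction),
external events move a run of B-genes into another region, and
duplications add extra linked gene copies whose identities are ranked so
the intended resolution loser is known. Planted geometry is validated
with a strip decomposition — every planted run must surface as exactly
one strip, and every backbone strip must outnumber the longest planted
translocation of its region — and resampled on failure; the validator
shares only the strip primitive with the detector, not the peeling
logic.

Matched feature tracks place one weighted element per gene with
`value = sqrt(c) * shared + sqrt(1 - c) * noise` for conservation level
c: identical values at c = 1, independent at c = 0, expected mean
difference shrinking like `sqrt(1 - c)` in between.

What the fixtures do **not** model: gene loss and gain (beyond orphan
genes created by external moves), unequal gene counts between species,
nested planted events, boundary-straddling genes, assembly gaps,
multi-chromosome layouts, and real sequence evolution. Passing tests
therefore demonstrate correctness of the order-based machinery under the
method's stated assumptions, not robustness to annotation noise in real
genomes.

## Numerical and interface choices

* Coordinates: 1-based inclusive in the gene/region/ortholog TSVs
  (ENSEMBL convention), 0-based half-open in BED and in all internal
  arithmetic, converted only at I/O boundaries.
* Duplicate ortholog rows are merged keeping the maximum identity per
  direction, with a warning; identities outside [0, 100] are errors.
* Gene order within a region is by start coordinate, ties by end then id.
* All randomness flows through explicit seeds (`numpy.random.default_rng`);
  writers emit sorted, formatted text so identical inputs give
  byte-identical outputs. CLI outputs carry `#` provenance headers
  (version, config hash, seed) that are themselves deterministic.

## Problem sizes used in the test suite

The exhaustive peeling check covers all 5,913 permutations of up to 7
genes. Planted-recovery and reference-symmetry sweeps use 1,000 seeded
fixtures of 20 regions x 50 genes with 1-10 internal and 0-2 external
events (blocks <= 5 genes). The track null uses 10,000 ortholog pairs;
the k-mer oracle check uses 500 pairs of 10 kb sequences; the
full-scale structural check uses 356 regions x 55 genes (~19.6k
orthologs), which refines in well under a second of wall time.
`scripts/acceptance.py` reports the same quantities from 200 planted
fixtures plus the full-scale timing.
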