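# Methods

## The model

A *taxonomy* is a partition of a fixed universe of specimens (or terminal
lineage units) into labeled species. The unit of comparison is not the
specimen but the **speciation-event hypothesis**: on a dichotomous species
tree, delimiting *k* species is equivalent to endorsing *k* − 1 cladogenetic
events. Two taxonomies are compared through their event sets:

- C_tax(A, B) = n(A ∩ B) / n(A ∪ B) — Jaccard similarity of event sets;
  1 − C_tax is consequently a proper Jaccard distance (symmetric, triangle
  inequality), which the test suite asserts on randomized nested triples.
- R_tax(A) = n(A) / n(union over all compared methods).

### Tree-based mode

Events are materialized as internal nodes of a rooted, strictly bifurcating
guide tree on which every species of every compared taxonomy is a clade. A
node is an event of taxonomy A iff the leaves it subtends are a disjoint union
of ≥ 2 complete species of A. Node identity is **topological** — a node is
the frozenset of its leaf labels — so newick rotations of the same topology
yield identical event sets. Set intersection/union of event-node sets gives
n(A ∩ B) and n(A ∪ B) directly.

Polytomies are refused. The k − 1 identity presumes dichotomy, and there is
no agreed semantics for sharing events across a soft polytomy; rather than
invent one, tree-based mode raises a clear error directing users to tree-free
mode. Likewise, species are required to be clades, not merely connected
edge-cut components: paraphyletic nominal taxa occur as *inputs* to
delimitation, but the delimited species this package compares are clades.

### Tree-free mode

No tree is needed: n(A) = k_A − 1 by the dichotomy identity, and for a
*laminar* pair (every cluster of A and cluster of B nested or disjoint)

    n(A ∪ B) = |meet(A, B)| − 1,
    n(A ∩ B) = (k_A − 1) + (k_B − 1) − n(A ∪ B),

where meet is the common refinement. Laminarity is exactly the condition that
both partitions fit on one species tree; non-laminar pairs have no defined
tree-free C_tax and are refused with a crossing-cluster witness rather than
generalized — any generalization would be an invention of this package, not a
property of the index. The two modes agree exactly on every valid shared
instance; the test suite verifies this equivalence on 500 random instances
(≤ 40 leaves), using the two independent code paths as mutual oracles.

Degenerate case: two single-species taxonomies share the same empty event set;
C_tax is defined as 1.0 there, with a warning, and R_tax is undefined (error)
when *no* method supports any event.

### Rounding

All index values are kept at full precision internally. Display and
table-reproduction rounding is decimal **half-up** at a configurable number of
decimals (default 2, matching the published table), applied only at the
serialization boundary. Published tables contain at least one apparent
truncation, so internal precision is never discarded.

## The haploweb consensus

Per locus, build a graph whose vertices are the locus's alleles with an edge
joining the two alleles of each phased diploid specimen (a self-loop for
homozygotes). Connected components are the *fields for recombination* (FFRs);
a specimen belongs to the FFR holding its alleles. Only sharing and
co-occurrence matter — haplotype-network topology (statistical parsimony,
connection limits) is deliberately not computed, as it plays no role in the
delimitation rule.

Across loci, a specimen pair is *separated* at a locus when both have data
there and fall in different FFRs. The pair is delimited as heterospecific when
its separating-locus count reaches the threshold T (default 3, the
three-of-four-markers rule). Design choices:

- **Chains.** "Separated by < T loci" is not transitive. The consensus
  partition is the connected components of that relation (single linkage):
  lumping wins along chains, the conservative reading. The per-pair count
  table is part of the result so forced merges can be audited.
- **Missing data.** A locus with no data for either member of a pair
  abstains. T is an absolute count by default (not rescaled by informative
  loci); an optional proportional mode (ceil of T/L × informative loci) is
  available but off by default.
- **Populations vs specimens.** The consensus operates at specimen level;
  pooling specimens into populations beforehand is the user's preprocessing
  choice.

## Synthetic data generator

The generators emulate the structural conditions of a single-genus,
multi-method comparison; defaults mirror that scale (34 terminal units;
seven methods with 9–34 species; four nuclear loci; no admixture):

- `generate_guide_tree` — uniform random pair-joining of subtrees. No branch
  lengths or coalescent times: the indices are topology-only.
- `generate_nested_taxonomies` — each taxonomy is drawn by random refinement
  from the root, so its species are clades; clade partitions of one tree are
  automatically pairwise laminar, and a `chain` flag additionally makes each
  partition refine the previous.
- `inflate_specimens` — replicates specimens within their species (uniformly
  or per-specimen, copies suffixed `#n`), the probe for specimen-count bias.
- `generate_haplotype_table` — per locus, either species-private allele pools
  or (admixed loci) one global pool. Every specimen carries its pool's first
  "major" allele plus one uniformly drawn pool member, modelling a
  high-frequency ancestral haplotype still segregating in each population.
  This makes each species one FFR at every clean locus *by construction*, so
  the consensus-recovery tests measure the consensus rule, not the vagaries
  of within-species allele sharing. `admixture_rate` draws admixed loci
  per-locus Bernoulli; `n_admixed_loci` fixes their exact number instead,
  which is how the one-admixed-locus recovery condition is realized.

What the generator does **not** emulate: sequence evolution, incomplete
lineage sorting, unequal sampling across loci, genotyping error, or partial
allele sharing between young species. Passing recovery tests therefore show
the consensus rule behaves correctly under its own assumptions, not that real
four-marker data always yields the true species.

All generators are pure functions of their inputs and an integer seed.

## The packaged worked example

The fixture encodes the published *outputs* of seven delimitation protocols
for *Madascincus* over 34 terminal units (the finest method's species),
plus a binary guide tree compatible with all seven partitions and the
published comparison table verbatim. The delimitation analyses themselves
(Bayesian phylogenetics, assignment tests, GMYC fitting, phasing) are out of
scope — only their resulting partitions are data here.

Where the published account under-determines which subunits a split separates
(e.g. how the finest method's five polleni-group species distribute over the
northern and southern clades), the encoding picks one assignment consistent
with (a) every method nesting inside the finest partition and (b) the
published per-nominal-species split counts. The table cells that reproduce
under recomputation are invariant to this freedom; cells that cannot be
reconciled with the event-count model under *any* such encoding (the BSD
resolving power, two BSD congruence values forced to 0.58 by integer
arithmetic, one congruence value and three column means that appear
mis-rounded, and every congruence value involving the figure-derived HW
partition) are stored with `consistent = False` and reported as *flagged* by
the regression check — documented, never corrected.

## Numerical and interface choices

- Meet labels are deterministic `"aLabel|bLabel"` composites; consensus and
  FFR component ids are numbered by first appearance in input order — all
  outputs are byte-identical across runs.
- Specimen universes must be identical across methods. A
  `restrict_to_shared` escape hatch drops incompletely labeled rows with a
  loud warning; silent subsetting would change what the indices mean.
- Missing species assignments are illegal rather than implicit singletons —
  implicit singletons would silently inflate event counts.
- Identical species labels in different columns carry no cross-method
  meaning; comparison is purely by cluster content.

## Known limitations

- Tree-free mode cannot compare incompatible (non-laminar) taxonomies at all;
  that is a property of the index, faithfully enforced.
- The haploweb consensus's single-linkage lumping can chain distant specimens
  into one species through intermediates; inspect the emitted pair-count
  table when that matters.
- No uncertainty quantification: the indices are descriptive; no bootstrap
  over specimens or significance test of congruence is provided.
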