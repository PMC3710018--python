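"""Seeded generators for trees, nested taxonomies and haplotype tables.

These generators emulate the structural setting the comparison indices assume:
several delimitation methods whose species are all clades of one guide tree,
and multi-locus diploid genotype data in which species carry private allele
pools except at occasional admixed loci.  They simulate no sequences, mutation
models or coalescent times — the event-set metrics are topology-only, so the
pair-joining tree model (uniform random cherry merging, no branch lengths)
suffices.  All outputs are pure functions of their inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import TaxonomyError
from .haploweb import HaplotypeTable
from .partition import SpeciesPartition, SpecimenUniverse, TaxonomyCollection
from .tree import GuideTree, tree_from_string

__all__ = [
    "SimulationConfig",
    "generate_guide_tree",
    "generate_nested_taxonomies",
    "inflate_specimens",
    "generate_haplotype_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic generators.

    Defaults mirror the scale of a single-genus multi-method study: 34
    terminal units, seven methods ranging from 9 coarse to 34 fully split
    species, four nuclear loci, and no admixture.  ``admixture_rate`` is the
    per-locus probability of drawing alleles from a global pool (a lumping
    signal); ``n_admixed_loci``, when set, fixes the exact number of admixed
    loci instead.  ``alleles_per_species`` counts alleles in each private
    pool; every specimen carries its pool's first ("major") allele plus one
    random pool member, so each species is one connected field for
    recombination by construction — emulating a common ancestral haplotype
    still segregating in every population.
    """

    seed: int = 0
    n_specimens: int = 34
    species_counts: tuple[int, ...] = (9, 11, 12, 13, 13, 20, 34)
    n_loci: int = 4
    alleles_per_species: int = 4
    admixture_rate: float = 0.0
    inflation_factor: int = 1
    n_admixed_loci: int | None = None

    def __post_init__(self):
        if self.n_specimens < 1 or self.n_loci < 1 or self.alleles_per_species < 1:
            raise TaxonomyError("all counts must be positive")
        if not 0.0 <= self.admixture_rate <= 1.0:
            raise TaxonomyError("admixture_rate must lie in [0, 1]")
        if self.inflation_factor < 1:
            raise TaxonomyError("inflation_factor must be >= 1")
        if any(k < 1 for k in self.species_counts):
            raise TaxonomyError("species counts must be positive")
        if self.n_admixed_loci is not None and not (
            0 <= self.n_admixed_loci <= self.n_loci
        ):
            raise TaxonomyError("n_admixed_loci must lie in [0, n_loci]")


def _specimen_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"s{i:0{width}d}" for i in range(1, n + 1)]


def generate_guide_tree(cfg: SimulationConfig) -> GuideTree:
    """Random rooted binary tree over ``cfg.n_specimens`` leaves.

    Iterative pair-joining: start from the leaves and repeatedly merge two
    uniformly chosen subtrees until one root remains.
    """
    if cfg.n_specimens < 2:
        raise TaxonomyError("a guide tree needs at least two leaves")
    rng = np.random.default_rng(cfg.seed)
    nodes = _specimen_labels(cfg.n_specimens)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return tree_from_string(nodes[0] + ";")


def _clade_partition(
    t: GuideTree, frontier: list[frozenset[str]], k: int, rng: np.random.Generator
) -> list[frozenset[str]]:
    """Refine ``frontier`` (a clade partition) to exactly ``k`` clades."""
    children: dict[frozenset[str], list[frozenset[str]]] = {}
    # reconstruct the child map from the postorder clade list
    clades = list(t.internal_clades)
    all_nodes = [frozenset([l]) for l in t.leaf_labels] + clades
    for clade in clades:
        kids = []
        remaining = set(clade)
        # children are the maximal strict sub-nodes; scan from largest
        for cand in sorted(all_nodes, key=len, reverse=True):
            if cand < clade and cand <= remaining:
                kids.append(cand)
                remaining -= cand
        children[clade] = kids
    frontier = list(frontier)
    while len(frontier) < k:
        splittable = [f for f in frontier if len(f) > 1]
        if not splittable:
            raise TaxonomyError(f"cannot refine to {k} species: out of internal nodes")
        pick = splittable[rng.integers(len(splittable))]
        frontier.remove(pick)
        frontier.extend(children[pick])
    return frontier


def generate_nested_taxonomies(
    t: GuideTree,
    species_counts: Sequence[int],
    seed: int = 0,
    chain: bool = True,
    method_names: Sequence[str] | None = None,
) -> TaxonomyCollection:
    """Taxonomies whose species are clades of ``t``, one per requested count.

    Each partition is produced by random refinement from the root, so every
    species is a clade; clade partitions of one tree are automatically
    pairwise laminar.  With ``chain=True`` the counts are processed in
    ascending order and each partition refines the previous one.
    """
    n = t.n_leaves
    for k in species_counts:
        if not 1 <= k <= n:
            raise TaxonomyError(f"species count {k} impossible on a {n}-leaf tree")
    rng = np.random.default_rng(seed)
    universe = SpecimenUniverse(tuple(t.leaf_labels))
    if method_names is None:
        method_names = [f"M{i + 1}" for i in range(len(species_counts))]
    if len(method_names) != len(species_counts):
        raise TaxonomyError("method_names and species_counts length mismatch")

    order = (
        sorted(range(len(species_counts)), key=lambda i: species_counts[i])
        if chain
        else list(range(len(species_counts)))
    )
    root = frozenset(t.leaf_labels)
    frontier = [root]
    partitions: list[SpeciesPartition | None] = [None] * len(species_counts)
    for idx in order:
        k = species_counts[idx]
        start = frontier if chain else [root]
        frontier_k = _clade_partition(t, start, k, rng)
        if chain:
            frontier = frontier_k
        assignment = {}
        for ci, clade in enumerate(
            sorted(frontier_k, key=lambda c: min(universe.ids.index(s) for s in c))
        ):
            for s in clade:
                assignment[s] = f"sp{ci + 1}"
        partitions[idx] = SpeciesPartition(
            method_name=str(method_names[idx]), universe=universe, assignment=assignment
        )
    return TaxonomyCollection(universe=universe, partitions=tuple(partitions))


def inflate_specimens(
    c: TaxonomyCollection, factor, seed: int = 0
) -> TaxonomyCollection:
    """Replicate specimens within their species, consistently across methods.

    ``factor`` is either one integer multiplier for every specimen or a
    mapping specimen -> multiplier (for deliberately unbalanced inflation).
    Copies receive ``"#n"`` suffixes so provenance stays auditable.  Species
    counts — and therefore every C_tax and R_tax value — are unchanged; the
    Rand index generally is not, which is the point of the exercise.
    """
    if isinstance(factor, int):
        if factor < 1:
            raise TaxonomyError("inflation factor must be >= 1")
        per = {s: factor for s in c.universe}
    else:
        per = {s: int(factor.get(s, 1)) for s in c.universe}
        if any(v < 1 for v in per.values()):
            raise TaxonomyError("inflation factors must be >= 1")
    new_ids: list[str] = []
    origin: dict[str, str] = {}
    for s in c.universe:
        new_ids.append(s)
        origin[s] = s
        for i in range(2, per[s] + 1):
            nid = f"{s}#{i}"
            new_ids.append(nid)
            origin[nid] = s
    universe = SpecimenUniverse(tuple(new_ids))
    partitions = tuple(
        SpeciesPartition(
            method_name=p.method_name,
            universe=universe,
            assignment={nid: p.assignment[origin[nid]] for nid in new_ids},
        )
        for p in c
    )
    return TaxonomyCollection(universe=universe, partitions=partitions)


def generate_haplotype_table(
    true_partition: SpeciesPartition, cfg: SimulationConfig
) -> HaplotypeTable:
    """Species-structured phased genotypes for the haploweb consensus.

    Per locus: with probability ``cfg.admixture_rate`` (or for exactly
    ``cfg.n_admixed_loci`` loci when set) the locus is *admixed* and every
    specimen draws from one global allele pool; otherwise each species owns a
    private pool.  In both cases a specimen carries the pool's major allele
    plus one uniformly drawn pool member, so non-admixed loci reproduce the
    true partition exactly and admixed loci collapse everything into one field
    for recombination.
    """
    rng = np.random.default_rng(cfg.seed)
    specs = list(true_partition.universe)
    labels = true_partition.labels
    records: list[tuple[str, str, str, str]] = []
    if cfg.n_admixed_loci is not None:
        admixed_idx = set(
            rng.choice(cfg.n_loci, size=cfg.n_admixed_loci, replace=False).tolist()
        )
    else:
        admixed_idx = {
            i for i in range(cfg.n_loci) if rng.random() < cfg.admixture_rate
        }
    for li in range(cfg.n_loci):
        locus = f"L{li + 1}"
        if li in admixed_idx:
            pools = {lab: [f"{locus}_g{j + 1}" for j in range(cfg.alleles_per_species)]
                     for lab in labels}
        else:
            pools = {
                lab: [f"{locus}_{lab}_a{j + 1}" for j in range(cfg.alleles_per_species)]
                for lab in labels
            }
        for s in specs:
            pool = pools[true_partition.assignment[s]]
            a = pool[0]
            b = pool[int(rng.integers(len(pool)))]
            records.append((s, locus, a, b))
    return HaplotypeTable(tuple(records))
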