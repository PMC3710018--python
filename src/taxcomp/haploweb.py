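"""Haploweb species delimitation: fields for recombination and their consensus.

A *field for recombination* (FFR) at one nuclear locus is a pool of alleles
connected by co-occurrence: build a graph whose vertices are the locus's
alleles with an edge between the two alleles of every (phased, diploid)
specimen, and take connected components.  Specimens carrying alleles of the
same component belong to the same FFR — a proxy for an interbreeding unit.
Only allele sharing and co-occurrence matter here; haplotype-network topology
plays no role in the delimitation itself.

Across loci, two specimens are delimited as distinct species when at least
``min_separating`` loci place them in different FFRs (the majority-consensus
rule; with four markers the conservative choice is three of four).  The
"separated by fewer than T loci" relation is not transitive, so the consensus
partition is taken as its connected components: lumping wins along chains,
and the per-pair count table is returned so forced merges can be audited.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .errors import TableFormatError, TaxonomyError
from .partition import SpeciesPartition, SpecimenUniverse

__all__ = [
    "HaplotypeTable",
    "LocusFFR",
    "ConsensusResult",
    "read_haplotype_table",
    "read_phased_fasta",
    "single_locus_ffr",
    "majority_consensus",
]

_MISSING = {"", "NA", "na", "NaN", "nan", "."}


@dataclass(frozen=True)
class HaplotypeTable:
    """Phased diploid genotypes: one record per (specimen, locus).

    Allele identifiers are opaque labels, unique within a locus; homozygotes
    carry the same label twice and allele order within a record is irrelevant.
    A missing record means the specimen was not sequenced at that locus.
    """

    records: tuple[tuple[str, str, str, str], ...]  # (specimen, locus, allele_a, allele_b)

    def __post_init__(self):
        seen = set()
        for spec, locus, a, b in self.records:
            key = (spec, locus)
            if key in seen:
                raise TableFormatError(
                    f"duplicate record for specimen {spec!r} at locus {locus!r}"
                )
            seen.add(key)

    @property
    def loci(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for _, locus, _, _ in self.records:
            out.setdefault(locus, None)
        return tuple(out)

    @property
    def specimens(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for spec, _, _, _ in self.records:
            out.setdefault(spec, None)
        return tuple(out)

    def locus_records(self, locus: str) -> list[tuple[str, str, str]]:
        recs = [(s, a, b) for s, l, a, b in self.records if l == locus]
        if not recs:
            raise TaxonomyError(f"unknown locus {locus!r}")
        return recs


@dataclass(frozen=True)
class LocusFFR:
    """Single-locus fields for recombination: specimen -> component id."""

    locus: str
    assignment: dict[str, int]
    n_components: int
    allele_components: dict[str, int] = field(default_factory=dict, compare=False)

    def partition_over(self, specimens: Sequence[str]) -> dict[str, int | None]:
        return {s: self.assignment.get(s) for s in specimens}


def read_haplotype_table(path, dialect: str = "tsv") -> HaplotypeTable:
    """Read a specimen/locus/allele_a/allele_b table; NA or absent row = missing."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise TableFormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = ["specimen", "locus", "allele_a", "allele_b"]
    if list(df.columns[:4]) != required:
        raise TableFormatError(
            f"haplotype table must start with columns {required}, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        a, b = str(row.allele_a).strip(), str(row.allele_b).strip()
        if a in _MISSING and b in _MISSING:
            continue
        if a in _MISSING or b in _MISSING:
            raise TableFormatError(
                f"half-missing genotype for specimen {row.specimen!r} at locus "
                f"{row.locus!r}; mark both alleles NA or neither"
            )
        records.append((str(row.specimen), str(row.locus), a, b))
    return HaplotypeTable(tuple(records))


def read_phased_fasta(path, locus: str) -> list[tuple[str, str, str, str]]:
    """Read one locus's phased alleles from FASTA: two sequences per specimen.

    Record ids may end in ``/1``, ``/2``, ``_a`` or ``_b`` (stripped to get the
    specimen id); otherwise the two consecutive records sharing an id are taken
    as the two alleles.  Identical sequences (exact string match after
    uppercasing; no alignment) receive identical allele ids ``h1, h2, ...`` in
    order of first appearance.
    """
    per_spec: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        for suffix in ("/1", "/2", "_a", "_b"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
        seq = str(rec.seq).upper()
        per_spec.setdefault(name, []).append(seq)
        if name not in order:
            order.append(name)
    allele_ids: dict[str, str] = {}
    records = []
    for spec in order:
        seqs = per_spec[spec]
        if len(seqs) != 2:
            raise TableFormatError(
                f"specimen {spec!r} has {len(seqs)} sequences at locus {locus!r}; "
                f"expected exactly two phased alleles"
            )
        labels = []
        for seq in seqs:
            if seq not in allele_ids:
                allele_ids[seq] = f"h{len(allele_ids) + 1}"
            labels.append(allele_ids[seq])
        records.append((spec, locus, labels[0], labels[1]))
    return records


def single_locus_ffr(h: HaplotypeTable, locus: str) -> LocusFFR:
    """Fields for recombination at one locus.

    Alleles are graph vertices; every specimen's record contributes the edge
    (allele_a, allele_b) — a self-loop for homozygotes.  Components are the
    transitive closure of allele sharing and co-occurrence; each specimen with
    data maps to the (necessarily unique) component holding its alleles.
    """
    recs = h.locus_records(locus)
    g = nx.Graph()
    for _, a, b in recs:
        g.add_edge(a, b)
    comp_of: dict[str, int] = {}
    # deterministic component ids: order components by first allele appearance
    appearance: dict[str, int] = {}
    for _, a, b in recs:
        appearance.setdefault(a, len(appearance))
        appearance.setdefault(b, len(appearance))
    comps = sorted(
        (sorted(comp, key=appearance.__getitem__) for comp in nx.connected_components(g)),
        key=lambda members: appearance[members[0]],
    )
    for idx, members in enumerate(comps):
        for allele in members:
            comp_of[allele] = idx
    assignment = {spec: comp_of[a] for spec, a, b in recs}
    return LocusFFR(
        locus=locus,
        assignment=assignment,
        n_components=len(comps),
        allele_components=comp_of,
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Multi-locus consensus delimitation plus its audit trail."""

    partition: SpeciesPartition
    separating_counts: dict[tuple[str, str], int]
    informative_counts: dict[tuple[str, str], int]
    threshold: int
    proportional: bool

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, self.separating_counts[(a, b)], self.informative_counts[(a, b)])
            for (a, b) in self.separating_counts
        ]
        return pd.DataFrame(
            rows, columns=["specimen_a", "specimen_b", "n_separating", "n_informative"]
        )


def majority_consensus(
    ffrs: Sequence[LocusFFR],
    min_separating: int = 3,
    specimens: Sequence[str] | None = None,
    proportional: bool = False,
    method_name: str = "HW-consensus",
) -> ConsensusResult:
    """Consensus species partition from per-locus FFRs.

    For each specimen pair, count loci where both have data and fall in
    different FFRs; the pair is kept in one species when that count is below
    the threshold, and species are the connected components of this relation.
    The default ``min_separating=3`` encodes the three-of-four-markers rule.

    A locus with no data for one of the two specimens abstains; by default the
    threshold is an absolute count, not rescaled by the number of informative
    loci.  With ``proportional=True`` the per-pair threshold becomes
    ``ceil(min_separating / n_loci * n_informative)`` instead.
    """
    if not ffrs:
        raise TaxonomyError("majority consensus requires at least one locus")
    if min_separating < 1:
        raise TaxonomyError("min_separating must be >= 1")
    n_loci = len(ffrs)
    if min_separating > n_loci:
        warnings.warn(
            f"min_separating={min_separating} exceeds the number of loci "
            f"({n_loci}); no pair can be separated and each co-sampled "
            f"component collapses to one species",
            UserWarning,
            stacklevel=2,
        )
    if specimens is None:
        ordered: dict[str, None] = {}
        for f in ffrs:
            for s in f.assignment:
                ordered.setdefault(s, None)
        specimens = tuple(ordered)
    else:
        specimens = tuple(specimens)

    sep_counts: dict[tuple[str, str], int] = {}
    info_counts: dict[tuple[str, str], int] = {}
    g = nx.Graph()
    g.add_nodes_from(specimens)
    for a, b in itertools.combinations(specimens, 2):
        informative = 0
        separating = 0
        for f in ffrs:
            ca, cb = f.assignment.get(a), f.assignment.get(b)
            if ca is None or cb is None:
                continue
            informative += 1
            if ca != cb:
                separating += 1
        sep_counts[(a, b)] = separating
        info_counts[(a, b)] = informative
        if proportional:
            thr = math.ceil(min_separating / n_loci * informative) if informative else 1
            thr = max(thr, 1)
        else:
            thr = min_separating
        if separating < thr:
            g.add_edge(a, b)

    label_of: dict[str, str] = {}
    comps = sorted(
        (sorted(comp, key=specimens.index) for comp in nx.connected_components(g)),
        key=lambda members: specimens.index(members[0]),
    )
    for idx, members in enumerate(comps, start=1):
        for s in members:
            label_of[s] = f"sp{idx}"
    partition = SpeciesPartition(
        method_name=method_name,
        universe=SpecimenUniverse(tuple(specimens)),
        assignment=label_of,
    )
    return ConsensusResult(
        partition=partition,
        separating_counts=sep_counts,
        informative_counts=info_counts,
        threshold=min_separating,
        proportional=proportional,
    )
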