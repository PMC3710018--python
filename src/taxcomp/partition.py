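"""Species partitions over a shared specimen universe.

A *taxonomy*, for the purposes of this package, is one delimitation method's
partition of a fixed set of specimens (or terminal lineage units) into labeled
species clusters.  A taxonomy with ``k`` species implicitly supports ``k - 1``
cladogenetic speciation events on a dichotomous species tree; that identity is
what connects partitions to the event-set metrics in :mod:`taxcomp.metrics`.

Species labels are meaningful only *within* a method: two methods using the
same label string do not thereby claim the same species.  All comparisons are
by cluster content.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import TableFormatError, UniverseMismatchError

__all__ = [
    "SpecimenUniverse",
    "SpeciesPartition",
    "TaxonomyCollection",
    "ValidationReport",
    "meet",
    "is_laminar",
    "validate_collection",
    "read_taxonomy_table",
    "write_taxonomy_table",
]


@dataclass(frozen=True)
class SpecimenUniverse:
    """Ordered set of unique specimen (terminal-unit) identifiers."""

    ids: tuple[str, ...]

    def __post_init__(self):
        if not self.ids:
            raise TableFormatError("specimen universe must be non-empty")
        seen = set()
        for s in self.ids:
            if s in seen:
                raise TableFormatError(f"duplicate specimen id {s!r}")
            seen.add(s)
        object.__setattr__(self, "_idset", frozenset(self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self._idset

    def __iter__(self):
        return iter(self.ids)

    @property
    def idset(self) -> frozenset[str]:
        return self._idset


@dataclass(frozen=True)
class SpeciesPartition:
    """One method's taxonomy: a total assignment of specimens to species labels.

    Parameters
    ----------
    method_name:
        Name of the delimitation method (e.g. ``"GMYC"``).
    universe:
        The specimen universe the partition covers.
    assignment:
        Total map from specimen id to species label.  Every specimen of the
        universe must appear exactly once; missing assignments are an error
        rather than implicit singletons, because silently created singletons
        would inflate event counts.
    """

    method_name: str
    universe: SpecimenUniverse
    assignment: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.universe if s not in self.assignment]
        if missing:
            raise TableFormatError(
                f"method {self.method_name!r}: no species label for specimens {missing}"
            )
        extra = set(self.assignment) - self.universe.idset
        if extra:
            raise TableFormatError(
                f"method {self.method_name!r}: labels for unknown specimens {sorted(extra)}"
            )
        for s in self.universe:
            lab = self.assignment[s]
            if lab is None or (isinstance(lab, float)) or str(lab).strip() == "":
                raise TableFormatError(
                    f"method {self.method_name!r}: empty species label for specimen {s!r}"
                )
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def labels(self) -> tuple[str, ...]:
        """Species labels in order of first appearance along the universe."""
        seen: dict[str, None] = {}
        for s in self.universe:
            seen.setdefault(self.assignment[s], None)
        return tuple(seen)

    def clusters(self) -> dict[str, frozenset[str]]:
        """Map label -> specimen set, labels in first-appearance order."""
        out: dict[str, set[str]] = {}
        for s in self.universe:
            out.setdefault(self.assignment[s], set()).add(s)
        return {lab: frozenset(mem) for lab, mem in out.items()}

    def cluster_sets(self) -> list[frozenset[str]]:
        return list(self.clusters().values())

    @property
    def n_species(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def n_events(self) -> int:
        """Number of speciation events supported in tree-free mode (k - 1)."""
        return self.n_species - 1

    def same_universe(self, other: "SpeciesPartition") -> None:
        if self.universe.idset != other.universe.idset:
            raise UniverseMismatchError(
                self.universe.idset - other.universe.idset,
                other.universe.idset - self.universe.idset,
                context=f"{self.method_name!r} vs {other.method_name!r}",
            )

    def is_refinement_of(self, other: "SpeciesPartition") -> bool:
        """True if every cluster of ``self`` lies inside one cluster of ``other``."""
        self.same_universe(other)
        for mem in self.cluster_sets():
            labels = {other.assignment[s] for s in mem}
            if len(labels) > 1:
                return False
        return True


@dataclass(frozen=True)
class TaxonomyCollection:
    """Several methods' partitions over one identical specimen universe."""

    universe: SpecimenUniverse
    partitions: tuple[SpeciesPartition, ...]

    def __post_init__(self):
        names = [p.method_name for p in self.partitions]
        if len(names) != len(set(names)):
            raise TableFormatError(f"duplicate method names in collection: {names}")
        for p in self.partitions:
            if p.universe.idset != self.universe.idset:
                raise UniverseMismatchError(
                    self.universe.idset - p.universe.idset,
                    p.universe.idset - self.universe.idset,
                    context=f"collection universe vs method {p.method_name!r}",
                )

    @property
    def method_names(self) -> tuple[str, ...]:
        return tuple(p.method_name for p in self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def __getitem__(self, name: str) -> SpeciesPartition:
        for p in self.partitions:
            if p.method_name == name:
                return p
        raise KeyError(name)

    def species_counts(self) -> dict[str, int]:
        return {p.method_name: p.n_species for p in self.partitions}


def meet(a: SpeciesPartition, b: SpeciesPartition) -> SpeciesPartition:
    """Common refinement of two partitions.

    Two specimens share a cluster of the meet iff they share a cluster in both
    ``a`` and ``b``.  Labels are the deterministic composite ``"aLabel|bLabel"``
    so repeated runs are byte-identical.
    """
    a.same_universe(b)
    assignment = {
        s: f"{a.assignment[s]}|{b.assignment[s]}" for s in a.universe
    }
    return SpeciesPartition(
        method_name=f"{a.method_name}&{b.method_name}",
        universe=a.universe,
        assignment=assignment,
    )


def meet_all(parts: Sequence[SpeciesPartition]) -> SpeciesPartition:
    """Common refinement of any number of partitions (left fold of :func:`meet`)."""
    if not parts:
        raise TableFormatError("meet_all requires at least one partition")
    acc = parts[0]
    for p in parts[1:]:
        acc = meet(acc, p)
    return acc


def is_laminar(
    a: SpeciesPartition, b: SpeciesPartition
) -> tuple[bool, tuple[frozenset[str], frozenset[str]] | None]:
    """Check that the clusters of ``a`` and ``b`` jointly form a laminar family.

    Returns ``(True, None)`` when every cluster of ``a`` and every cluster of
    ``b`` are either nested or disjoint — the compatibility condition under
    which both taxonomies can sit on one species tree and the tree-free C_tax
    is defined.  On failure returns ``(False, (cluster_a, cluster_b))`` with
    one crossing pair as witness.
    """
    a.same_universe(b)
    for ca in a.cluster_sets():
        for cb in b.cluster_sets():
            inter = ca & cb
            if inter and not (ca <= cb or cb <= ca):
                return False, (ca, cb)
    return True, None


@dataclass
class ValidationReport:
    """Read-only summary of a collection: sizes, singletons, pairwise laminarity."""

    species_counts: dict[str, int]
    singletons: dict[str, list[str]]
    laminar_pairs: dict[tuple[str, str], bool] = field(default_factory=dict)
    witnesses: dict[tuple[str, str], tuple[frozenset, frozenset]] = field(
        default_factory=dict
    )
    notes: list[str] = field(default_factory=list)

    @property
    def all_laminar(self) -> bool:
        return all(self.laminar_pairs.values())

    def to_text(self) -> str:
        lines = ["Taxonomy collection validation", "=" * 32]
        for m, k in self.species_counts.items():
            sing = self.singletons.get(m, [])
            lines.append(f"{m}: {k} species, {len(sing)} singleton(s)")
        for (ma, mb), ok in self.laminar_pairs.items():
            if ok:
                lines.append(f"{ma} / {mb}: laminar")
            else:
                wa, wb = self.witnesses[(ma, mb)]
                lines.append(
                    f"{ma} / {mb}: NOT laminar; crossing clusters "
                    f"{sorted(wa)} vs {sorted(wb)}"
                )
        lines.extend(self.notes)
        return "\n".join(lines)


def validate_collection(c: TaxonomyCollection) -> ValidationReport:
    """Summarize per-method species counts, singleton species and pairwise laminarity."""
    counts = c.species_counts()
    singles = {
        p.method_name: sorted(
            lab for lab, mem in p.clusters().items() if len(mem) == 1
        )
        for p in c
    }
    report = ValidationReport(species_counts=counts, singletons=singles)
    names = c.method_names
    if len(names) < 2:
        report.notes.append(
            "only one method present: pairwise comparisons unavailable"
        )
        return report
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ok, wit = is_laminar(c[names[i]], c[names[j]])
            report.laminar_pairs[(names[i], names[j])] = ok
            if not ok:
                report.witnesses[(names[i], names[j])] = wit
    return report


# ---------------------------------------------------------------------------
# I/O: taxonomy table (TSV/CSV; column 1 = specimen id, others = methods)
# ---------------------------------------------------------------------------

_SEPARATORS = {"tsv": "\t", "csv": ","}


def read_taxonomy_table(
    path, dialect: str = "tsv", restrict_to_shared: bool = False
) -> TaxonomyCollection:
    """Read a taxonomy table into a :class:`TaxonomyCollection`.

    The table is UTF-8 with a header row; the first column holds specimen ids
    and each remaining column one method's species labels.  Method order
    follows column order and specimen order follows row order.  Empty cells
    and duplicate specimen ids are hard errors.

    ``restrict_to_shared`` exists only for tables assembled from unequally
    sampled studies: it drops rows with any missing label, with a loud warning,
    because comparing taxonomies over different specimen sets is not what the
    indices are defined for.
    """
    if dialect not in _SEPARATORS:
        raise TableFormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    header = text.splitlines()[0].split(_SEPARATORS[dialect]) if text else []
    if len(header) != len(set(header)):
        raise TableFormatError(f"duplicate method column names: {header}")
    df = pd.read_csv(
        io.StringIO(text), sep=_SEPARATORS[dialect], dtype=str, keep_default_na=False
    )
    return taxonomy_from_frame(df, restrict_to_shared=restrict_to_shared)


def taxonomy_from_frame(
    df: pd.DataFrame, restrict_to_shared: bool = False
) -> TaxonomyCollection:
    """Build a collection from a DataFrame shaped like the on-disk table."""
    if df.shape[1] < 2:
        raise TableFormatError(
            "taxonomy table needs a specimen-id column plus >= 1 method column"
        )
    cols = list(df.columns)
    if len(cols) != len(set(cols)):
        raise TableFormatError(f"duplicate method column names: {cols}")
    id_col = cols[0]
    methods = cols[1:]
    ids = [str(v) for v in df[id_col]]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise TableFormatError(f"duplicate specimen id(s): {sorted(dupes)}")

    if restrict_to_shared:
        mask = (df[methods].astype(str).apply(lambda s: s.str.strip()) != "").all(axis=1)
        if not mask.all():
            dropped = [str(v) for v in df.loc[~mask, id_col]]
            warnings.warn(
                f"restrict_to_shared: dropping {len(dropped)} specimen(s) with "
                f"missing labels ({dropped}); the congruence indices are defined "
                f"over one shared sample set — interpret results with care",
                UserWarning,
                stacklevel=2,
            )
            df = df.loc[mask]
            ids = [str(v) for v in df[id_col]]

    universe = SpecimenUniverse(tuple(ids))
    partitions = []
    for m in methods:
        assignment = {}
        for row_i, (s, lab) in enumerate(zip(ids, df[m]), start=2):
            lab = str(lab).strip()
            if lab == "":
                raise TableFormatError(
                    f"empty species label at row {row_i} (specimen {s!r}), "
                    f"column {m!r}"
                )
            assignment[s] = lab
        partitions.append(
            SpeciesPartition(method_name=str(m), universe=universe, assignment=assignment)
        )
    return TaxonomyCollection(universe=universe, partitions=tuple(partitions))


def write_taxonomy_table(c: TaxonomyCollection, path, dialect: str = "tsv") -> None:
    """Write a collection back to the tabular format read by :func:`read_taxonomy_table`."""
    if dialect not in _SEPARATORS:
        raise TableFormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    rows = []
    for s in c.universe:
        rows.append([s] + [p.assignment[s] for p in c])
    df = pd.DataFrame(rows, columns=["specimen", *c.method_names])
    df.to_csv(path, sep=_SEPARATORS[dialect], index=False)


def taxonomy_to_string(c: TaxonomyCollection, dialect: str = "tsv") -> str:
    buf = io.StringIO()
    write_taxonomy_table(c, buf, dialect=dialect)
    return buf.getvalue()
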