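"""Congruence (C_tax) and resolving-power (R_tax) indices, plus Rand baselines.

Both indices live on *speciation-event sets*.  A taxonomy with k species
supports k - 1 events; for a pair of taxonomies A, B

    C_tax(A, B) = n(A ∩ B) / n(A ∪ B)

where n(A ∩ B) counts events congruently supported by both and n(A ∪ B) events
supported by at least one — a Jaccard index on event sets.  R_tax(A) is A's
event count divided by the size of the union of events over *all* compared
methods; the method whose events exhaust the union scores 1.0.

Event sets can be materialized on a guide tree (tree mode) or counted
implicitly from species numbers (tree-free mode): for laminar pairs the union
event count equals |meet(A, B)| - 1, because the common refinement's clusters
are exactly the species bounded by some event of either taxonomy.  Both modes
agree exactly whenever both apply.

Unlike the Rand index, which counts agreeing *specimen pairs* and is therefore
pulled around by how many specimens happen to sit in each cluster, event-set
indices depend only on where the species boundaries fall.

All values are kept at full precision internally; rounding (decimal half-up)
is a display concern, applied only when serializing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, rand_score

from .errors import NonLaminarError, TaxonomyError
from .partition import (
    SpeciesPartition,
    TaxonomyCollection,
    is_laminar,
    meet,
    meet_all,
)
from .tree import EventSet, GuideTree, extract_event_nodes

__all__ = [
    "PairwiseComparison",
    "CongruenceReport",
    "ctax_pair",
    "rtax",
    "mean_ctax",
    "compare_all",
    "rand_index",
    "adjusted_rand_index",
    "round_half_up",
]

Mode = Literal["tree", "free"]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 dp), as in printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairwiseComparison:
    """C_tax bookkeeping for one pair of taxonomies.

    ``n_shared`` is n(A ∩ B), ``n_union`` is n(A ∪ B); the conservation law
    ``n_shared + n_union == n_a + n_b`` holds by construction.
    """

    method_a: str
    method_b: str
    n_a: int
    n_b: int
    n_shared: int
    n_union: int
    mode: Mode

    def __post_init__(self):
        assert self.n_union == self.n_a + self.n_b - self.n_shared
        assert 0 <= self.n_shared <= min(self.n_a, self.n_b)

    @property
    def ctax(self) -> float:
        if self.n_union == 0:
            # both taxonomies are a single species: identical (empty) event sets
            return 1.0
        return self.n_shared / self.n_union


def _events_free(a: SpeciesPartition, b: SpeciesPartition) -> tuple[int, int]:
    """(n_shared, n_union) for a laminar pair without a tree."""
    ok, witness = is_laminar(a, b)
    if not ok:
        raise NonLaminarError(a.method_name, b.method_name, *witness)
    n_union = meet(a, b).n_species - 1
    n_shared = (a.n_species - 1) + (b.n_species - 1) - n_union
    return n_shared, n_union


def ctax_pair(
    a: SpeciesPartition,
    b: SpeciesPartition,
    mode: Mode = "free",
    t: GuideTree | None = None,
) -> PairwiseComparison:
    """Taxonomic index of congruence between two taxonomies.

    Tree mode intersects/unions explicit event-node sets on ``t``; tree-free
    mode requires the pair to be laminar and uses the common-refinement count.
    """
    a.same_universe(b)
    if mode == "tree":
        if t is None:
            raise TaxonomyError("tree mode requires a guide tree")
        ea = extract_event_nodes(a, t)
        eb = extract_event_nodes(b, t)
        n_shared = len(ea.nodes & eb.nodes)
        n_union = len(ea.nodes | eb.nodes)
    elif mode == "free":
        n_shared, n_union = _events_free(a, b)
    else:
        raise TaxonomyError(f"unknown mode {mode!r}; use 'tree' or 'free'")
    if n_union == 0:
        warnings.warn(
            f"both {a.method_name!r} and {b.method_name!r} delimit a single "
            f"species; C_tax defined as 1.0 over empty event sets",
            UserWarning,
            stacklevel=2,
        )
    return PairwiseComparison(
        method_a=a.method_name,
        method_b=b.method_name,
        n_a=a.n_species - 1,
        n_b=b.n_species - 1,
        n_shared=n_shared,
        n_union=n_union,
        mode=mode,
    )


def rtax(
    c: TaxonomyCollection,
    mode: Mode = "free",
    t: GuideTree | None = None,
) -> dict[str, float]:
    """Relative taxonomic resolving power of every method in the collection.

    The denominator is the total number of events supported by any method:
    the size of the union of all event sets (tree mode) or the event count of
    the meet of all partitions (tree-free mode, which requires the whole
    collection to be pairwise laminar).
    """
    if len(c) < 2:
        raise TaxonomyError("R_tax requires at least two methods")
    if mode == "tree":
        if t is None:
            raise TaxonomyError("tree mode requires a guide tree")
        union: set[frozenset[str]] = set()
        for p in c:
            union |= extract_event_nodes(p, t).nodes
        denom = len(union)
    elif mode == "free":
        names = c.method_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ok, wit = is_laminar(c[names[i]], c[names[j]])
                if not ok:
                    raise NonLaminarError(names[i], names[j], *wit)
        denom = meet_all(list(c)).n_species - 1
    else:
        raise TaxonomyError(f"unknown mode {mode!r}; use 'tree' or 'free'")
    if denom == 0:
        raise TaxonomyError(
            "every method delimits a single species: no events, R_tax undefined"
        )
    return {p.method_name: (p.n_species - 1) / denom for p in c}


def total_union_events(
    c: TaxonomyCollection, mode: Mode = "free", t: GuideTree | None = None
) -> int:
    """Size of the union of speciation events over all methods."""
    any_rtax = rtax(c, mode=mode, t=t)
    # rtax = (k-1)/denom, recover denom from any method with k > 1
    for p in c:
        if p.n_species > 1:
            return round((p.n_species - 1) / any_rtax[p.method_name])
    raise TaxonomyError("no events in collection")


def mean_ctax(matrix: pd.DataFrame, method: str) -> float:
    """Mean of all pairwise C_tax values involving ``method``.

    ``matrix`` is a symmetric methods x methods frame (diagonal ignored); it
    may hold freshly computed full-precision values or, equally, a matrix of
    printed rounded values when reproducing a published table.
    """
    if method not in matrix.index:
        raise TaxonomyError(f"method {method!r} absent from matrix")
    vals = []
    for other in matrix.columns:
        if other == method:
            continue
        v = matrix.at[method, other]
        if pd.isna(v):
            raise TaxonomyError(f"missing pairwise value for ({method!r}, {other!r})")
        vals.append(float(v))
    if not vals:
        raise TaxonomyError("matrix has a single method; no pairwise values")
    return float(np.mean(vals))


@dataclass
class CongruenceReport:
    """The full comparison table for a collection: one row/column per method.

    Mirrors the usual published layout: a symmetric pairwise C_tax matrix with
    unit diagonal, plus per-method species counts, R_tax and mean C_tax, and
    the total number of events any method supports.
    """

    method_names: tuple[str, ...]
    species_counts: dict[str, int]
    ctax_matrix: pd.DataFrame
    rtax: dict[str, float]
    mean_ctax: dict[str, float]
    n_union_total: int
    mode: Mode
    pairwise: dict[tuple[str, str], PairwiseComparison]

    def rounded_matrix(self, decimals: int = 2) -> pd.DataFrame:
        return self.ctax_matrix.map(lambda v: round_half_up(v, decimals))

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """One summary frame: C_tax columns then Nb_species, Rtax, mean_Ctax."""
        mat = self.ctax_matrix.copy()
        extra = pd.DataFrame(
            {
                "Nb_species": [self.species_counts[m] for m in self.method_names],
                "Rtax": [self.rtax[m] for m in self.method_names],
                "mean_Ctax": [self.mean_ctax[m] for m in self.method_names],
            },
            index=list(self.method_names),
        )
        out = pd.concat([mat, extra], axis=1)
        if decimals is not None:
            for col in out.columns:
                if col != "Nb_species":
                    out[col] = out[col].map(lambda v: round_half_up(v, decimals))
        return out

    def to_csv(self, path, decimals: int | None = 2) -> None:
        self.to_frame(decimals=decimals).to_csv(path, index_label="method")

    def to_json_dict(self, decimals: int | None = None) -> dict:
        rnd = (lambda v: round_half_up(v, decimals)) if decimals is not None else float
        return {
            "mode": self.mode,
            "methods": list(self.method_names),
            "species_counts": self.species_counts,
            "ctax": {
                f"{a}|{b}": rnd(self.ctax_matrix.at[a, b])
                for i, a in enumerate(self.method_names)
                for b in self.method_names[i + 1 :]
            },
            "rtax": {m: rnd(v) for m, v in self.rtax.items()},
            "mean_ctax": {m: rnd(v) for m, v in self.mean_ctax.items()},
            "n_union_total": self.n_union_total,
        }


def compare_all(
    c: TaxonomyCollection,
    mode: Mode = "free",
    t: GuideTree | None = None,
) -> CongruenceReport:
    """Compute the full report (pairwise C_tax, R_tax, mean C_tax) for a collection."""
    if len(c) < 2:
        raise TaxonomyError("comparison requires at least two methods")
    names = c.method_names
    mat = pd.DataFrame(
        np.ones((len(names), len(names))), index=list(names), columns=list(names)
    )
    pairwise: dict[tuple[str, str], PairwiseComparison] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pc = ctax_pair(c[a], c[b], mode=mode, t=t)
            pairwise[(a, b)] = pc
            mat.at[a, b] = pc.ctax
            mat.at[b, a] = pc.ctax
    r = rtax(c, mode=mode, t=t)
    means = {m: mean_ctax(mat, m) for m in names}
    denom = total_union_events(c, mode=mode, t=t)
    return CongruenceReport(
        method_names=names,
        species_counts=c.species_counts(),
        ctax_matrix=mat,
        rtax=r,
        mean_ctax=means,
        n_union_total=denom,
        mode=mode,
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Baselines: pair-counting agreement indices
# ---------------------------------------------------------------------------


def _label_vectors(a: SpeciesPartition, b: SpeciesPartition):
    a.same_universe(b)
    if len(a.universe) < 2:
        raise TaxonomyError("Rand index needs at least two specimens")
    order = a.universe.ids
    return (
        [a.assignment[s] for s in order],
        [b.assignment[s] for s in order],
    )


def rand_index(a: SpeciesPartition, b: SpeciesPartition) -> float:
    """Plain pair-counting Rand index — the baseline the event-set indices replace.

    Counts specimen pairs on which the two taxonomies agree (together in both
    or apart in both) over all pairs, so clusters holding many specimens
    dominate the score.
    """
    la, lb = _label_vectors(a, b)
    return float(rand_score(la, lb))


def adjusted_rand_index(a: SpeciesPartition, b: SpeciesPartition) -> float:
    """Chance-adjusted Rand index (Hubert & Arabie)."""
    la, lb = _label_vectors(a, b)
    return float(adjusted_rand_score(la, lb))
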