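"""Exception hierarchy for taxonomy-comparison errors."""


class TaxonomyError(ValueError):
    """Base class for all validation and comparison errors."""


class UniverseMismatchError(TaxonomyError):
    """Two partitions (or a partition and a tree) cover different specimen sets."""

    def __init__(self, only_a, only_b, context=""):
        self.only_a = frozenset(only_a)
        self.only_b = frozenset(only_b)
        msg = "specimen universes differ"
        if context:
            msg += f" ({context})"
        if self.only_a:
            msg += f"; only in first: {sorted(self.only_a)}"
        if self.only_b:
            msg += f"; only in second: {sorted(self.only_b)}"
        super().__init__(msg)


class NonLaminarError(TaxonomyError):
    """Two partitions contain crossing clusters, so tree-free C_tax is undefined."""

    def __init__(self, method_a, method_b, cluster_a, cluster_b):
        self.method_a = method_a
        self.method_b = method_b
        self.cluster_a = frozenset(cluster_a)
        self.cluster_b = frozenset(cluster_b)
        super().__init__(
            f"C_tax undefined for incompatible taxonomies: cluster "
            f"{sorted(self.cluster_a)} of {method_a!r} crosses cluster "
            f"{sorted(self.cluster_b)} of {method_b!r}"
        )


class NonCladePartitionError(TaxonomyError):
    """A species of the partition is not a clade of the guide tree (tree mode only)."""

    def __init__(self, method, label, members):
        self.method = method
        self.label = label
        self.members = frozenset(members)
        super().__init__(
            f"species {label!r} of method {method!r} ({sorted(self.members)}) is not "
            f"a clade of the guide tree; use tree-free mode instead"
        )


class PolytomyError(TaxonomyError):
    """The guide tree is not strictly bifurcating, so event counting is undefined."""


class TableFormatError(TaxonomyError):
    """A taxonomy or haplotype table violates the input contract."""
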