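"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A numeric or structural parameter is outside its valid domain."""


class FormatError(RuntimeError):
    """A genotype file is malformed or internally inconsistent."""


class MergeConflictError(RuntimeError):
    """Allele pairs at one or more SNPs cannot be reconciled across panels."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            f"irreconcilable allele pairs at {len(self.snp_ids)} SNP(s): "
            + ", ".join(self.snp_ids[:10])
        )


class DimensionError(ValueError):
    """Array shapes do not agree (e.g. Q and F disagree on k)."""


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given input
    (e.g. F_st with no polymorphic loci, HWE test with zero counts)."""


class CyclicPedigreeError(RuntimeError):
    """The mating graph contains a cycle."""
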