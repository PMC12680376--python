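"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration value (bad counts, empty label lists, ...)."""


class DegeneratePatternError(ValueError):
    """A voxel pattern is constant (zero variance), so Pearson r is undefined."""


class DegenerateColumnError(ValueError):
    """A metric column is constant and cannot be standardized."""


class AlignmentError(ValueError):
    """Subject sets of two record collections do not match."""


class RankDeficientDesignError(ValueError):
    """Model design matrix is rank deficient; aliased terms are reported."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(self.aliased)
        )
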