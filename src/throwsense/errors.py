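"""Exception hierarchy for the throwsense pipeline."""


class ThrowsenseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ThrowsenseError):
    """A column mapping refers to a column that the file does not provide."""


class DataError(ThrowsenseError):
    """Input data violate a structural requirement (e.g. non-monotonic time)."""


class InsufficientDataError(ThrowsenseError):
    """Too few samples to perform the requested operation."""


class ContractError(ThrowsenseError):
    """An internal precondition was violated by the caller."""


class ConfigurationError(ThrowsenseError):
    """A configuration object is internally inconsistent or incomplete."""


class BalanceError(ThrowsenseError):
    """A repeated-measures table is missing subject x cell combinations."""

    def __init__(self, missing_cells):
        self.missing_cells = list(missing_cells)
        super().__init__(
            "incomplete repeated-measures crossing; missing cells: "
            + ", ".join(map(str, self.missing_cells))
        )
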