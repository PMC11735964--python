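"""Exception hierarchy.

Config/spec problems and data problems are kept distinct so the CLI can map
them to different exit codes.
"""


class SlabsplineError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SlabsplineError):
    """A basis or model specification is invalid (bad knots, bad strategy...)."""


class InvalidInputError(SlabsplineError):
    """Input data violate a precondition (negative doses, length mismatch...)."""


class CollinearityError(InvalidInputError):
    """Design matrix is rank deficient; message names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class InsufficientDataError(InvalidInputError):
    """Fewer observations than parameters."""


class InvalidReferenceError(InvalidInputError):
    """Requested reference dose is excluded by the model specification."""


class ConfigError(SlabsplineError):
    """A run configuration failed validation; message names the field."""
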