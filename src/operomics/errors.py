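"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/format problems exit 1,
anything unexpected exits 2.
"""


class OperomicsError(Exception):
    """Base class for all package errors."""


class FormatError(OperomicsError):
    """A file is not in the expected external format."""


class ValidationError(OperomicsError):
    """A value violates a documented contract (bad channel, bad range, ...)."""


class ResidueError(ValidationError):
    """A sequence contains a residue outside the 20 standard one-letter codes."""


class UndefinedPropertyError(ValidationError):
    """A property is mathematically undefined for the given input (e.g. II on L<2)."""


class GenerationError(OperomicsError):
    """A synthetic-data request is internally inconsistent (e.g. overlapping spans)."""
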