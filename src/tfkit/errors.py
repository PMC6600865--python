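"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: SchemaError and FormatError map to exit
code 2, EmptyInputError to exit code 3.
"""


class TfkitError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(TfkitError):
    """A required column or field is missing or malformed."""


class FormatError(TfkitError):
    """A file does not conform to its declared dialect (GMT, narrowPeak...)."""


class EmptyInputError(TfkitError):
    """A required input is empty (e.g. header-only catalog snapshot)."""
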