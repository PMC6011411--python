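"""Exception hierarchy.

Schema and vocabulary errors map onto the CLI exit codes 2 and 3; everything
else exits 1.
"""


class EthnomarketError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(EthnomarketError):
    """Input table is missing required columns or is structurally invalid."""

    exit_code = 2


class VocabularyError(EthnomarketError):
    """A label is not in the controlled vocabulary and no alias resolves it."""

    exit_code = 3


class ParameterError(EthnomarketError):
    """An argument is outside its admissible range."""


class SizingError(EthnomarketError):
    """A synthetic-survey configuration cannot be realized (pools exhausted)."""
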