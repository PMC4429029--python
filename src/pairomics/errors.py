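"""Exception hierarchy for pairomics.

All package-raised errors derive from :class:`PairomicsError` so callers can
catch pipeline problems without swallowing programming errors.
"""


class PairomicsError(Exception):
    """Base class for all pairomics errors."""


class PairingError(PairomicsError):
    """A sample column lacks its tumor or normal counterpart."""


class ParseError(PairomicsError):
    """A cell in an input table could not be parsed; reports row/column."""


class FormatError(PairomicsError):
    """A file does not follow the documented layout (columns, tokens)."""


class CoordinateError(FormatError):
    """Genomic interval with end <= start or negative start."""


class InsufficientPairsError(PairomicsError):
    """Fewer than two complete tumor/normal pairs available for a test."""


class IntegrationError(PairomicsError):
    """Inconsistent inputs when joining gene-level results."""
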