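"""Exception hierarchy for the mathqsar package."""


class MathQsarError(Exception):
    """Base class for all package errors."""


class ParseError(MathQsarError):
    """SMILES string could not be parsed."""


class SanitizeError(ParseError):
    """SMILES parsed syntactically but failed chemical sanitization (valence)."""


class EmbedError(MathQsarError):
    """3D conformer embedding failed after the configured retries."""


class MissingConformerError(MathQsarError):
    """Operation requires 3D coordinates but none are attached to the graph."""


class ShapeError(MathQsarError):
    """Matrix arguments are not conformable."""


class MissingColumnError(MathQsarError):
    """Required column absent from an input table."""


class SingleClassError(MathQsarError):
    """Training set contains only one activity class."""
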