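"""Exception hierarchy shared across the package."""


class CoreorgError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CoreorgError, ValueError):
    """An input object violates a documented invariant.

    The message names the offending field.
    """


class ParseError(CoreorgError, ValueError):
    """A file does not follow its declared text format.

    Where possible the message names the line (and row/column for
    tabular cells) that failed.
    """


class ZeroVarianceError(CoreorgError, ValueError):
    """Correlation requested for a constant expression profile."""


class VocabularyMismatchError(CoreorgError, ValueError):
    """Two category matrices carry different category vocabularies."""
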