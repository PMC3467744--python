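"""Exception hierarchy shared across the toolkit.

Everything raised on bad user input derives from :class:`SeqForgeError`
so callers (and the CLI) can distinguish data problems from bugs.
"""


class SeqForgeError(Exception):
    """Base class for all errors raised on invalid input or usage."""


class ValidationError(SeqForgeError):
    """A symbol or value violates an alphabet or type contract."""


class UnsupportedOperationError(SeqForgeError):
    """The operation is undefined for this alphabet (e.g. protein revcomp)."""


class FormatError(SeqForgeError):
    """A file did not conform to its format.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ScoringError(SeqForgeError):
    """A symbol has no entry in the substitution matrix."""


class AnchorError(SeqForgeError):
    """Alignment anchors are crossing or out of range."""


class ConsistencyError(SeqForgeError):
    """Features passed together violate a joint precondition."""


class ConfigError(SeqForgeError):
    """A configuration document (e.g. a PTM XML file) is invalid."""
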