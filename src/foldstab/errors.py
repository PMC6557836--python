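"""Exception hierarchy shared by all foldstab modules."""


class FoldstabError(Exception):
    """Base class for all package errors."""


class SchemaError(FoldstabError):
    """A table is missing required columns or the schema is inconsistent."""


class ParseError(FoldstabError):
    """A cell could not be parsed; carries the offending row when known."""


class ValidationError(FoldstabError):
    """A domain-type invariant is violated."""


class RangeError(FoldstabError):
    """A requested coordinate lies outside the recorded range."""


class DataError(FoldstabError):
    """Input data is insufficient or degenerate for the requested operation."""


class FitError(FoldstabError):
    """A least-squares fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SelectionError(FoldstabError):
    """An atom/residue selection failed to resolve."""


class FormatError(FoldstabError):
    """A structure/trajectory file violates its format contract."""
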