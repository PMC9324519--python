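"""Exception hierarchy for paslab.

Parse-time problems raise :class:`ParseError` with the offending line number;
scoring-time degeneracies raise dedicated signals so batch drivers can skip a
pathway (or a feature) and record the reason instead of aborting a whole run.
"""


class PaslabError(Exception):
    """Base class for all paslab errors."""


class ParseError(PaslabError):
    """A file failed to parse; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PathwayUnmeasured(PaslabError):
    """No member of the pathway is present in the measured gene set."""


class PathwayUnscorable(PaslabError):
    """All measured members are neutral (ARR = 0): the PAL denominator is 0."""


class UndefinedCorrelation(PaslabError):
    """Pearson correlation is undefined (constant input or too few pairs)."""
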