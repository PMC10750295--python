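"""Exception hierarchy shared across the package."""


class SubtyperxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SubtyperxError):
    """A file does not conform to the expected tabular/GMT layout."""


class ParseError(FormatError):
    """A cell could not be interpreted; message names the offending row/column."""


class ConfigError(SubtyperxError):
    """A simulation or run configuration violates its preconditions."""


class AnalysisError(SubtyperxError):
    """Input data is degenerate for the requested statistical operation."""
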