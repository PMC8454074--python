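"""Exception hierarchy shared across the package.

Three failure classes map onto the CLI exit codes: configuration problems
(exit 2), missing/unreadable data (exit 3), and analysis failures such as
"no organoid found" or a non-converged fit (exit 4).
"""


class BBBArrayError(Exception):
    """Base class for package errors."""


class ConfigurationError(BBBArrayError, ValueError):
    """Invalid configuration: impossible geometry, bad parameter ranges."""


class DataError(BBBArrayError, ValueError):
    """Missing or malformed input data (files, tables, channel maps)."""


class AnalysisError(BBBArrayError, RuntimeError):
    """A computation could not produce a result (no organoid, degenerate fit)."""
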