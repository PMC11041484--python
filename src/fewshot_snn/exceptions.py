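"""Error hierarchy.

Two user-facing families map onto the CLI exit codes: configuration errors
(bad options, unknown backends/methods, invalid hyperparameters -> exit 1)
and data errors (malformed or degenerate inputs -> exit 2).
"""


class FewshotSnnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FewshotSnnError):
    """Invalid configuration: unknown backend/method, bad hyperparameter."""

    exit_code = 1


class DataError(FewshotSnnError):
    """Invalid or degenerate data: empty corpus, zero rows, shape mismatch."""

    exit_code = 2
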