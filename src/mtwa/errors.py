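"""Exception hierarchy shared across the pipeline.

Exit-code convention for the CLI: :class:`DataError` maps to exit status 1,
:class:`ConfigError` to exit status 2.
"""


class MtwaError(Exception):
    """Base class for all package errors."""


class DataError(MtwaError):
    """Malformed or inconsistent input data (reference mismatch, missing calls...)."""

    exit_code = 1


class ConfigError(MtwaError):
    """Invalid configuration or parameters."""

    exit_code = 2
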