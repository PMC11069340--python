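"""Exception types shared across the pipeline."""


class IsocatError(Exception):
    """Base class for all package errors."""


class FormatError(IsocatError, ValueError):
    """Malformed input data (bad FASTA, bad table, bad coordinates)."""


class ConfigError(IsocatError, ValueError):
    """Invalid configuration (simulation or run config)."""
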