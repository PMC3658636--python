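"""Exception hierarchy shared across pipeline stages."""


class McraProfError(Exception):
    """Base class for package errors."""


class ConfigError(McraProfError):
    """Invalid configuration (bad thresholds, duplicate tags, missing paths)."""


class DataError(McraProfError):
    """Malformed or inconsistent input data (annotations, tabular files, sequences)."""
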