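"""Exception hierarchy; the CLI maps these to exit codes (2/3/4)."""


class TrimedError(Exception):
    """Base class for all package errors."""


class ConfigError(TrimedError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(TrimedError):
    """Malformed or contract-violating input data (CLI exit code 3)."""


class EstimationError(TrimedError):
    """A model could not be estimated (CLI exit code 4)."""
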