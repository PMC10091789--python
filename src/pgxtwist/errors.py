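"""Exception hierarchy; the CLI maps these onto exit codes (config=2, data=3)."""


class PgxTwistError(Exception):
    """Base class for all package errors."""


class ConfigError(PgxTwistError):
    """Invalid configuration (bad parameter, negative hazard cell, bad YAML)."""


class DataError(PgxTwistError):
    """Invalid input data (schema mismatch, duplicate ids, excess malformed rows)."""


class FitError(PgxTwistError):
    """A model fit could not be completed (singular design, empty subset)."""
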