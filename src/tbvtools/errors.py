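"""Exception hierarchy shared across the package."""


class TbvToolsError(Exception):
    """Base class for all package errors."""


class ValidationError(TbvToolsError):
    """A single input value is out of range or malformed.

    Carries ``field`` so callers can report which input failed.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ConfigurationError(TbvToolsError):
    """The run configuration is inconsistent or requests something unknown."""


class DataError(TbvToolsError):
    """A cohort-level data problem (missing formula, empty input, bad row)."""


class StatisticsError(TbvToolsError):
    """A statistical operation is undefined for the given group sizes."""
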