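"""Exception hierarchy for the screen-analysis pipeline."""


class PhScreenError(Exception):
    """Base class for all errors raised by phscreen."""


class SchemaError(PhScreenError):
    """An input table is missing required columns or has malformed fields."""


class ValidationError(PhScreenError):
    """Input values violate a documented invariant (well ids, roles, duplicates...)."""


class CalibrationError(PhScreenError):
    """The fluorescence-ratio calibration cannot be fitted or applied."""


class BatchError(PhScreenError):
    """A replicate batch lacks the wild-type wells needed for Z normalisation."""


class FitError(PhScreenError):
    """The pH-growth-rate law cannot be fitted to the supplied points."""


class ConfigError(PhScreenError):
    """A run configuration fails to parse or validate."""
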