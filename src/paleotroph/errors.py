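"""Exception hierarchy for the paleotroph package."""


class PaleotrophError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PaleotrophError, ValueError):
    """Invalid simulation or pipeline configuration; message names the field."""


class SchemaError(PaleotrophError, ValueError):
    """A tabular input violates the documented schema (missing column, bad enum)."""


class CalibrationError(PaleotrophError, ValueError):
    """Isotope-scale calibration cannot be established from the given references."""


class BlankError(PaleotrophError, ValueError):
    """Blank estimation or correction is impossible or ill-posed."""


class FitError(PaleotrophError, ValueError):
    """A regression or statistical fit is undefined on the given data."""
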