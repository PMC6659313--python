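"""Exception hierarchy shared across the package."""


class PrestartError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PrestartError):
    """A data file does not conform to the documented schema."""


class ValidationError(PrestartError):
    """A record or value violates an invariant."""


class ConfigurationError(PrestartError):
    """A threshold / rule-set configuration is invalid or incomplete."""


class PairingError(PrestartError):
    """Predictions and reference labels do not cover the same ids."""


class UnresolvedCaseError(PrestartError):
    """Raters disagree and no third rating is available to adjudicate."""


class CalibrationError(PrestartError):
    """A simulator calibration target cannot be attained."""


class InfeasibleError(PrestartError):
    """Published marginals admit no integer 2x2 table."""
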