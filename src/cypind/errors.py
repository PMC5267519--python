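"""Exception hierarchy.

DataError (exit code 1) marks problems with the measurements themselves;
ConfigurationError (exit code 2) marks invalid settings or unusable study
designs; FitError marks a curve fit that could not be carried out at all
(as opposed to one that converged but was rejected by the R² rule).
"""


class CypindError(Exception):
    """Base class for package errors."""

    exit_code = 1


class DataError(CypindError):
    """Measurements violate a precondition (e.g. nonpositive vehicle mean)."""

    exit_code = 1


class ConfigurationError(CypindError):
    """Invalid configuration or study design (e.g. too few calibration points)."""

    exit_code = 2


class FitError(CypindError):
    """Nonlinear fit could not be performed (degenerate data, non-convergence)."""

    exit_code = 1
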