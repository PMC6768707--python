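"""Exception hierarchy for vbgnsum.

Each failure mode the estimators and samplers can hit gets its own named
error so callers (and the simulation driver) can distinguish configuration
mistakes from data problems from genuinely inestimable situations.
"""


class VBGNSUMError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VBGNSUMError, ValueError):
    """Invalid generator, scenario, or run parameters."""


class SamplingError(VBGNSUMError, RuntimeError):
    """Sampling targets cannot be met (e.g. a stratum is exhausted)."""


class DegenerateInputError(VBGNSUMError, ValueError):
    """Estimator input is structurally degenerate (e.g. zero total degree)."""


class InestimableVisibilityError(VBGNSUMError, ArithmeticError):
    """Every sampled key-population member reported zero in-ties.

    The scale-up ratio has no finite value in this case; it is a distinct
    condition from an estimate of zero and must not be silently coerced.
    """


class SurveyValidationError(VBGNSUMError, ValueError):
    """One or more survey rows violate the required value constraints."""

    def __init__(self, problems):
        # problems: list of (line_number, message)
        self.problems = list(problems)
        lines = "; ".join(f"line {row}: {msg}" for row, msg in self.problems[:10])
        extra = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"invalid survey rows: {lines}{extra}")


class MissingColumnError(SurveyValidationError):
    """The survey file lacks one or more required columns."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        VBGNSUMError.__init__(self, f"missing required columns: {', '.join(self.missing)}")
        self.problems = []
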