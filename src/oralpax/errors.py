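"""Exception hierarchy for oralpax."""


class OralpaxError(Exception):
    """Base class for all package errors."""


class ParameterError(OralpaxError, ValueError):
    """A model parameter violates its physical/statistical domain."""


class InputError(OralpaxError, ValueError):
    """A model input (concentration, dose, formulation code...) is invalid."""


class DatasetValidationError(OralpaxError, ValueError):
    """A study dataset failed validation.

    Carries the list of individual problems, each naming the offending
    row(s), so callers can report them all at once.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        msg = "dataset validation failed:\n" + "\n".join(
            f"  - {p}" for p in self.problems
        )
        super().__init__(msg)


class IntegrationError(OralpaxError, RuntimeError):
    """The ODE solver failed; message carries time and state context."""


class EstimationError(OralpaxError, RuntimeError):
    """Population fit did not converge or produced an unreliable optimum."""
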