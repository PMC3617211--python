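"""Exception hierarchy for kinetrap."""


class KinetrapError(Exception):
    """Base class for all kinetrap-specific errors."""


class InvalidRateError(KinetrapError, ValueError):
    """A kinetic rate constant is negative, non-finite, or all rates are zero."""


class InvalidDistributionError(KinetrapError, ValueError):
    """A state vector is not a probability distribution over (S, I, P)."""


class InputError(KinetrapError, ValueError):
    """Malformed user input (unordered times, bad thresholds, ...)."""


class RouteUndefinedError(KinetrapError, ValueError):
    """First-passage routing to the product is undefined (P unreachable from S)."""


class BaselineNotViableError(KinetrapError, ValueError):
    """Baseline classification requested for a rate set that is not viable unperturbed."""


class PerturbationConflictError(KinetrapError, ValueError):
    """Two perturbations target the same enzyme."""


class GridError(KinetrapError, ValueError):
    """Inconsistent phase-diagram grid specification."""


class ConfigurationError(KinetrapError, ValueError):
    """Invalid analysis configuration (thresholds, simulation settings, ...)."""


class UndefinedStatisticError(KinetrapError, ValueError):
    """A statistic's denominator is empty (no pairs, no within-pathway negatives)."""
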