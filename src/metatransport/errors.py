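"""Exception hierarchy shared across the package."""


class TransportError(Exception):
    """Base class for all metatransport errors."""


class ParseError(TransportError):
    """A delimited-text input could not be parsed."""


class ValidationError(TransportError):
    """An input violated a structural invariant of the IPD container."""


class ConvergenceError(TransportError):
    """A nuisance-model fit failed to converge (or separated)."""


class PositivityError(TransportError):
    """A weight denominator was zero: a unit had (estimated) probability
    zero of its treatment arm or of study membership."""


class DegenerateWeightsError(TransportError):
    """All weight mass in a treatment arm vanished, so a weighted arm mean
    is undefined."""


class SimulationError(TransportError):
    """The synthetic data generator could not satisfy its constraints."""
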