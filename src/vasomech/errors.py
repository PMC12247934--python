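"""Exception hierarchy shared across the package."""


class VasomechError(Exception):
    """Base class for all package errors."""


class ParameterError(VasomechError, ValueError):
    """An input parameter violates a documented invariant."""


class DomainError(VasomechError, ValueError):
    """A kinematic or constitutive quantity is outside its admissible domain."""


class ConvergenceError(VasomechError, RuntimeError):
    """A root-find or optimisation failed to converge."""


class TrackingError(VasomechError, RuntimeError):
    """Diameter tracking could not produce an estimate."""


class ParseError(VasomechError, ValueError):
    """A recording file does not conform to the table dialect."""


class AnalysisError(VasomechError, RuntimeError):
    """A trace-analysis operation has no defined result for this input."""
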