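"""Exception hierarchy for spinetape."""


class SpinetapeError(Exception):
    """Base class for all package errors."""


class InvalidElementError(SpinetapeError):
    """A tape element violates its geometric invariants (e.g. zero chord)."""


class MustBeLineError(SpinetapeError):
    """Arc fitting was requested for a collinear (line) element."""


class ChainError(SpinetapeError):
    """Element list cannot be chained (empty, or ordering violated)."""


class ResampleError(SpinetapeError):
    """Requested resampling spacing is invalid for the curve."""


class TapeParseError(SpinetapeError):
    """Tape CSV/JSON could not be parsed; message names the offending row."""


class InfeasibleProfileError(SpinetapeError):
    """No sagittal profile consistent with the requested spine parameters."""


class CohortError(SpinetapeError):
    """Cohort specification invalid or repeated re-draws failed."""


class NoTangentError(SpinetapeError):
    """No thoracic-sacral support line exists for the curve."""


class RegionError(SpinetapeError):
    """A named spinal region holds no curve points."""


class FoamFitError(SpinetapeError):
    """Stress-strain data violate monotonicity; message names the index."""


class DensificationError(SpinetapeError):
    """Foundation deflection beyond 95% of stack thickness."""


class BodyModelError(SpinetapeError):
    """Body segment model inputs out of plausible range."""


class ConvergenceError(SpinetapeError):
    """Equilibrium solve did not converge; carries the energy trace."""

    def __init__(self, message, energy_trace=None):
        super().__init__(message)
        self.energy_trace = energy_trace


class MissingCellError(SpinetapeError):
    """Crossover table is missing a participant x condition cell."""


class UndefinedCorrelationError(SpinetapeError):
    """Pearson correlation undefined (zero variance or too few points)."""


class PipelineError(SpinetapeError):
    """A pipeline stage failed; message names the stage."""
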