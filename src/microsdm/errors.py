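"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`MicrosdmError`
so callers (and the CLI) can distinguish user/data errors from bugs.
"""


class MicrosdmError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MicrosdmError):
    """A generator or scenario specification violates its invariants."""


class AlignmentError(MicrosdmError):
    """Two rasters that must share a grid do not."""


class GridSizeError(MicrosdmError):
    """A raster is too small for the requested neighbourhood operation."""


class ParameterError(MicrosdmError):
    """An operation parameter is out of its valid range."""


class SchemaError(MicrosdmError):
    """A tabular input is missing required columns or malformed."""


class FormatError(MicrosdmError):
    """A file does not conform to its declared format."""


class DesignError(MicrosdmError):
    """A sampling design cannot be satisfied by the available cells."""


class PlacementError(MicrosdmError):
    """Geometry placement failed after bounded retries."""


class TriangulationError(MicrosdmError):
    """Scattered points cannot be triangulated (e.g. collinear)."""


class VariogramFitError(MicrosdmError):
    """Variogram parameter estimation failed to converge."""


class KrigingError(MicrosdmError):
    """The kriging system is singular beyond recovery."""


class DegenerateTrainingError(MicrosdmError):
    """Training data lacks one of the two classes."""


class SeparationError(MicrosdmError):
    """Perfect separation: the unpenalised GLM likelihood is unbounded."""


class ConvergenceError(MicrosdmError):
    """Iterative fit did not converge within the iteration budget."""


class ContractError(MicrosdmError):
    """A named factor required by a model or scenario is absent."""


class SelectionError(MicrosdmError):
    """No candidate model clears the AUC acceptance gate."""


class TransformError(MicrosdmError):
    """A log transform was requested on non-positive data."""


class PipelineError(MicrosdmError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
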