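"""Exception hierarchy for microexp."""


class MicroexpError(Exception):
    """Base class for all microexp errors."""


class DegenerateGeometryError(MicroexpError, ValueError):
    """Landmark geometry is degenerate (coincident eye corners, zero mouth width...)."""


class CellGeometryError(MicroexpError, ValueError):
    """A facial cell is empty after clipping to the image bounds."""


class ShapeError(MicroexpError, ValueError):
    """Frames or arrays have inconsistent shapes."""


class ParameterError(MicroexpError, ValueError):
    """A parameter violates its documented constraints."""


class TrainingError(MicroexpError, ValueError):
    """A model cannot be trained from the data given (missing class, ...)."""


class FormatError(MicroexpError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ModelFormatError(FormatError):
    """A serialized model file is malformed or incompatible."""
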