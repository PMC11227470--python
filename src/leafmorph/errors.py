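"""Exception hierarchy for the leaf morphometrics pipeline."""


class LeafmorphError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LeafmorphError):
    """Input image/array does not have the expected layout."""


class DegenerateHistogramError(LeafmorphError):
    """Thresholding requested on a constant (single-valued) image."""


class NoLeafFoundError(LeafmorphError):
    """Mask cleaning left no foreground component."""


class CalibrationError(LeafmorphError):
    """Physical calibration (dpi) missing or invalid."""


class GeometryError(LeafmorphError):
    """Degenerate geometry (zero perimeter, too few vertices, ...)."""


class InvalidShapeError(LeafmorphError):
    """Generated outline is not a simple closed polygon."""


class CanvasOverflowError(LeafmorphError):
    """Outline does not fit on the requested raster canvas."""


class ConfigurationError(LeafmorphError):
    """Mismatched or out-of-range analysis parameters."""


class ResolutionError(LeafmorphError):
    """Raster grid too coarse for a region-overlap estimate."""


class DegeneratePopulationError(LeafmorphError):
    """A population ratio has a zero denominator."""


class IncompleteDesignError(LeafmorphError):
    """Study table is missing one or more (node, treatment) cells."""
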