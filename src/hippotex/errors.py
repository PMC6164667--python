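"""Exception hierarchy for the hippotex pipeline."""


class HippotexError(Exception):
    """Base class for all pipeline errors."""


class VolumeFormatError(HippotexError):
    """Input image is not a usable 3D volume."""


class RoiOutOfBoundsError(HippotexError):
    """Requested ROI would extend past the volume boundary."""


class MaskFormatError(HippotexError):
    """External mask is not a binary image aligned to the volume."""


class DegenerateRoiError(HippotexError):
    """ROI too degenerate for the requested texture matrix (e.g. no valid voxel pair)."""


class ParameterError(HippotexError):
    """Invalid configuration parameter."""


class TableFormatError(HippotexError):
    """Feature table does not follow the expected CSV dialect."""
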