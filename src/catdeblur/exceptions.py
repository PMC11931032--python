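"""Exception hierarchy for the package."""


class CatDeblurError(Exception):
    """Base class for all package errors."""


class ChannelCountError(CatDeblurError):
    """Raised when a color operation receives a non-3-channel image."""


class KernelSpecError(CatDeblurError):
    """Invalid Gaussian kernel specification (even/non-positive size, sigma <= 0)."""


class SizeError(CatDeblurError):
    """Kernel larger than image, or image too small for the operation."""


class ParameterError(CatDeblurError):
    """Invalid scalar parameter (e.g. gamma <= 0)."""


class ShapeError(CatDeblurError):
    """Mismatched or unsupported array shapes."""


class PlacementError(CatDeblurError):
    """Fixture blobs could not be placed after bounded retries."""


class TrainingDivergenceError(CatDeblurError):
    """Training produced non-finite losses."""
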