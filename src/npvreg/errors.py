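"""Exception hierarchy for npvreg."""


class NpvregError(Exception):
    """Base class for all npvreg errors."""


class FormatError(NpvregError, ValueError):
    """Unknown or unsupported file format."""


class ChannelError(FormatError):
    """Multi-channel (e.g. RGB) input where a scalar image is required."""


class DegenerateInputError(NpvregError, ValueError):
    """Input is degenerate for the requested operation (constant image, zero mass, ...)."""


class MappingError(NpvregError, ValueError):
    """An intensity remap does not cover every gray class present."""


class SizeError(NpvregError, ValueError):
    """Image or array dimensions violate a size requirement."""


class OutOfFrameError(NpvregError, ValueError):
    """A requested warp pushes image content too close to (or past) the frame border."""


class SpacingError(NpvregError, ValueError):
    """A control-grid spacing does not divide the image extent."""


class InvalidKernelError(NpvregError, ValueError):
    """A kernel specification violates nonnegativity or partition of unity."""


class LineSearchError(NpvregError, RuntimeError):
    """Armijo backtracking exhausted its budget without satisfying the descent test."""


class EvaluationError(NpvregError, RuntimeError):
    """An objective evaluated to a non-finite value."""
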