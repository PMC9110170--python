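"""Exception hierarchy shared across the package."""


class MindfuseError(Exception):
    """Base class for all package-specific errors."""


class KeypointFormatError(MindfuseError, ValueError):
    """A keypoint file violates the expected layout (e.g. wrong point count)."""


class InsufficientDataError(MindfuseError, ValueError):
    """Not enough valid samples/frames for the requested computation."""


class UnrecoverableChannelError(MindfuseError, ValueError):
    """A channel is invalid in every frame and cannot be interpolated."""
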