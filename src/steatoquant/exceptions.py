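"""Exception types shared across the package."""


class SteatoquantError(Exception):
    """Base class for all package-specific errors."""


class NoTissueError(SteatoquantError, ValueError):
    """Raised when an image contains no usable tissue signal.

    Emitted when the whole field is border/black, when fewer than the
    configured minimum fraction of pixels lie inside the field of view,
    or when a channel histogram has no mass above the lower bound.
    """


class PhantomSpecError(SteatoquantError, ValueError):
    """Raised for infeasible or invalid phantom specifications."""


class IccUndefinedError(SteatoquantError, ValueError):
    """Raised when the intraclass correlation is undefined.

    This happens for a constant rating matrix: with zero between-subject
    variance the ICC numerator and denominator both vanish.
    """
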