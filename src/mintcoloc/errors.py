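"""Exception hierarchy.

Every failure mode that the pipeline records per-nucleus (rather than
aborting the run) has its own exception type so callers can distinguish
"this nucleus could not be segmented" from "this parameter set is invalid".
"""


class MintcolocError(Exception):
    """Base class for all package errors."""


class ParameterError(MintcolocError, ValueError):
    """A parameter violates its documented invariant; names the field."""


class DegenerateImageError(MintcolocError):
    """Image has no separable intensity classes (e.g. constant raster)."""


class SegmentationError(MintcolocError):
    """No nucleus-sized object found by auto-threshold segmentation."""


class UndefinedPCCError(MintcolocError):
    """Pearson correlation undefined (zero variance in a channel in-mask)."""
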