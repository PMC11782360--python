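"""Exception types shared across the tracing pipeline.

Several of these are not fatal: inside the tracer they feed the "chances"
retry mechanism (advance one radius along the current tangent and try again)
rather than aborting the trace.
"""


class VesselTraceError(Exception):
    """Base class for all package errors."""


class ValidationError(VesselTraceError, ValueError):
    """Invalid user input (spec fields, shapes, parameter ranges)."""


class OutOfBoundsError(VesselTraceError):
    """A requested subvolume asks for image data outside the global volume.

    This is the tracer's forced stop criterion at the image boundary.
    """


class EmptySegmentationError(VesselTraceError):
    """The local probability map contains no voxel at or above the isovalue."""


class NoOutletError(VesselTraceError):
    """The local surface has no (or too few) truncation boundaries."""


class UnreachableTargetError(VesselTraceError):
    """No target cap is reachable from the source in the eikonal solve."""


class StallError(VesselTraceError):
    """Centerline gradient descent failed to make progress toward the source."""


class TraceFailedError(VesselTraceError):
    """The very first step failed after exhausting all chances."""
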