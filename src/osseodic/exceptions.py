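"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`OsseodicError` so that the pipeline
driver can attach stage context without catching unrelated failures.
"""


class OsseodicError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(OsseodicError):
    """The loading protocol is inconsistent (non-positive frequency, empty cycles, ...)."""


class DegenerateGeometryError(OsseodicError):
    """Marker or grid layout cannot support a rigid-pose estimate (collinear, <3 points)."""


class NoCyclesError(OsseodicError):
    """The load channel contains no detectable loading cycles."""


class FrameMismatchError(OsseodicError):
    """Two poses or sequences that must refer to the same frame do not."""


class NonOrthonormalFrameError(OsseodicError):
    """An anatomical frame failed the orthonormality / handedness check."""


class StrainWindowError(OsseodicError):
    """Invalid strain computation window (even, or smaller than 3 nodes)."""


class EmptyROIError(OsseodicError):
    """A region of interest contains no valid node after masking."""


class SchemaError(OsseodicError):
    """A file or configuration does not match the documented schema."""


class IntegrityError(OsseodicError):
    """Point identities or frame structure of an imported track file are inconsistent."""

    def __init__(self, message: str, frames: list | None = None):
        super().__init__(message)
        self.frames = frames or []
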