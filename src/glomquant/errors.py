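"""Exception hierarchy for glomquant.

All package-specific failures derive from :class:`GlomQuantError` so callers
can catch the whole family with one clause.
"""


class GlomQuantError(Exception):
    """Base class for all glomquant errors."""


class OverlapError(GlomQuantError):
    """Two atlas regions claim the same voxel."""


class BoundsError(GlomQuantError):
    """An atlas region extends outside the stack."""


class DegenerateHistogramError(GlomQuantError):
    """Otsu thresholding requested on a constant (single-valued) stack."""


class EmptyRegionError(GlomQuantError):
    """A named atlas region has no voxels in the label volume."""


class UndefinedIndexError(GlomQuantError):
    """Preference index requested with both inputs zero."""


class ZeroReferenceVolumeError(GlomQuantError):
    """Mistargeting ratio requested with zero reference targeting volume."""


class DegenerateSampleError(GlomQuantError):
    """A statistical test received a sample it cannot evaluate."""


class FormatError(GlomQuantError):
    """An input file does not match the expected on-disk format."""


class NameTableError(GlomQuantError):
    """Atlas label volume contains labels absent from the name table."""
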