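"""Exception hierarchy shared across the package."""


class McBuildError(Exception):
    """Base class for all errors raised by mcbuild."""


class MapFormatError(McBuildError):
    """The map file could not be parsed as MRC/CCP4."""


class UnsupportedMapError(McBuildError):
    """The map is valid but outside the supported conventions (e.g. skewed cell)."""


class StructureError(McBuildError):
    """Invalid or empty atomic model input."""


class DomainError(McBuildError):
    """Domain segmentation does not partition the chain."""


class FittingError(McBuildError):
    """Rigid-fitting preconditions violated (empty point set, shape mismatch...)."""


class AssemblyError(McBuildError):
    """Complex assembly failed (nothing could be placed)."""
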