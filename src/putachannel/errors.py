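"""Exception types shared across the package."""


class PutaChannelError(Exception):
    """Base class for all package errors."""


class StructureFormatError(PutaChannelError):
    """A coordinate file could not be parsed under the named standard."""


class TrajectoryFormatError(PutaChannelError):
    """A trajectory source is malformed (atom-count mismatch, bad dialect...)."""


class AtomNotFoundError(PutaChannelError):
    """An atom reference did not resolve against a structure or trajectory."""


class AmbiguousAtomError(PutaChannelError):
    """An atom reference matched more than one atom after the altloc policy."""


class DegenerateGeometryError(PutaChannelError):
    """Geometry is degenerate (collinear dihedral, coincident atoms, zero-length path)."""


class EmptySelectionError(PutaChannelError):
    """A selection or conditioning filter produced an empty set."""


class ConfigError(PutaChannelError):
    """An invalid configuration was supplied."""
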