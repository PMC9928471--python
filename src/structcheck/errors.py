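"""Exception hierarchy."""


class StructCheckError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(StructCheckError):
    """A structure file could not be parsed (malformed record, bad format)."""


class EmptyModelError(StructureParseError):
    """The file contained no polymer residues."""


class DegenerateGeometryError(StructCheckError):
    """Geometric primitive undefined (collinear/coincident points)."""


class UnknownElementError(StructCheckError):
    """An element has no van der Waals radius and strict mode is on."""


class SelectionError(StructCheckError):
    """A residue selection could not be resolved against a model."""


class ConfigurationError(StructCheckError):
    """Invalid parameter combination (thresholds, point counts, ...)."""
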