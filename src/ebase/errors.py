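"""Exception hierarchy shared by all ebase modules."""


class EbaseError(Exception):
    """Base class for all ebase errors."""


class ParseError(EbaseError):
    """A structure file could not be parsed."""


class EmptyStructureError(EbaseError):
    """No usable nucleotide was found in the input."""


class TopologyError(EbaseError):
    """Frames of a trajectory disagree on nucleotide count or ordering."""


class GeometryError(EbaseError):
    """Degenerate geometry (e.g. collinear ring atoms)."""


class CorrespondenceError(EbaseError):
    """Two structures cannot be placed in 1:1 correspondence."""


class InputError(EbaseError):
    """Invalid argument to an operation."""
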