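"""Exception hierarchy for rglatch."""


class RglatchError(Exception):
    """Base class for all rglatch errors."""


class ParseError(RglatchError):
    """A structure or alignment file could not be parsed."""


class FormatError(RglatchError):
    """An unknown or unsupported file format was requested."""


class SelectionError(RglatchError):
    """A residue selection referenced a missing chain or overlapping regions."""


class ConfigurationError(RglatchError):
    """An out-of-range cutoff, unknown matrix, or similar bad parameter."""


class PairingError(RglatchError):
    """Atom pairing between two structures produced no usable pairs."""


class DegeneracyError(RglatchError):
    """Point sets are collinear/coincident; the rotation is not determined."""


class RejectionCollapseError(RglatchError):
    """Outlier rejection removed every atom pair."""


class LoopTaxonomyError(RglatchError):
    """Loop length outside the 3-8 residue range covered by the taxonomy."""


class MappingError(RglatchError):
    """Alignment-column mapping failed (absent reference or unmappable span)."""


class ConstructionError(RglatchError):
    """A synthetic blueprint could not be realized."""
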