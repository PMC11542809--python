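"""Exception hierarchy shared across the package."""


class CircfoldError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(CircfoldError):
    """Input contained no usable records (e.g. a PDB with no ATOM lines)."""


class FormatError(CircfoldError):
    """Malformed input text (PDB, dot-bracket, config ...)."""


class UnsupportedResidueError(FormatError):
    """A residue that is not a standard ribonucleotide (A, C, G, U)."""


class InvalidCoordinateError(CircfoldError):
    """A coordinate is NaN/inf or does not fit the PDB fixed-width fields."""


class MappingError(CircfoldError):
    """All-atom to coarse-grained mapping failed (missing atoms)."""


class GeometryError(CircfoldError):
    """Degenerate geometry (coincident bonded beads, collinear point sets ...)."""


class TopologyError(CircfoldError):
    """Invalid chain/pair topology (cannot circularize, bad pair table ...)."""


class SimulationBlowupError(CircfoldError):
    """Non-finite forces or coordinates during dynamics; carries diagnostics."""


class ConfigError(CircfoldError):
    """Invalid or incomplete run configuration."""
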