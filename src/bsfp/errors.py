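"""Exception hierarchy for the bsfp toolkit."""


class BsfpError(Exception):
    """Base class for all toolkit errors."""


class ParseError(BsfpError):
    """A structure file could not be parsed."""


class MissingChainError(BsfpError):
    """A requested chain is absent from the structure."""


class InvalidInputError(BsfpError):
    """An argument violates an operation's preconditions."""


class EmptyRegionError(BsfpError):
    """A residue region resolved to zero residues."""


class DegenerateGeometryError(BsfpError):
    """Too few or collinear points for a unique rigid superimposition."""


class ScheduleOutOfRangeError(BsfpError):
    """A quench schedule requests a time outside the trajectory."""


class WindowOutOfRangeError(BsfpError):
    """An analysis window is longer than the trajectory."""


class SelectionMismatchError(BsfpError):
    """Atom selections on two structures do not pair up."""


class SelectionOverlapError(BsfpError):
    """Receptor and ligand selections share atoms or miss atoms."""


class ParameterError(BsfpError):
    """A force-field parameter is missing or malformed."""


class NumericalDegeneracyError(BsfpError):
    """A numerical quantity (e.g. a GB effective radius) became invalid."""


class ModelFailureError(BsfpError):
    """A receptor-ligand complex model could not be built."""


class GenerationError(BsfpError):
    """A synthetic-structure generator failed to place atoms."""


class ConfigError(BsfpError):
    """A run configuration is invalid."""


class StageDependencyError(BsfpError):
    """A pipeline stage requires output of a stage that did not run."""
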