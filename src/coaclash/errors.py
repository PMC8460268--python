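"""Exception hierarchy for the pipeline.

Every error raised on a user-facing path derives from :class:`CoaClashError`
so the CLI can catch one type, log the offending (target, state, donor)
triple, and continue with the next configuration.
"""


class CoaClashError(Exception):
    """Base class for all package errors."""


class InputError(CoaClashError):
    """A source file is missing or unreadable."""


class FormatError(CoaClashError):
    """A coordinate file could not be parsed; the message names the line."""


class EmptyStructureError(CoaClashError):
    """A coordinate file contained zero ATOM/HETATM records."""


class EmptySelectionError(CoaClashError):
    """An atom selection resolved to zero atoms where atoms are required."""


class MissingLigandError(CoaClashError):
    """The requested hetero-component is absent; message lists what exists."""


class IncompleteLigandError(CoaClashError):
    """A CoA-like ligand lacks atoms needed for the mast/flag partition."""


class MappingError(CoaClashError):
    """Ligand atom names could not be resolved against the expected naming."""


class UnderdeterminedError(CoaClashError):
    """Fewer than three point pairs supplied to a rigid superposition."""


class DegenerateGeometryError(CoaClashError):
    """Point set geometry (collinear/coincident) leaves a fit undefined."""


class CorrespondenceError(CoaClashError):
    """No residue correspondence could be established between structures."""


class UnknownElementError(CoaClashError):
    """An element symbol is absent from the van der Waals radii table."""


class ParameterError(CoaClashError):
    """A numeric parameter is outside its valid range."""


class ConfigError(CoaClashError):
    """The run configuration is inconsistent or incomplete."""
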