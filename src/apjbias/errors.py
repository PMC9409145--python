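"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`ApjBiasError`, so callers (and the CLI) can separate user/data
problems from genuine bugs.
"""


class ApjBiasError(Exception):
    """Base class for all errors raised by apjbias."""


class PDBParseError(ApjBiasError):
    """A PDB record could not be parsed; the message names the line."""


class TopologyMismatchError(ApjBiasError):
    """Models of a multi-model file do not share one topology."""


class SelectionError(ApjBiasError):
    """An atom/residue selection could not be resolved."""


class MissingResidueError(SelectionError):
    """A residue label required by an analysis is absent from the structure."""


class DegenerateGeometryError(ApjBiasError):
    """Too few or collinear points for a rigid-body superposition."""


class DegenerateFitError(ApjBiasError):
    """A curve fit is under-determined (too few doses, flat response)."""


class UnknownModelError(ApjBiasError):
    """An assay model name is not one of the supported models."""
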