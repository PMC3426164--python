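"""Exception taxonomy.

Each error class maps to a distinct CLI exit code (see cli.EXIT_CODES) so that
pipelines can distinguish bad input from a failed optimisation.
"""


class LatticeFitError(Exception):
    """Base class for all package errors."""


class UnsupportedLatticeError(LatticeFitError):
    """Requested lattice name is not in the registry."""


class InvalidStructureError(LatticeFitError):
    """A lattice model violates connectivity or self-avoidance."""


class MoveStringError(LatticeFitError):
    """A move string contains tokens outside the lattice alphabet."""


class PDBError(LatticeFitError):
    """Problems extracting a fitting target from PDB input."""


class ChainNotFoundError(PDBError):
    """The requested chain is absent from the structure."""


class EmptyStructureError(PDBError):
    """No residue with a C-alpha coordinate was found."""


class UnsupportedInputError(PDBError):
    """Input cannot serve the requested mode (e.g. CA-only file, side-chain mode)."""


class FitFailureError(LatticeFitError):
    """Chain growth ran out of valid extensions."""

    def __init__(self, residue_index: int, message: str | None = None):
        self.residue_index = residue_index
        super().__init__(
            message
            or f"no valid lattice extension for residue index {residue_index}"
        )
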