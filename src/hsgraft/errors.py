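"""Exception hierarchy for hsgraft."""


class HsGraftError(Exception):
    """Base class for all hsgraft errors."""


class StructureFormatError(HsGraftError):
    """Input file could not be parsed as the declared structure format."""


class EmptyStructureError(HsGraftError):
    """Structure contains no polymer residues."""


class InsertionCodeError(StructureFormatError):
    """Residues with insertion codes are not supported."""


class SequenceMismatchError(HsGraftError):
    """Modeled residues do not match the supplied full-length sequence.

    Carries ``position`` — the first conflicting author residue number.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class StaleProposalError(HsGraftError):
    """A mutation's from-amino-acid no longer matches the current sequence."""


class MutationParseError(HsGraftError):
    """Mutation string is not valid ``K42Q`` notation."""


class ParameterError(HsGraftError, ValueError):
    """A parameter is outside its documented domain."""


class DomainError(HsGraftError):
    """Operation applied to a residue outside its domain (e.g. non-basic)."""


class CannotProjectError(HsGraftError):
    """Mutant side-chain tip cannot be projected (missing/degenerate backbone)."""


class InfeasibleSpecError(HsGraftError):
    """Requested fixture geometry cannot realize the planted distances."""


class SerialOverflowError(HsGraftError):
    """Model exceeds the fixed-width field capacity of the PDB format."""
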