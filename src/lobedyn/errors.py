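"""Exception types shared across the package."""


class LobedynError(Exception):
    """Base class for all package errors."""


class PDBParseError(LobedynError):
    """A fixed-width PDB record could not be parsed; message names the line."""


class EmptySelectionError(LobedynError):
    """A selection resolved to zero atoms."""


class PairingError(LobedynError):
    """Atoms could not be paired between two structures; lists the misses."""


class DegenerateFitError(LobedynError):
    """Superposition subset has <3 atoms or is collinear."""


class AtomLookupError(LobedynError):
    """A requested atom is absent from the structure."""


class DegenerateTensorError(LobedynError):
    """ADP tensor has no positive eigenvalue."""


class UndefinedOverlapError(LobedynError):
    """Overlap requested against an (effectively) zero displacement field."""


class StageError(LobedynError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
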