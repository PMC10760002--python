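"""Exception hierarchy.

All package errors derive from :class:`ProtomerScopeError` so callers can
catch everything the library raises with one clause.
"""


class ProtomerScopeError(Exception):
    """Base class for all errors raised by protomerscope."""


class FormatError(ProtomerScopeError):
    """Input file could not be parsed as the expected format."""


class ModelNotFoundError(ProtomerScopeError, IndexError):
    """Requested model index is absent from a multi-model file."""


class MissingResidueError(ProtomerScopeError, KeyError):
    """A residue (or a required atom of it) is not resolved in the structure.

    Raised eagerly instead of propagating NaN metrics: unresolved anchor
    residues (e.g. an unmodelled activation loop) must be visible failures.
    """

    def __init__(self, protomer, residue_id, detail=""):
        self.protomer = protomer
        self.residue_id = residue_id
        msg = f"residue {residue_id} (protomer {protomer!r}) not resolved"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class TopologyMismatchError(ProtomerScopeError):
    """Trajectory frames do not match the topology's atom count/order."""


class UndefinedDihedralError(ProtomerScopeError, ArithmeticError):
    """Torsion angle undefined because three consecutive atoms are collinear."""


class AlignmentError(ProtomerScopeError):
    """Two series/matrices that must share indexing do not."""


class ArityError(ProtomerScopeError, ValueError):
    """Operation requires a dimer (exactly two protomers) and got something else."""


class ConstructionError(ProtomerScopeError, ValueError):
    """Synthetic scaffold geometry is unrealizable."""


class EmptyInputError(ProtomerScopeError, ValueError):
    """An operation received an empty series or ensemble."""


class TypingError(ProtomerScopeError):
    """Ligand atom typing failed (connectivity could not be perceived)."""


class ConfigError(ProtomerScopeError, ValueError):
    """Run configuration is invalid."""
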