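"""Exception hierarchy.

Everything derives from :class:`DGFoldError` so callers can catch the
package's own failures without swallowing programming errors; the
concrete classes also derive from the closest built-in (``ValueError``
or ``IndexError``) so code written against plain numpy semantics keeps
working.
"""


class DGFoldError(Exception):
    """Base class for all dgfold errors."""


class ShapeError(DGFoldError, ValueError):
    """Array/chain lengths do not agree."""


class InvalidAngleError(DGFoldError, ValueError):
    """A planar angle is outside the open interval (0, 180) degrees."""


class DegenerateGeometryError(DGFoldError, ValueError):
    """Three consecutive residues are (numerically) collinear."""


class ChainTooShortError(DGFoldError, ValueError):
    """Fewer residues than the operation requires."""


class ResidueIndexError(DGFoldError, IndexError):
    """A residue index addresses no residue with the required angles."""


class InsufficientPointsError(DGFoldError, ValueError):
    """A superposition was requested on fewer than 3 points."""


class FormatError(DGFoldError, ValueError):
    """A file or stream violates its format contract."""


class ConfigError(DGFoldError, ValueError):
    """An optimizer/cascade configuration is invalid."""


class DivergenceError(DGFoldError, RuntimeError):
    """The optimizer produced a non-finite or exploding energy."""


class GenerationError(DGFoldError, RuntimeError):
    """A synthetic-structure generator exhausted its rejection budget."""
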