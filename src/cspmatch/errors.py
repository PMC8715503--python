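"""Exception hierarchy for cspmatch.

Every error raised on bad user input or an unusable problem instance derives
from :class:`CspMatchError`, so callers (and the CLI) can distinguish user
errors from genuine bugs.
"""


class CspMatchError(Exception):
    """Base class for all cspmatch errors."""


class MalformedInputError(CspMatchError):
    """A peak-list file could not be parsed (message names the offending row)."""


class DuplicateAssignmentError(CspMatchError):
    """Two assigned peaks in the same list claim the same residue index."""


class EmptyAfterFilterError(CspMatchError):
    """Dropping unassigned peaks left an empty list."""


class AssignmentsRequiredError(CspMatchError):
    """A Smart algorithm (or accuracy scoring) needs residue assignments it does not have."""


class IncompatibleSpectraError(CspMatchError):
    """The two peak lists record different heteronuclei."""


class InvalidShiftError(CspMatchError):
    """A chemical shift value is NaN or infinite."""


class InsufficientDataError(CspMatchError):
    """Fewer than two residues: mean/SD classification is undefined."""


class GenerationInfeasibleError(CspMatchError):
    """The requested synthetic peak density cannot satisfy the separation floor."""


class OracleSizeError(CspMatchError):
    """The brute-force oracle refuses instances with more than 8 peaks on the shorter side."""
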