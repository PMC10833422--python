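"""Exception hierarchy.

All package-raised errors derive from :class:`ZernsegError` so callers can
catch configuration/contract problems separately from numpy/scipy internals.
"""


class ZernsegError(Exception):
    """Base class for all zernseg errors."""


class ConfigurationError(ZernsegError):
    """A spec/plan/config object is invalid; the message names the field."""


class ContractError(ZernsegError):
    """An operation precondition was violated (shape/range/normalization)."""


class FormatError(ZernsegError):
    """A file could not be parsed as the expected volume/label format."""


class DomainError(ZernsegError):
    """A quantity is undefined for this input (empty mask, zero denominator)."""


class DegenerateTestError(ZernsegError):
    """A statistical test is undefined for this input (e.g. all-zero diffs)."""


class TrainingError(ZernsegError):
    """Optimization failed (non-finite loss); carries the epoch index."""
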