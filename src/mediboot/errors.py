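"""Exception hierarchy.

All errors derive from :class:`MedibootError` so callers can catch the
package's failures with a single except clause; the finer-grained classes
distinguish malformed files, violated data invariants, mathematically
invalid inputs, and model-fitting failures.
"""


class MedibootError(Exception):
    """Base class for all errors raised by mediboot."""


class FormatError(MedibootError, ValueError):
    """A file or table does not have the required columns or encoding."""


class IntegrityError(MedibootError, ValueError):
    """Data violate a structural invariant (duplicates, arm switches, ...)."""


class DomainError(MedibootError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class InputError(MedibootError, ValueError):
    """An operation was called with unusable inputs (e.g. all missing)."""


class ContractError(MedibootError, RuntimeError):
    """A precondition between pipeline stages was not met."""


class ConvergenceError(MedibootError, RuntimeError):
    """A mixed-model fit failed to converge.

    ``path`` identifies which mediation path the failing fit belonged to
    when the error is raised from :func:`mediboot.mediation.estimate_paths`.
    """

    def __init__(self, message: str, path: str | None = None):
        super().__init__(message)
        self.path = path
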