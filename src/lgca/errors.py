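"""Exception hierarchy.

All package errors derive from :class:`LGCAError` so callers can catch the
whole family; the subclasses distinguish bad user configuration, malformed
in-memory structures, unsupported capabilities, numerical failures and
infeasible problem domains.
"""


class LGCAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LGCAError, ValueError):
    """Invalid user-supplied configuration (parameters, config files)."""


class StructuralError(LGCAError, ValueError):
    """In-memory object inconsistent with the lattice geometry."""


class CapabilityError(LGCAError, NotImplementedError):
    """Requested feature outside the supported model family."""


class NumericalError(LGCAError, ArithmeticError):
    """Numerical failure (non-finite energies, non-convergence)."""


class DomainError(LGCAError, ValueError):
    """Problem infeasible (e.g. a target outside the observable range)."""
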