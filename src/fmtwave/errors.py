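"""Exception hierarchy for fmtwave."""


class FmtwaveError(Exception):
    """Base class for all fmtwave errors."""


class InvalidParameterError(FmtwaveError, ValueError):
    """A physical or geometric parameter is out of its valid range."""


class ContractError(FmtwaveError, ValueError):
    """Inputs violate an interface contract (shape/length mismatch)."""


class AssemblyError(FmtwaveError):
    """FEM assembly failed (e.g. degenerate element)."""


class SolverError(FmtwaveError):
    """A linear solve failed or the system is singular/inconsistent."""


class PlacementError(FmtwaveError):
    """A source or detector could not be placed inside the domain."""


class NotFoundError(FmtwaveError, LookupError):
    """A geometric query found no containing element."""


class ConfigurationError(FmtwaveError, ValueError):
    """An experiment or solver configuration is invalid."""


class DataError(FmtwaveError):
    """Required measurement data are missing or inconsistent."""
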