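"""Exception hierarchy for labferm."""


class LabfermError(Exception):
    """Base class for all labferm errors."""


class DomainError(LabfermError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigurationError(LabfermError, ValueError):
    """A parameter / configuration combination is inconsistent or singular."""


class SolverError(LabfermError, RuntimeError):
    """The ODE solver or an optimiser failed to converge."""


class ObservationParseError(LabfermError, ValueError):
    """An observation file violates the expected schema."""
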