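"""Exception hierarchy shared across the package."""


class EpistasimError(Exception):
    """Base class for all package-specific errors."""


class ExpressionError(EpistasimError, ValueError):
    """A penetrance expression failed to parse or used disallowed syntax."""


class ModelError(EpistasimError, ValueError):
    """A model specification or penetrance table is invalid."""


class NoSolutionError(ModelError):
    """No relative penetrance f reaches the requested prevalence/heritability."""


class FormatError(EpistasimError, ValueError):
    """An input file violates the expected dialect."""


class InfeasibleTargetsError(EpistasimError, ValueError):
    """MAF-matched locus selection cannot satisfy the requested targets."""


class QuotaError(EpistasimError, RuntimeError):
    """Balanced case/control quotas could not be filled within the attempt cap."""
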