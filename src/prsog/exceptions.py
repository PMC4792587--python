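"""Exception hierarchy for the prsog pipeline."""


class PrsogError(Exception):
    """Base class for all prsog errors."""


class ConfigurationError(PrsogError, ValueError):
    """A simulation or analysis configuration violates a stated constraint."""


class FormatError(PrsogError, ValueError):
    """An input file or table violates the expected dialect."""


class ImputationError(PrsogError, ValueError):
    """Missing-value imputation cannot proceed (e.g. a gene with no observed values)."""


class DesignError(PrsogError, ValueError):
    """Sample labels are inconsistent with the requested experimental design."""


class PipelineError(PrsogError, ValueError):
    """A pipeline stage received inputs that make the analysis undefined."""


class MembershipError(PrsogError, KeyError):
    """A gene referenced by an operation is absent from the relevant gene pool."""


class FitError(PrsogError, ValueError):
    """Distribution fitting refused: precondition violated or tail too small."""
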