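"""Exception hierarchy for the toolkit."""


class PseudocallError(Exception):
    """Base class for all toolkit-specific errors."""


class SizingError(PseudocallError, ValueError):
    """A synthetic locus cannot be laid out with the requested geometry."""


class PlantingError(PseudocallError, ValueError):
    """Truth variants cannot be placed under the requested density/spacing."""


class FormatError(PseudocallError, ValueError):
    """A record in an external file could not be parsed."""


class TallyError(PseudocallError, ValueError):
    """A detection tally is internally inconsistent (detected > total)."""


class BreakpointInconsistencyError(PseudocallError, ValueError):
    """A clip placement contradicts the deletion geometry it should support."""
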