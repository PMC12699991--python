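"""Exception hierarchy shared across the pipeline."""


class VinascreenError(Exception):
    """Base class for all pipeline errors."""


class ParseError(VinascreenError):
    """A file violated its format; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(VinascreenError):
    """An input contained no usable records."""


class EmptyOutputError(VinascreenError):
    """A docking output file contained no result records (failed run, not low affinity)."""


class UnsupportedElementError(VinascreenError):
    """An element is missing from an embedded parameter table."""


class ContractViolationError(VinascreenError):
    """A precondition on assigned attributes (charges, types, torsion tree) was not met."""


class InconsistentConfidenceError(VinascreenError):
    """A residue carries mixed pLDDT values across its atoms."""
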