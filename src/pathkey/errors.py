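"""Exception hierarchy for the pathkey pipeline."""


class PathkeyError(Exception):
    """Base class for all pathkey errors."""


class ConfigurationError(PathkeyError):
    """Invalid generator or pipeline configuration."""


class AlignmentError(PathkeyError):
    """A gold keyword phrase could not be located in a statement."""

    def __init__(self, phrase: str, statement_id: str | None = None):
        self.phrase = phrase
        self.statement_id = statement_id
        where = f" in statement {statement_id!r}" if statement_id else ""
        super().__init__(f"gold phrase {phrase!r} has no occurrence{where}")


class CapabilityError(PathkeyError):
    """A requested model architecture or backend is unavailable."""


class TaxonomyError(PathkeyError):
    """Malformed taxonomy: cycle, orphan node, or missing root."""


class EvaluationError(PathkeyError):
    """Prediction/gold mismatch during metric computation."""
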