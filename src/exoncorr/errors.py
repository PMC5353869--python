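"""Exception hierarchy shared across the pipeline."""


class ExoncorrError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ExoncorrError, ValueError):
    """A text input (BLAST table, GTF, TSV) violates its format contract."""


class AnnotationLookupError(ExoncorrError, KeyError):
    """An exon or gene ID is missing from the annotation."""


class ConfigurationError(ExoncorrError, ValueError):
    """Invalid configuration values (fractions, thresholds, mismatched contexts)."""


class CompletenessError(ExoncorrError, ValueError):
    """An (exon, sample) table is missing cells or contains duplicates."""


class DomainError(ExoncorrError, ValueError):
    """Numeric arguments outside the mathematical domain of an operation."""


class PipelineError(ExoncorrError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
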