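"""Exception hierarchy.

Every error raised by the library derives from :class:`SigReverseError`, so
callers (and the CLI) can catch one base class. Parsing errors carry the file
path and 1-based line number of the offending record.
"""

from __future__ import annotations


class SigReverseError(Exception):
    """Base class for all library errors."""


class ConfigurationError(SigReverseError):
    """Invalid parameter or study configuration."""


class AlignmentError(SigReverseError):
    """Gene universes of two matrices do not match."""


class ConsistencyError(SigReverseError):
    """A ground truth or derived object does not match its configuration."""


class EmptyTagSetError(SigReverseError):
    """Cutoff-based tag-set extraction produced an empty up or down side."""


class ScoringError(SigReverseError):
    """A tag set cannot be scored against a ranked list."""


class CoverageError(ScoringError):
    """Too few tag genes are present in the ranked list (< 25% retained)."""


class DegenerateSetError(ScoringError):
    """Tag set covers the entire ranked list; enrichment is undefined."""


class DegenerateWeightError(ScoringError):
    """All tag weights are zero under a positive weighting exponent."""


class InputError(SigReverseError):
    """Empty or unusable analysis input (e.g. query with no background genes)."""


class TargetNotFoundError(SigReverseError):
    """Percentile target score is absent from the score library."""


class IncompleteEvidenceError(SigReverseError):
    """A concordance call was requested with expected conditions missing."""


class FormatError(SigReverseError):
    """Malformed GMT / RNK / TSV input."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class PipelineError(SigReverseError):
    """A pipeline stage failed; names the stage and offending entity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
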