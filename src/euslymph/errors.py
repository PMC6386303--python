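"""Exception hierarchy.

All package errors derive from :class:`EusLymphError` so callers can catch
one type at pipeline boundaries while tests distinguish the specific
failure modes the input contracts define.
"""


class EusLymphError(Exception):
    """Base class for all package errors."""


class FormatError(EusLymphError):
    """A table file violates its format contract (missing column, bad value)."""


class VocabularyError(EusLymphError):
    """A rating category is not in its feature's vocabulary."""


class DuplicateRatingError(EusLymphError):
    """More than one category for the same (lesion, rater, feature) key."""


class UndefinedKappaError(EusLymphError):
    """Chance agreement is 1 (a single observed category): kappa undefined."""


class ConfigError(EusLymphError):
    """A configuration value violates its invariants."""


class DegenerateInputError(EusLymphError):
    """An analysis input admits no answer (single class, constant values...)."""


class PipelineStageError(EusLymphError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
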