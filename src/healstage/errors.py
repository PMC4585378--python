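"""Exception hierarchy used across the package."""


class HealstageError(Exception):
    """Base class for all package errors."""


class ConfigError(HealstageError):
    """Invalid configuration; the message names the offending field."""


class ParseError(HealstageError):
    """Malformed input file; carries a line number when one is known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StudyError(HealstageError):
    """An expression study violates a structural invariant."""


class PairingError(HealstageError):
    """An injured time point lacks a control counterpart."""


class LabelError(HealstageError):
    """A requested sample label is not part of the study design."""


class GroupEmptiedError(HealstageError):
    """A replicate group lost all its members during quality filtering."""


class DimensionError(HealstageError):
    """A vector does not match the model's feature space."""
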