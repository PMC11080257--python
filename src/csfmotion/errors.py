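"""Exception types raised across the pipeline."""


class CSFMotionError(Exception):
    """Base class for all package errors."""


class SizingError(CSFMotionError):
    """Phantom matrix too small to place the requested regions."""


class LabelingError(CSFMotionError):
    """A mask references a tissue class with no parameters (or vice versa)."""


class StructureError(CSFMotionError):
    """A series violates its structural contract (volume counts, direction scheme)."""


class AlignmentError(CSFMotionError):
    """Two volumes that must share geometry do not."""


class MaskError(CSFMotionError):
    """An operation received an empty or invalid mask."""


class UnderDeterminedError(CSFMotionError):
    """Fewer data points than free model parameters."""


class DomainError(CSFMotionError):
    """A physical parameter outside its admissible range (e.g. negative perfusion)."""


class ConfigError(CSFMotionError):
    """Invalid run configuration; carries a list of field-path messages."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class FormatError(CSFMotionError):
    """An input file could not be parsed as the expected format."""
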