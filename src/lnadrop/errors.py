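"""Exception hierarchy shared across the toolkit."""


class LnadropError(Exception):
    """Base class for all toolkit errors."""


class InputError(LnadropError, ValueError):
    """Invalid user-supplied value (bad sequence characters, out-of-range coordinate...)."""


class AlignmentError(LnadropError):
    """Sequences cannot be paired/aligned as requested."""


class UnalignableCloneError(AlignmentError):
    """Clone identity to the reference is below the configured floor."""


class IncompleteCloneError(AlignmentError):
    """Clone alignment does not cover the full analysis window."""


class DesignError(LnadropError):
    """No oligo design satisfies the requested constraints."""


class FormatError(LnadropError, ValueError):
    """Malformed input file (missing column, duplicate FASTA id, ...)."""


class ThresholdError(LnadropError):
    """Automatic fluorescence thresholding failed (unimodal channel)."""


class SaturatedChipError(LnadropError):
    """Every partition is positive; Poisson occupancy is unbounded."""


class NoTemplateError(LnadropError):
    """Reference channel has no positive partitions."""


class ConfigurationError(LnadropError):
    """Run configuration is inconsistent (missing control class, unknown key, ...)."""


class GenerationError(LnadropError):
    """A requested synthetic allele cannot be generated in the given window."""
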