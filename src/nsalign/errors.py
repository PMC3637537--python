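"""Exception hierarchy for the alignment pipeline."""


class NSAlignError(Exception):
    """Base class for all package-specific errors."""


class StructureInputError(NSAlignError):
    """Unreadable file, missing chain, or malformed structure input."""


class EmptyStructureError(StructureInputError):
    """No residue with a C-alpha atom survives parsing/filtering."""


class NoSSEError(NSAlignError):
    """A structure yields too few secondary-structure elements to align."""


class EmptyResultError(NSAlignError):
    """The search produced no candidate alignment (e.g. disjoint SSE types)."""


class UndefinedMetricError(NSAlignError):
    """A statistic is undefined for the given input (e.g. empty reference)."""


class CannotPermuteError(NSAlignError):
    """Segment permutation impossible (fewer than two segments)."""


class GenerationError(NSAlignError):
    """Synthetic structure generation could not satisfy its geometric contract."""
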