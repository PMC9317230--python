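"""Exception hierarchy for testtreat.

All validation problems raise :class:`ValidationError` (a ``ValueError``), so
callers can catch one type; the more specific subclasses distinguish the
degenerate situations that the design machinery must treat differently.
"""


class ValidationError(ValueError):
    """An input violates a documented invariant (out-of-range probability,
    bad fraction, malformed configuration)."""


class DegenerateEffectError(ValidationError):
    """The two arms have identical expected outcomes, so the required sample
    size is infinite (Delta = 0)."""


class UninformativeTestsError(ValidationError):
    """The summed Youden indices of both tests vanish: the overall positive
    rate carries no information about the prevalence."""


class EmptyInterimError(ValidationError):
    """An interim snapshot with zero patients cannot estimate anything."""
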