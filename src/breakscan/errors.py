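"""Exception hierarchy.

Everything raised on purpose derives from :class:`BreakscanError` so callers
(and the CLI) can distinguish data problems from pipeline-phase failures.
"""


class BreakscanError(Exception):
    """Base class for all package errors."""


class DataError(BreakscanError, ValueError):
    """Malformed or inconsistent input data (bad alphabet, missing column...)."""


class FeatureCollisionError(DataError):
    """Two planned genome features overlap."""


class UninformativePanelError(BreakscanError):
    """No primer in the panel is informative for an allele."""


class NoJunctionError(BreakscanError):
    """A putative junction read aligns contiguously to the reference."""


class RepetitiveJunctionError(BreakscanError):
    """Both sides of a junction read map to multiple reference locations."""


class RepetitiveFlankError(BreakscanError):
    """No unique validation primer can be placed on a breakpoint flank."""


class PhaseError(BreakscanError):
    """A pipeline phase failed for one allele; later phases are skipped."""
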