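"""Exception hierarchy.

All user-facing failures derive from :class:`PcaplaceError` so the CLI can
render them as single-line diagnostics and map them onto exit codes.
"""


class PcaplaceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PcaplaceError):
    """An on-disk file violates its dialect (dimensions, value ranges, alleles)."""


class InsufficientSitesError(PcaplaceError):
    """A study sample shares too few usable sites with the reference panel."""


class DegenerateInputError(PcaplaceError):
    """A numerical routine received an input without enough structure to solve
    its problem (rank-deficient source configuration, zero target variance,
    all-missing dosage vector, ...)."""
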