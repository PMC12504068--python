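"""Exception hierarchy.

Validation failures (a contour cine or clinical table violating its
contract) are kept distinct from malformed files (missing/duplicate cells,
unparseable numbers) and from degenerate numerical inputs (zero-length
systolic contour, constant samples), so that the CLI can map them onto
distinct exit codes.
"""


class CtikinError(Exception):
    """Base class for all errors raised by this package."""


class MalformedInputError(CtikinError):
    """A data file is structurally broken: missing or duplicated cells,
    unparseable values, unknown boolean tokens."""


class ContourValidationError(CtikinError):
    """A contour cine violates its invariants (point/frame counts,
    non-finite coordinates, unusable CTI index range)."""


class ClinicalValidationError(CtikinError):
    """A clinical record violates its invariants (NYHA class outside 1-4,
    non-positive BMI, negative durations)."""


class DegenerateInputError(CtikinError):
    """An operation received input on which its result is undefined
    (empty point sequence, coincident endpoints, constant sample, ...)."""
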