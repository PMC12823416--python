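"""Exception hierarchy.

All errors raised by the library derive from :class:`MacroburdenError` so
callers can catch one type; the subclasses distinguish bad parameter values
(:class:`DomainError`), malformed or inconsistent inputs
(:class:`ValidationError`) and non-conformable array grids
(:class:`ShapeError`).
"""


class MacroburdenError(ValueError):
    """Base class for all library errors."""


class DomainError(MacroburdenError):
    """A numeric argument lies outside its mathematically valid range."""


class ValidationError(MacroburdenError):
    """An input object violates one of its invariants."""


class ShapeError(MacroburdenError):
    """Array arguments do not share the required year/age/sex grids."""
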