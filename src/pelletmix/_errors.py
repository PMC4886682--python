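"""Exception hierarchy shared across pelletmix modules."""


class PelletmixError(Exception):
    """Base class for all pelletmix errors."""


class ParameterError(PelletmixError, ValueError):
    """A parameter violates its documented constraints; names the field."""


class EmptyInputError(PelletmixError, ValueError):
    """An operation that requires data received an empty collection."""


class ShapeMismatchError(PelletmixError, ValueError):
    """Arrays that must share dimensions do not."""


class PlacementError(PelletmixError, RuntimeError):
    """Particles could not be placed without overlap on the given canvas."""


class InsufficientDataError(PelletmixError, ValueError):
    """Too few observations for the requested fit."""


class DegenerateDataError(PelletmixError, ValueError):
    """The data admit no meaningful mixture fit (e.g. zero variance)."""


class GridSizeError(PelletmixError, ValueError):
    """A grid-search specification is invalid or too large."""
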