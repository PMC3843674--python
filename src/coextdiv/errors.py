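"""Exception hierarchy for coextdiv."""


class CoextdivError(Exception):
    """Base class for all coextdiv errors."""


class FormatError(CoextdivError, ValueError):
    """An input file violates the expected on-disk format.

    The message names the offending row/column or cell where possible.
    """


class InvalidArgumentError(CoextdivError, ValueError):
    """An argument violates a documented precondition."""


class IncomputableDistanceError(CoextdivError, ValueError):
    """A pair of species shares no non-missing trait, so no pairwise
    distance can be computed. The message names the pair."""


class InternalConsistencyError(CoextdivError, RuntimeError):
    """Simulation state violates an invariant that the engine should
    maintain; indicates a bug rather than bad user input."""
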