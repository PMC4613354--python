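"""Exception hierarchy shared across the package.

Data errors (bad files, bad coordinates) and statistical degeneracies
(undefined means, empty groups) are kept distinct so callers can decide
which to propagate and which to log-and-skip.
"""


class StrandBiasError(Exception):
    """Base class for all package errors."""


class InvalidCoordinatesError(StrandBiasError):
    """ori/ter or gene coordinates violate the circular-chromosome contract."""


class UndefinedStatisticError(StrandBiasError):
    """A statistic is requested on input where it is mathematically undefined."""


class SequenceAlphabetError(StrandBiasError):
    """Sequence contains a character outside the IUPAC nucleotide alphabet."""

    def __init__(self, position: int, char: str):
        self.position = position
        self.char = char
        super().__init__(
            f"illegal sequence character {char!r} at position {position}"
        )


class ParseError(StrandBiasError):
    """A file violates its format contract."""


class PackingError(StrandBiasError):
    """Requested genes cannot be packed into the simulated chromosome."""
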