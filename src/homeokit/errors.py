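"""Exception hierarchy shared across the toolkit.

``HomeokitError`` marks data/domain failures that the CLI maps to exit
code 3, as opposed to usage errors (exit code 2, handled by click).
"""


class HomeokitError(Exception):
    """Base class for all toolkit-specific errors."""


class AlphabetError(HomeokitError):
    """Sequence contains characters outside the {A,C,G,T,N} alphabet."""


class OutOfBoundsError(HomeokitError):
    """A coordinate or window falls outside the sequence it refers to."""


class InputError(HomeokitError):
    """Invalid or inconsistent user-supplied data."""


class ProbeUniquenessError(HomeokitError):
    """No paralog-unique probe window exists at the requested flanks."""

    def __init__(self, message: str, hits=None):
        super().__init__(message)
        self.hits = list(hits or [])


class FastqFormatError(HomeokitError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


class DegenerateFitError(HomeokitError):
    """Curve fitting attempted on data with no usable signal."""
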