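"""Shared helpers: exceptions, RNG handling, rounding conventions."""
from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGT")


class AdnapopError(Exception):
    """Base class for package errors."""


class ParseError(AdnapopError):
    """A file could not be parsed under the declared dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UndefinedStatisticError(AdnapopError):
    """The requested statistic is undefined for this input (e.g. n < 2)."""


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from a seed, an existing Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (88.2 -> 88, 90.5 -> 91)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def norm_pair(a, b):
    """Unordered allele pair normalised under a fixed (lexicographic) ordering."""
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)
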