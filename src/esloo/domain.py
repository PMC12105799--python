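"""Bounded rectangular input domains.

All emulation and acquisition code in this package works on the unit cube
``[0, 1]^p``; :class:`InputDomain` is the bijection between physical
coordinates and that internal representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class InputDomain:
    """A hyperrectangle ``[lower_1, upper_1] x ... x [lower_p, upper_p]``.

    Parameters
    ----------
    lower, upper : array-like of shape (p,)
        Physical bounds; ``lower[j] < upper[j]`` is required for every
        dimension.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def p(self) -> int:
        return self.lower.size

    @classmethod
    def unit(cls, p: int) -> "InputDomain":
        return cls(np.zeros(p), np.ones(p))

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Map physical coordinates to the unit cube."""
        x = np.asarray(x, dtype=float)
        return (x - self.lower) / (self.upper - self.lower)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube coordinates back to physical units."""
        u = np.asarray(u, dtype=float)
        return self.lower + u * (self.upper - self.lower)

    def contains_unit(self, u: np.ndarray, atol: float = 1e-12) -> bool:
        u = np.asarray(u, dtype=float)
        return bool(np.all(u >= -atol) and np.all(u <= 1.0 + atol))

    def to_dict(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "InputDomain":
        return cls(np.asarray(d["lower"], float), np.asarray(d["upper"], float))
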