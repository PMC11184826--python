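"""Small shared primitives: index intervals and z-normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass(frozen=True)
class Interval:
    """Half-open sample interval ``[start, stop)``."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"empty interval [{self.start}, {self.stop})")

    def __len__(self) -> int:
        return self.stop - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of samples shared with *other* (0 if disjoint)."""
        return max(0, min(self.stop, other.stop) - max(self.start, other.start))

    def contains(self, idx: int) -> bool:
        return self.start <= idx < self.stop


def znorm(x: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Z-normalize (population SD). A constant sequence maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = float(x.std())
    if sd < eps:
        return np.zeros_like(x)
    return (x - x.mean()) / sd
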