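"""Bandt-Pompe ordinal-pattern symbolization.

A time series x_1..x_M is scanned with overlapping windows of D elements
taken at stride ``tau`` (offsets 0, tau, ..., (D-1)*tau; consecutive windows
advance by one sample).  Each window is mapped to the permutation that lists
the positions of its entries in ascending value order; the relative
frequencies of the D! possible permutations form the ordinal-pattern
probability distribution that all entropy/complexity quantifiers consume.

Ties are broken by order of appearance (stable sort), the dominant
convention for continuous signals where ties are rare.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "OrdinalDistribution",
    "ordinal_pattern",
    "ordinal_distribution",
    "pattern_index",
    "index_to_pattern",
]


@dataclass
class TimeSeries:
    """A single real-valued signal with optional sampling rate and metadata."""

    values: np.ndarray
    sampling_rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("TimeSeries needs at least one sample")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class OrdinalDistribution:
    """Probability distribution over the D! ordinal patterns of a series.

    ``probabilities`` is dense over all N = D! patterns in lexicographic
    order (unobserved patterns carry p = 0, which the disequilibrium terms
    need explicitly); ``counts`` maps observed pattern tuples to counts.
    """

    D: int
    tau: int
    n_windows: int
    counts: dict
    probabilities: np.ndarray

    @property
    def N(self) -> int:
        return math.factorial(self.D)

    def validate(self) -> None:
        if sum(self.counts.values()) != self.n_windows:
            raise ValueError("counts do not sum to n_windows")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities do not sum to 1")
        if self.probabilities.size != self.N:
            raise ValueError("dense probability vector must have D! entries")

    def to_json(self) -> str:
        dense_counts = {
            str(pattern_index(p)): int(c) for p, c in sorted(self.counts.items())
        }
        return json.dumps(
            {
                "D": self.D,
                "tau": self.tau,
                "n_windows": self.n_windows,
                "counts": dense_counts,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OrdinalDistribution":
        obj = json.loads(text)
        D, tau, n = int(obj["D"]), int(obj["tau"]), int(obj["n_windows"])
        N = math.factorial(D)
        probs = np.zeros(N)
        counts: dict = {}
        for key, c in obj["counts"].items():
            idx = int(key)
            counts[index_to_pattern(idx, D)] = int(c)
            probs[idx] = c / n
        return cls(D=D, tau=tau, n_windows=n, counts=counts, probabilities=probs)


_FACTORIALS = [math.factorial(i) for i in range(21)]


def pattern_index(perm: Sequence[int]) -> int:
    """Lexicographic rank (Lehmer code) of a permutation of 0..D-1."""
    perm = tuple(perm)
    D = len(perm)
    rank = 0
    for i, v in enumerate(perm):
        smaller_later = sum(1 for u in perm[i + 1 :] if u < v)
        rank += smaller_later * _FACTORIALS[D - 1 - i]
    return rank


def index_to_pattern(idx: int, D: int) -> tuple:
    """Inverse of :func:`pattern_index`."""
    pool = list(range(D))
    perm = []
    for i in range(D):
        f = _FACTORIALS[D - 1 - i]
        j, idx = divmod(idx, f)
        perm.append(pool.pop(j))
    return tuple(perm)


def ordinal_pattern(window: Sequence[float]) -> tuple:
    """Ordinal pattern of one window: source positions in ascending value order.

    Equal values rank by order of appearance.  ``(9, 10, 6) -> (2, 0, 1)``.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise ValueError("window must be one-dimensional")
    return tuple(int(i) for i in np.argsort(w, kind="stable"))


def ordinal_distribution(
    series: TimeSeries | Sequence[float], D: int, tau: int = 1
) -> OrdinalDistribution:
    """Ordinal-pattern probability distribution of a series at (D, tau).

    There are n = M - (D-1)*tau overlapping windows; probabilities are
    relative frequencies over the dense space of N = D! patterns.  A warning
    is emitted when n < 100*D! (pattern statistics get unreliable well before
    that, but short series remain computable).
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    x = x.ravel()
    if D < 2:
        raise ValueError("embedding dimension D must be >= 2")
    if tau < 1:
        raise ValueError("embedding delay tau must be >= 1")
    M = x.size
    n = M - (D - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {M} too short for D={D}, tau={tau} "
            f"(needs M > (D-1)*tau)"
        )
    N = math.factorial(D)
    if n < 100 * N:
        warnings.warn(
            f"only {n} windows for {N} possible patterns; pattern statistics "
            "may be unreliable (recommend M >> D!)",
            stacklevel=2,
        )
    # n x D window matrix; windows advance by 1, elements stride by tau
    idx = np.arange(n)[:, None] + tau * np.arange(D)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")

    # vectorized Lehmer rank
    ranks = np.zeros(n, dtype=np.int64)
    for i in range(D):
        smaller_later = (patterns[:, i + 1 :] < patterns[:, i : i + 1]).sum(axis=1)
        ranks += smaller_later * _FACTORIALS[D - 1 - i]

    dense = np.bincount(ranks, minlength=N)
    counts = {
        index_to_pattern(int(r), D): int(c)
        for r, c in zip(*np.unique(ranks, return_counts=True))
    }
    return OrdinalDistribution(
        D=D, tau=tau, n_windows=n, counts=counts, probabilities=dense / n
    )
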