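"""Maximum and minimum complexity frontiers of the (H_q, C_q) plane.

Following Martin et al.'s extremal construction, the maximal-complexity
frontier is the upper envelope of the N-1 families in which m-1 states
carry probability 0, one state carries p in [0, 1/(N-m)] and the remaining
N-m states share 1-p equally (m = 1..N-1); the minimal-complexity frontier
is the lower envelope of the two-level families {p/n x n, (1-p)/(N-n) x
(N-n)}, which reduces to the classical one-parameter minimal family at
q = 1 and stays a valid lower bound at other orders.

Every family member takes at most three distinct probability values, so all
quantifiers are evaluated from (value, multiplicity) pairs; this keeps even
the D = 6 (N = 720) frontiers cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .quantifiers import _jensen_shannon_nats, _shannon_nats, max_divergence

__all__ = ["BoundsCurve", "min_complexity_curve", "max_complexity_curve"]

_Q_ONE_TOL = 1e-9


def _hc_weighted(values: np.ndarray, counts: np.ndarray, N: int, q: float):
    """(H_q, C_q) for a batch of distributions given as distinct values.

    ``values`` is (batch, k) of distinct probability values with integer
    multiplicities ``counts`` (k,) summing to N.  Zero values are allowed.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(counts, dtype=float)
    lnN = math.log(N)
    mix = 0.5 * (v + 1.0 / N)  # strictly positive
    if abs(q - 1.0) < _Q_ONE_TOL:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(v > 0, v * np.log(v), 0.0)
        S = -(c * plogp).sum(axis=1)
        Hm = -(c * mix * np.log(mix)).sum(axis=1)
        Dq = Hm - 0.5 * S - 0.5 * lnN
        Dstar = max_divergence(N, 1.0)
    else:
        vq = np.where(v > 0, v, 1.0) ** q * (v > 0)
        S = np.log((c * vq).sum(axis=1)) / (1.0 - q)
        t1 = np.log((c * vq * mix ** (1.0 - q)).sum(axis=1))
        t2 = np.log((c * N ** (-float(q)) * mix ** (1.0 - q)).sum(axis=1))
        Dq = (t1 + t2) / (2.0 * (q - 1.0))
        Dstar = max_divergence(N, q)
    H = S / lnN
    C = Dq * H / Dstar
    return H, C


@dataclass
class BoundsCurve:
    """One side (max or min) of the complexity frontier for given (D, q).

    ``H`` and ``C`` are sorted by H; ``interp`` evaluates the frontier at
    arbitrary H by piecewise-linear interpolation.
    """

    D: int
    q: float
    side: str  # "max" | "min"
    H: np.ndarray
    C: np.ndarray
    resolution: int

    def interp(self, h) -> np.ndarray:
        return np.interp(h, self.H, self.C)

    def samples(self) -> np.ndarray:
        return np.column_stack([self.H, self.C])


def _check_args(D: int, q: float, resolution: int) -> None:
    if D < 2:
        raise ValueError("D must be >= 2")
    if not np.isfinite(q) or q <= 0:
        raise ValueError("q must be positive")
    if resolution < 100:
        raise ValueError("resolution must be >= 100")


def min_complexity_curve(D: int, q: float, resolution: int = 10_000) -> BoundsCurve:
    """Minimal-complexity frontier: lower envelope of two-level families.

    Family n (n = 1..N-1) puts total mass p on n equally likely states and
    shares 1-p over the rest, for p in [n/N, 1].  At q = 1 the n = 1 member
    {p, (1-p)/(N-1), ...} is provably minimal and the envelope coincides
    with it; away from q = 1 that single family is no longer extremal
    (observed distributions undercut it by up to ~1e-2 at q = 0.5, N = 720)
    while the envelope over all n remains a valid lower frontier in
    Monte-Carlo checks.  Endpoints reach (0, 0) (delta) and (1, 0) (uniform).
    """
    _check_args(D, q, resolution)
    N = math.factorial(D)
    n_bins = max(1000, resolution // 2)
    h_grid = np.linspace(0.0, 1.0, n_bins)
    env = np.full(n_bins, np.inf)
    for n in range(1, N):
        rem = N - n
        p = np.linspace(n / N, 1.0, resolution)
        values = np.column_stack([p / n, (1.0 - p) / rem])
        counts = np.array([n, rem])
        H, C = _hc_weighted(values, counts, N, q)
        bins = np.clip(np.round(H * (n_bins - 1)).astype(int), 0, n_bins - 1)
        np.minimum.at(env, bins, C)
    env[0] = min(env[0], 0.0)    # delta endpoint
    env[-1] = min(env[-1], 0.0)  # uniform endpoint
    valid = np.isfinite(env)
    return BoundsCurve(D=D, q=q, side="min", H=h_grid[valid], C=env[valid],
                       resolution=resolution)


def max_complexity_curve(D: int, q: float, resolution: int = 10_000) -> BoundsCurve:
    """Maximal-complexity frontier: upper envelope of the m-zero families.

    For m = 1..N-1: m-1 states at 0, one state at p in [0, 1/(N-m)], and the
    remaining N-m states sharing 1-p equally.  The envelope is returned on a
    uniform H grid (pointwise maximum over families).
    """
    _check_args(D, q, resolution)
    N = math.factorial(D)
    n_bins = max(1000, resolution // 2)
    h_grid = np.linspace(0.0, 1.0, n_bins)
    env = np.full(n_bins, -np.inf)
    for m in range(1, N):
        rem = N - m
        p = np.linspace(0.0, 1.0 / rem, resolution)
        if m == 1:
            values = np.column_stack([p, (1.0 - p) / rem])
            counts = np.array([1, rem])
        else:
            values = np.column_stack([p, np.zeros_like(p), (1.0 - p) / rem])
            counts = np.array([1, m - 1, rem])
        H, C = _hc_weighted(values, counts, N, q)
        # scatter the family onto the H grid, keeping the running maximum
        bins = np.clip(np.round(H * (n_bins - 1)).astype(int), 0, n_bins - 1)
        np.maximum.at(env, bins, C)
    # the delta (H=0, C=0) belongs to the m = N-1 family at p = 0; make the
    # grid explicit at both endpoints
    env[0] = max(env[0], 0.0)
    env[-1] = max(env[-1], 0.0)
    valid = np.isfinite(env)
    H_out = h_grid[valid]
    C_out = env[valid]
    return BoundsCurve(D=D, q=q, side="max", H=H_out, C=C_out, resolution=resolution)
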