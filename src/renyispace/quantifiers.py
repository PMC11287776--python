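"""Renyi permutation entropy and statistical complexity.

For an ordinal-pattern distribution P = (p_1..p_N), N = D!:

    S_q = (1/(1-q)) ln sum_j p_j^q              (q > 0, q != 1; nats)
    H_q = S_q / ln N                            (normalized, in [0, 1])
    D_q = (1/(2(q-1))) [ ln sum_j p_j^q m_j^{1-q}
                         + ln sum_j N^{-q} m_j^{1-q} ],  m_j = (p_j + 1/N)/2
    C_q = D_q * H_q / D_q*

where D_q is the Jensen-Renyi divergence between P and the uniform
distribution through their even mixture, and D_q* its maximum over the
simplex (attained at a delta distribution), with the closed form

    D_q* = (1/(2(q-1))) ln[ ((N+1)^{1-q} + N - 1)/N * ((N+1)/(4N))^{1-q} ].

At q = 1 everything dispatches to the Shannon / Jensen-Shannon limits.
The Shannon-case (MPR) complexity C = Q_0 * J * H is also provided with its
conventional base-2 logarithms; H and C are base-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ordinal import OrdinalDistribution

__all__ = [
    "RenyiPoint",
    "ShannonComplexity",
    "ECCurve",
    "default_q_grid",
    "renyi_entropy",
    "normalized_renyi_entropy",
    "jensen_renyi_divergence",
    "max_divergence",
    "renyi_complexity",
    "renyi_point",
    "mpr_complexity",
    "ec_curve",
]

_Q_ONE_TOL = 1e-9


def default_q_grid(q_min: float = 0.1, q_max: float = 7.0, step: float = 0.01) -> np.ndarray:
    """The default Renyi-order grid: 0.1 to 7 inclusive, step 0.01 (691 points)."""
    n = int(round((q_max - q_min) / step)) + 1
    return np.round(np.linspace(q_min, q_max, n), 10)


def _as_probs(dist) -> np.ndarray:
    """Accept an OrdinalDistribution or a plain probability vector."""
    if isinstance(dist, OrdinalDistribution):
        return dist.probabilities
    p = np.asarray(dist, dtype=float).ravel()
    if p.size < 2:
        raise ValueError("need at least two states")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability vector")
    return np.clip(p, 0.0, None)


def _check_q(q: float) -> float:
    q = float(q)
    if not np.isfinite(q) or q <= 0:
        raise ValueError(f"Renyi order q must be positive, got {q}")
    return q


def _shannon_nats(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def renyi_entropy(dist, q: float) -> float:
    """Order-q Renyi entropy S_q in nats; q = 1 returns the Shannon limit."""
    p = _as_probs(dist)
    q = _check_q(q)
    if abs(q - 1.0) < _Q_ONE_TOL:
        return _shannon_nats(p)
    nz = p[p > 0]  # 0^q = 0 for q > 0: zero-probability states contribute nothing
    return float(np.log((nz**q).sum()) / (1.0 - q))


def normalized_renyi_entropy(dist, q: float) -> float:
    """H_q = S_q / ln N, dimensionless in [0, 1]."""
    p = _as_probs(dist)
    return renyi_entropy(p, q) / math.log(p.size)


def _jensen_shannon_nats(p: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between P and the uniform."""
    N = p.size
    pe = np.full(N, 1.0 / N)
    m = 0.5 * (p + pe)
    return _shannon_nats(m) - 0.5 * _shannon_nats(p) - 0.5 * _shannon_nats(pe)


def jensen_renyi_divergence(dist, q: float) -> float:
    """Jensen-Renyi divergence D_q between P and the uniform distribution.

    Equals (1/2)[R_q(P||M) + R_q(P_e||M)] with M the even mixture
    (p_j + 1/N)/2 and R_q the order-q Renyi divergence; the q -> 1 limit is
    the Jensen-Shannon divergence.
    """
    p = _as_probs(dist)
    q = _check_q(q)
    if abs(q - 1.0) < _Q_ONE_TOL:
        return _jensen_shannon_nats(p)
    N = p.size
    m = 0.5 * (p + 1.0 / N)  # >= 1/(2N) > 0 always
    t1 = np.log((p**q * m ** (1.0 - q)).sum())
    t2 = np.log((N ** (-float(q)) * m ** (1.0 - q)).sum())
    return float((t1 + t2) / (2.0 * (q - 1.0)))


def max_divergence(N: int, q: float) -> float:
    """Maximum of D_q over the N-simplex (attained by a delta distribution)."""
    if int(N) != N or N < 2:
        raise ValueError("N must be an integer >= 2")
    N = int(N)
    q = _check_q(q)
    if abs(q - 1.0) < _Q_ONE_TOL:
        delta = np.zeros(N)
        delta[0] = 1.0
        return _jensen_shannon_nats(delta)
    inner = ((N + 1.0) ** (1.0 - q) + N - 1.0) / N * ((N + 1.0) / (4.0 * N)) ** (1.0 - q)
    return float(np.log(inner) / (2.0 * (q - 1.0)))


def renyi_complexity(dist, q: float) -> float:
    """Renyi statistical complexity C_q = D_q * H_q / D_q*."""
    p = _as_probs(dist)
    return (
        jensen_renyi_divergence(p, q)
        * normalized_renyi_entropy(p, q)
        / max_divergence(p.size, q)
    )


@dataclass
class RenyiPoint:
    """All order-q quantifiers of one distribution at one q."""

    q: float
    S_q: float
    H_q: float
    D_q: float
    D_q_star: float
    C_q: float


def renyi_point(dist, q: float) -> RenyiPoint:
    p = _as_probs(dist)
    S = renyi_entropy(p, q)
    H = S / math.log(p.size)
    D = jensen_renyi_divergence(p, q)
    Dstar = max_divergence(p.size, q)
    return RenyiPoint(q=float(q), S_q=S, H_q=H, D_q=D, D_q_star=Dstar, C_q=D * H / Dstar)


@dataclass
class ShannonComplexity:
    """Shannon-case (MPR) complexity bundle, base-2 logarithms."""

    S: float
    S_max: float
    H: float
    J: float
    Q_0: float
    Q_J: float
    C: float


def mpr_complexity(dist) -> ShannonComplexity:
    """MPR statistical complexity C = Q_0 * J * H.

    S and J use base-2 logarithms; Q_0 is the reciprocal of the
    Jensen-Shannon divergence between a delta distribution and the uniform,
    so that Q_J = Q_0*J lies in [0, 1] and equals 1 at a delta.  H and C are
    invariant to the base choice.
    """
    p = _as_probs(dist)
    N = p.size
    ln2 = math.log(2.0)
    S = _shannon_nats(p) / ln2
    S_max = math.log2(N)
    H = S / S_max
    J = _jensen_shannon_nats(p) / ln2
    delta = np.zeros(N)
    delta[0] = 1.0
    J_max = _jensen_shannon_nats(delta) / ln2
    Q_0 = 1.0 / J_max
    Q_J = Q_0 * J
    return ShannonComplexity(S=S, S_max=S_max, H=H, J=J, Q_0=Q_0, Q_J=Q_J, C=Q_J * H)


@dataclass
class ECCurve:
    """Parametric entropy-complexity curve {(q, H_q, C_q)} over a q grid."""

    q_grid: np.ndarray
    H: np.ndarray
    C: np.ndarray
    S: np.ndarray
    D: int
    tau: int
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.q_grid.size

    def point(self, i: int) -> tuple:
        return (float(self.q_grid[i]), float(self.H[i]), float(self.C[i]))

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "label": self.label,
                "D": self.D,
                "tau": self.tau,
                "q_grid": self.q_grid.tolist(),
                "H": self.H.tolist(),
                "C": self.C.tolist(),
                "S": self.S.tolist(),
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ECCurve":
        import json

        o = json.loads(text)
        return cls(
            q_grid=np.asarray(o["q_grid"]),
            H=np.asarray(o["H"]),
            C=np.asarray(o["C"]),
            S=np.asarray(o["S"]),
            D=int(o["D"]),
            tau=int(o["tau"]),
            label=o.get("label", ""),
            meta=o.get("meta", {}),
        )


def ec_curve(
    dist,
    q_grid: Sequence[float] | None = None,
    label: str = "",
    D: int | None = None,
    tau: int | None = None,
) -> ECCurve:
    """Evaluate (S_q, H_q, C_q) over a strictly increasing q grid.

    Vectorized over the grid; the q = 1 grid point (if present) uses the
    exact Shannon/Jensen-Shannon limit.
    """
    if isinstance(dist, OrdinalDistribution):
        D = dist.D if D is None else D
        tau = dist.tau if tau is None else tau
    p = _as_probs(dist)
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float).ravel()
    if q.size == 0:
        raise ValueError("q grid must be non-empty")
    if np.any(q <= 0):
        raise ValueError("all q must be positive")
    if q.size > 1 and np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")

    N = p.size
    lnN = math.log(N)
    nz = p[p > 0]
    m = 0.5 * (p + 1.0 / N)
    is_one = np.abs(q - 1.0) < _Q_ONE_TOL
    qc = np.where(is_one, 2.0, q)[:, None]  # placeholder order at q=1 slots

    S = np.log((nz[None, :] ** qc).sum(axis=1)) / (1.0 - qc[:, 0])
    t1 = np.log((p[None, :] ** qc * m[None, :] ** (1.0 - qc)).sum(axis=1))
    t2 = np.log((N ** (-qc) * m[None, :] ** (1.0 - qc)).sum(axis=1))
    Dq = (t1 + t2) / (2.0 * (qc[:, 0] - 1.0))
    inner = ((N + 1.0) ** (1.0 - qc[:, 0]) + N - 1.0) / N * (
        (N + 1.0) / (4.0 * N)
    ) ** (1.0 - qc[:, 0])
    Dstar = np.log(inner) / (2.0 * (qc[:, 0] - 1.0))

    if is_one.any():
        S[is_one] = _shannon_nats(p)
        Dq[is_one] = _jensen_shannon_nats(p)
        delta = np.zeros(N)
        delta[0] = 1.0
        Dstar[is_one] = _jensen_shannon_nats(delta)

    H = S / lnN
    C = Dq * H / Dstar
    return ECCurve(
        q_grid=q, H=H, C=C, S=S, D=int(D) if D else 0, tau=int(tau) if tau else 0,
        label=label,
    )
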