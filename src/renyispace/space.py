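"""The Renyi entropy-complexity causality space (H_q x C_q x q).

A space stacks per-signal entropy-complexity curves over a shared q grid,
attaches the theoretical max/min complexity frontiers at a set of q planes,
and provides group statistics plus an explicit numeric stand-in for the
visual judgement of curve separation: two groups are separated at a given q
when their axis-aligned 1-SD ellipses are disjoint,

    (dH)^2/(sH_A+sH_B)^2 + (dC)^2/(sC_A+sC_B)^2 > 1,

and flagged when a contiguous separated run spans at least 0.5 in q inside
the inspection window (default [1, 7]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bounds import BoundsCurve, max_complexity_curve, min_complexity_curve
from .quantifiers import ECCurve

__all__ = ["ECSpace", "GroupCurveStats", "build_space", "group_stats",
           "ellipse_separation", "matched_q_separation",
           "projected_min_distance", "render", "DEFAULT_Q_PLANES"]

DEFAULT_Q_PLANES = (0.5, 0.7, 1.0, 1.4, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)


@dataclass
class ECSpace:
    curves: list
    D: int
    q_planes: tuple
    bounds: dict  # q -> (min BoundsCurve, max BoundsCurve)

    def plane_points(self, q: float):
        """(label, H, C) of every curve at the grid point nearest to q."""
        out = []
        for c in self.curves:
            i = int(np.argmin(np.abs(c.q_grid - q)))
            out.append((c.label, float(c.H[i]), float(c.C[i])))
        return out

    def projection(self):
        """All (H, C) pairs of all curves — the 2-D projection, no resampling."""
        return [(c.label, np.column_stack([c.H, c.C])) for c in self.curves]


def build_space(curves, D: int | None = None, q_planes=DEFAULT_Q_PLANES,
                bounds_resolution: int = 2000, tolerance: float = 5e-3) -> ECSpace:
    """Assemble curves into a space, attach bounds, validate containment.

    All curves must share (D, tau, q grid).  Every curve point must lie
    within [C_min(H), C_max(H)] of its plane's bounds at each materialized
    plane.  The default tolerance covers both interpolation error and the
    fact that the extremal one-parameter families are exactly extremal only
    in the Shannon case (q = 1); off q = 1 real distributions can pass the
    frontiers by a few parts in a thousand.
    """
    curves = sorted(list(curves), key=lambda c: c.label)
    if not curves:
        raise ValueError("need at least one curve")
    ref = curves[0]
    D = ref.D if D is None else D
    offenders = [c.label for c in curves
                 if c.D != ref.D or c.tau != ref.tau
                 or c.q_grid.size != ref.q_grid.size
                 or not np.allclose(c.q_grid, ref.q_grid)]
    if offenders:
        raise ValueError(f"curves not homogeneous in (D, tau, q grid): {offenders}")

    bounds = {}
    for q in q_planes:
        bounds[q] = (min_complexity_curve(D, q, bounds_resolution),
                     max_complexity_curve(D, q, bounds_resolution))
    space = ECSpace(curves=curves, D=D, q_planes=tuple(q_planes), bounds=bounds)
    for q, (bmin, bmax) in bounds.items():
        for label, H, C in space.plane_points(q):
            lo, hi = float(bmin.interp(H)), float(bmax.interp(H))
            if C < lo - tolerance or C > hi + tolerance:
                raise ValueError(
                    f"curve '{label}' leaves the complexity bounds at q={q}: "
                    f"H={H:.4f}, C={C:.6f} not in [{lo:.6f}, {hi:.6f}]"
                )
    return space


@dataclass
class GroupCurveStats:
    label: str
    n: int
    q_grid: np.ndarray
    mean_H: np.ndarray
    mean_C: np.ndarray
    sd_H: np.ndarray
    sd_C: np.ndarray


def group_stats(curves, label: str = "") -> GroupCurveStats:
    """Pointwise mean and SD of H and C along the shared q grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("empty group")
    q = curves[0].q_grid
    H = np.stack([c.H for c in curves])
    C = np.stack([c.C for c in curves])
    return GroupCurveStats(label=label, n=len(curves), q_grid=q,
                           mean_H=H.mean(axis=0), mean_C=C.mean(axis=0),
                           sd_H=H.std(axis=0), sd_C=C.std(axis=0))


@dataclass
class SeparationResult:
    flag: int
    intervals: list          # [(q_start, q_end), ...] of separated runs
    criterion: np.ndarray    # per-grid-point ellipse statistic
    q_window: tuple
    min_run: float


def ellipse_separation(stats_a: GroupCurveStats, stats_b: GroupCurveStats,
                       q_window=(1.0, 7.0), sd_mult: float = 1.0,
                       min_run: float = 0.5) -> SeparationResult:
    """Disjoint 1-SD ellipse test along the q grid.

    Flag 1 iff a contiguous run of separated grid points spans at least
    ``min_run`` in q inside the window.  Degenerate points (all SDs zero and
    equal means) are not separated.
    """
    q = stats_a.q_grid
    if stats_b.q_grid.size != q.size or not np.allclose(stats_b.q_grid, q):
        raise ValueError("group stats live on different q grids")
    dH = stats_a.mean_H - stats_b.mean_H
    dC = stats_a.mean_C - stats_b.mean_C
    sH = sd_mult * (stats_a.sd_H + stats_b.sd_H)
    sC = sd_mult * (stats_a.sd_C + stats_b.sd_C)
    with np.errstate(divide="ignore", invalid="ignore"):
        termH = np.where(sH > 0, (dH / sH) ** 2, np.where(dH != 0, np.inf, 0.0))
        termC = np.where(sC > 0, (dC / sC) ** 2, np.where(dC != 0, np.inf, 0.0))
    crit = termH + termC
    in_win = (q >= q_window[0]) & (q <= q_window[1])
    sep = (crit > 1.0) & in_win

    intervals = []
    flag = 0
    start = None
    for i, s in enumerate(sep):
        if s and start is None:
            start = i
        if (not s or i == sep.size - 1) and start is not None:
            end = i if s else i - 1
            intervals.append((float(q[start]), float(q[end])))
            if q[end] - q[start] >= min_run:
                flag = 1
            start = None
    return SeparationResult(flag=flag, intervals=intervals, criterion=crit,
                            q_window=tuple(q_window), min_run=min_run)


def matched_q_separation(curve_a: ECCurve, curve_b: ECCurve) -> float:
    """Minimum Euclidean (H, C) distance at matched q — the 3-D separation."""
    d = np.hypot(curve_a.H - curve_b.H, curve_a.C - curve_b.C)
    return float(d.min())


def projected_min_distance(curve_a: ECCurve, curve_b: ECCurve) -> float:
    """Minimum (H, C) distance over all q pairs — the 2-D projection distance."""
    dH = curve_a.H[:, None] - curve_b.H[None, :]
    dC = curve_a.C[:, None] - curve_b.C[None, :]
    return float(np.hypot(dH, dC).min())


def render(space: ECSpace, outdir: str | Path, stem: str = "space") -> list:
    """Write a 3-D view and per-plane 2-D projections with bounds (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for c in space.curves:
        ax.plot(c.H, c.q_grid, c.C, label=c.label)
    for q, (bmin, bmax) in space.bounds.items():
        ax.plot(bmax.H, np.full_like(bmax.H, q), bmax.C, color="red", lw=0.6)
        ax.plot(bmin.H, np.full_like(bmin.H, q), bmin.C, color="blue", lw=0.6)
    ax.set_xlabel("$H_q$"); ax.set_ylabel("$q$"); ax.set_zlabel("$C_q$")
    if len(space.curves) <= 12:
        ax.legend(fontsize=7)
    p3d = outdir / f"{stem}_3d.png"
    fig.savefig(p3d, dpi=120); plt.close(fig)
    written.append(p3d)

    for q, (bmin, bmax) in space.bounds.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(bmax.H, bmax.C, "k-", lw=1)
        ax.plot(bmin.H, bmin.C, "k-", lw=1)
        for label, H, C in space.plane_points(q):
            ax.plot(H, C, "o", ms=4, label=label)
        ax.set_xlabel("$H_q$"); ax.set_ylabel("$C_q$"); ax.set_title(f"q = {q}")
        fp = outdir / f"{stem}_plane_q{q}.png"
        fig.savefig(fp, dpi=120); plt.close(fig)
        written.append(fp)
    return written
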