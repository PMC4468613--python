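"""Box-constrained Nelder-Mead simplex minimizer.

A from-scratch implementation of the Nelder-Mead direct-search method with a
Spendley regular initial simplex, the standard reflection / expansion /
contraction / shrink logic (coefficients 1, 2, 0.5, 0.5) and componentwise
projection of every trial point onto a bound box before evaluation.

To make a single scalar initial-simplex edge length meaningful across
parameters of very different magnitudes, :func:`minimize` runs internally in
box-normalized coordinates (each parameter scaled to [0, 1] by its bounds);
all public inputs and outputs are in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NMConfig",
    "Simplex",
    "FitResult",
    "OptimizationError",
    "initial_simplex",
    "order_vertices",
    "centroid",
    "nm_step",
    "minimize",
]


class OptimizationError(RuntimeError):
    """The cost function could not be evaluated anywhere useful."""


@dataclass
class NMConfig:
    """Nelder-Mead settings.

    delta_* are the reflection/expansion/contraction/shrink coefficients;
    ``simplex_size`` is the Spendley edge length in normalized coordinates;
    ``tol_x`` is the simplex-diameter and ``tol_f`` the value-spread stopping
    tolerance; ``n_restarts`` > 1 re-runs from seeded random starts inside
    the box and keeps the best result.
    """

    delta_reflect: float = 1.0
    delta_expand: float = 2.0
    delta_contract: float = 0.5
    delta_shrink: float = 0.5
    simplex_size: float = 0.1
    max_iter: int = 5000
    tol_x: float = 1e-6
    tol_f: float = 1e-10
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_reflect", "delta_expand", "delta_contract", "delta_shrink"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simplex_size <= 0:
            raise ValueError("simplex_size must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")


@dataclass
class Simplex:
    """n+1 vertices in n dimensions with their cost values."""

    vertices: np.ndarray  # (n+1, n)
    values: np.ndarray  # (n+1,)

    @property
    def n(self) -> int:
        return self.vertices.shape[1]

    def diameter(self) -> float:
        """Max vertex distance from the best vertex (infinity norm)."""
        best = self.vertices[int(np.argmin(self.values))]
        return float(np.max(np.abs(self.vertices - best)))


@dataclass
class FitResult:
    """Outcome of a bounded Nelder-Mead minimization."""

    x_opt: np.ndarray
    j_opt: float
    n_iter: int
    converged: bool
    trace: np.ndarray
    restart_index: int = 0
    n_fev: int = 0


def initial_simplex(
    x0: np.ndarray, a: float, bounds: np.ndarray | None = None
) -> np.ndarray:
    """Spendley regular simplex of edge length ``a`` anchored at ``x0``.

    Vertex j (j = 1..n) is ``x0 + p e_j + q sum_{k != j} e_k`` with
    ``p = a/(n sqrt 2) (sqrt(n+1) + n - 1)`` and
    ``q = a/(n sqrt 2) (sqrt(n+1) - 1)``; x0 itself is kept as the last
    vertex.  All n+1 pairwise edges have length exactly ``a`` before any
    clipping.  If ``bounds`` is given, vertices are projected componentwise
    onto the box.
    """
    if a <= 0:
        raise ValueError("initial simplex size a must be positive")
    x0 = np.asarray(x0, dtype=float).ravel()
    n = x0.size
    p = a / (n * np.sqrt(2.0)) * (np.sqrt(n + 1.0) + n - 1.0)
    q = a / (n * np.sqrt(2.0)) * (np.sqrt(n + 1.0) - 1.0)
    verts = np.tile(x0, (n + 1, 1))
    verts[:n] += q
    verts[np.arange(n), np.arange(n)] += p - q
    if bounds is not None:
        verts = np.clip(verts, bounds[:, 0], bounds[:, 1])
    return verts


def order_vertices(s: Simplex) -> tuple[int, int, int]:
    """Indices of the best (x_l), second-worst (x_s) and worst (x_h) vertices.

    Ties break by vertex index (stable sort).
    """
    order = np.argsort(s.values, kind="stable")
    return int(order[0]), int(order[-2]), int(order[-1])


def centroid(s: Simplex, exclude: int) -> np.ndarray:
    """Arithmetic mean of all vertices except ``exclude`` (the worst)."""
    mask = np.ones(len(s.values), dtype=bool)
    mask[exclude] = False
    return s.vertices[mask].mean(axis=0)


def _safe_eval(f, x: np.ndarray) -> float:
    try:
        v = float(f(x))
    except (ArithmeticError, ValueError):
        return np.inf
    return v if np.isfinite(v) else np.inf


def nm_step(
    s: Simplex, cfg: NMConfig, f, bounds: np.ndarray | None = None
) -> tuple[Simplex, int]:
    """One Nelder-Mead iteration; returns the updated simplex and #evaluations.

    Applies the standard acceptance logic: reflect the worst vertex through
    the centroid; expand when the reflected point improves on the best;
    contract (outside or inside) when it does not improve on the second
    worst; shrink all vertices toward the best when contraction fails.  Every
    candidate is clipped to the box before evaluation, so no point outside
    the bounds is ever evaluated.  The best vertex value never increases.
    """

    def clip(x: np.ndarray) -> np.ndarray:
        if bounds is None:
            return x
        return np.clip(x, bounds[:, 0], bounds[:, 1])

    il, is_, ih = order_vertices(s)
    xbar = centroid(s, ih)
    fl, fs, fh = s.values[il], s.values[is_], s.values[ih]
    verts = s.vertices.copy()
    vals = s.values.copy()
    nfev = 0

    xr = clip(xbar + cfg.delta_reflect * (xbar - s.vertices[ih]))
    fr = _safe_eval(f, xr)
    nfev += 1

    if fr < fl:
        xe = clip(xbar + cfg.delta_expand * (xr - xbar))
        fe = _safe_eval(f, xe)
        nfev += 1
        if fe < fr:
            verts[ih], vals[ih] = xe, fe
        else:
            verts[ih], vals[ih] = xr, fr
    elif fr < fs:
        verts[ih], vals[ih] = xr, fr
    else:
        if fr < fh:  # outside contraction
            xc = clip(xbar + cfg.delta_contract * (xr - xbar))
            fc = _safe_eval(f, xc)
            nfev += 1
            accept = fc <= fr
        else:  # inside contraction
            xc = clip(xbar + cfg.delta_contract * (s.vertices[ih] - xbar))
            fc = _safe_eval(f, xc)
            nfev += 1
            accept = fc < fh
        if accept:
            verts[ih], vals[ih] = xc, fc
        else:  # shrink every vertex toward the best
            xl = s.vertices[il]
            for i in range(len(vals)):
                if i == il:
                    continue
                verts[i] = clip(xl + cfg.delta_shrink * (s.vertices[i] - xl))
                vals[i] = _safe_eval(f, verts[i])
                nfev += 1
    return Simplex(verts, vals), nfev


def _run_single(f, x0: np.ndarray, bounds: np.ndarray, cfg: NMConfig) -> FitResult:
    x0 = np.clip(np.asarray(x0, dtype=float).ravel(), bounds[:, 0], bounds[:, 1])
    verts = initial_simplex(x0, cfg.simplex_size, bounds)
    vals = np.array([_safe_eval(f, v) for v in verts])
    nfev = len(vals)
    if not np.any(np.isfinite(vals)):
        raise OptimizationError(
            "cost function is non-finite at every initial simplex vertex; "
            f"vertices:\n{verts!r}"
        )
    s = Simplex(verts, vals)
    trace = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        trace.append(float(np.min(s.values)))
        if s.diameter() <= cfg.tol_x and np.ptp(s.values) <= cfg.tol_f:
            converged = True
            break
        s, ne = nm_step(s, cfg, f, bounds)
        nfev += ne
    best = int(np.argmin(s.values))
    trace.append(float(s.values[best]))
    return FitResult(
        x_opt=s.vertices[best].copy(),
        j_opt=float(s.values[best]),
        n_iter=it,
        converged=converged,
        trace=np.minimum.accumulate(np.asarray(trace)),
        n_fev=nfev,
    )


# Restart-polish schedule: ladder shrink factor and the smallest ladder edge
# length (box-normalized coordinates).
_LADDER_SHRINK = 4.0
_LADDER_FLOOR = 1e-5


def _restart_run(
    f, z0: np.ndarray, bounds: np.ndarray, cfg: NMConfig, size: float | None = None
) -> FitResult:
    """One restart: iterated NM with a coarse-to-fine simplex-size ladder.

    Each round runs NM to its own tol_x/tol_f convergence (never
    interrupted mid-descent, so the simplex can adapt to valley
    anisotropy).  After a converged round, a fresh simplex is re-seeded at
    the incumbent — the classic remedy for premature simplex collapse —
    keeping the edge length while rounds still improve materially and
    shrinking it toward the ladder floor otherwise.  The total iteration
    budget for the restart is ``cfg.max_iter``.
    """
    from dataclasses import replace

    a = size if size is not None else cfg.simplex_size
    floor = min(a, _LADDER_FLOOR)
    budget = cfg.max_iter
    best: FitResult | None = None
    start = np.asarray(z0, dtype=float)
    total_iter = 0
    total_fev = 0
    traces = []
    converged = False
    while budget > 0:
        sub = replace(cfg, simplex_size=a, max_iter=budget)
        res = _run_single(f, start, bounds, sub)
        total_iter += res.n_iter
        total_fev += res.n_fev
        budget -= res.n_iter
        traces.append(res.trace)
        # only a materially better round earns another pass at this edge
        # length; otherwise descend the ladder and polish finer
        improved = best is None or res.j_opt < best.j_opt - max(
            cfg.tol_f, 1e-3 * abs(best.j_opt)
        )
        if best is None or res.j_opt < best.j_opt:
            best = res
        start = best.x_opt
        converged = res.converged
        if not improved:
            if a <= floor:
                break
            a = max(a / _LADDER_SHRINK, floor)
    assert best is not None
    trace = np.minimum.accumulate(np.concatenate(traces))
    return FitResult(
        x_opt=best.x_opt,
        j_opt=best.j_opt,
        n_iter=total_iter,
        converged=converged,
        trace=trace,
        n_fev=total_fev,
    )


def minimize(
    f,
    x0: np.ndarray,
    bounds: np.ndarray,
    cfg: NMConfig | None = None,
    start_sizes: np.ndarray | None = None,
) -> FitResult:
    """Minimize ``f`` over the box ``bounds`` starting from ``x0``.

    Optimization runs in box-normalized coordinates so the Spendley edge
    length applies uniformly to all parameters.  ``x0`` may be a single
    point or a stack of candidate starts (shape ``(m, n)``).  With
    ``cfg.n_restarts`` > the number of supplied starts, the remaining starts
    are drawn uniformly inside the box from a generator seeded with
    ``cfg.seed``; the best final value wins (``restart_index`` records
    which).  Each restart polishes by re-seeding the simplex at its
    incumbent until no further improvement.

    ``start_sizes`` optionally gives a per-start initial simplex edge length
    (normalized coordinates) for the supplied starts — useful when a start
    is already believed to lie close to a minimum; random restarts always
    use ``cfg.simplex_size``.

    Parameters with a zero-width bound (lower == upper) are held fixed.
    """
    cfg = cfg if cfg is not None else NMConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must have shape (n, 2)")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("every lower bound must not exceed its upper bound")
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    free = width > 0
    starts = np.atleast_2d(np.asarray(x0, dtype=float))
    if starts.shape[1] != bounds.shape[0]:
        raise ValueError("x0 dimension does not match bounds")
    starts = np.clip(starts, lo, hi)

    def denorm(z: np.ndarray) -> np.ndarray:
        x = lo.copy()
        x[free] = lo[free] + z * width[free]
        return x

    def f_norm(z: np.ndarray) -> float:
        return f(denorm(z))

    nfree = int(free.sum())
    unit_box = np.tile([0.0, 1.0], (nfree, 1))
    z_starts = (starts[:, free] - lo[free]) / width[free]

    rng = np.random.default_rng(cfg.seed)
    n_restarts = max(cfg.n_restarts, 1)
    best: FitResult | None = None
    for k in range(n_restarts):
        if k < len(z_starts):
            start = z_starts[k]
            size = None if start_sizes is None else float(start_sizes[k])
        else:
            start = rng.uniform(0.0, 1.0, size=nfree)
            size = None
        res = _restart_run(f_norm, start, unit_box, cfg, size=size)
        if best is None or res.j_opt < best.j_opt:
            res.restart_index = k
            res.x_opt = denorm(res.x_opt)
            best = res
    assert best is not None
    return best
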