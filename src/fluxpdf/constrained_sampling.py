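"""Rejection-free weighted sampling of one linear constraint.

The primitive this module provides draws a joint configuration of variables
subject to a single linear equality ``sum_l c_l x_l = target`` (or interval
``target_lo <= sum_l c_l x_l <= target_hi``), where each variable carries its
own density represented as a *weighted population*: a finite set of support
points with nonnegative weights.

Variables are sampled sequentially.  Before sampling a variable, interval
arithmetic over the not-yet-sampled variables gives the exact range the
remaining sum can still cover; the next variable is then drawn from its
population *truncated to the feasible window* that keeps the constraint
satisfiable.  The probability mass of the window (relative to the whole
population) multiplies the draw's importance weight, so the procedure never
rejects: an infeasible configuration simply comes back with weight zero.
For hard equalities one designated variable is solved for exactly at the
end, contributing its population density at the solved point divided by
|coefficient| (the Jacobian of the delta function) to the weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WeightedPopulation",
    "LinearConstraint",
    "WeightedDraw",
    "DrawCounter",
    "achievable_range",
    "feasible_window",
    "truncated_weighted_draw",
    "constrained_joint_sample",
    "sample_many",
]

#: relative tolerance used when deciding whether an interval is empty
EMPTY_TOL = 1e-12


@dataclass
class DrawCounter:
    """Counts elementary (per-variable) truncated draws.  Used to verify the
    linear cost scaling of the message-passing engine by operation counts
    rather than wall clock."""

    elementary_draws: int = 0

    def add(self, n: int) -> None:
        self.elementary_draws += int(n)


class WeightedPopulation:
    """Density of one variable as ``Q`` support points with weights.

    Values must lie within the support ``[lo, hi]``; weights are finite,
    nonnegative, with at least one strictly positive.  The population is
    stored sorted by value with a prefix-sum of weights so window masses and
    truncated draws are O(log Q).
    """

    __slots__ = (
        "values", "weights", "lo", "hi", "_cum", "_total", "_dens_cache",
        "_step", "_v0",
    )

    def __init__(self, values, weights, lo: float | None = None, hi: float | None = None):
        values = np.asarray(values, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if values.ndim != 1 or values.shape != weights.shape or values.size == 0:
            raise ValueError("values and weights must be equal-length 1-D arrays")
        if not np.all(np.isfinite(values)):
            raise ValueError("population values must be finite")
        if not np.all(np.isfinite(weights)) or np.any(weights < 0):
            raise ValueError("weights must be finite and nonnegative")
        if not np.any(weights > 0):
            raise ValueError("population needs at least one positive weight")
        order = np.argsort(values, kind="stable")
        self.values = values[order]
        self.weights = weights[order]
        self.lo = float(self.values[0] if lo is None else lo)
        self.hi = float(self.values[-1] if hi is None else hi)
        if self.values[0] < self.lo - _tol(self.lo, self.hi) or self.values[-1] > self.hi + _tol(self.lo, self.hi):
            raise ValueError("population values outside declared support")
        self._cum = np.concatenate(([0.0], np.cumsum(self.weights)))
        self._total = float(self._cum[-1])
        self._dens_cache: dict[int, tuple[np.ndarray, float]] = {}
        # equispaced grids admit O(1) window indexing
        self._step = None
        self._v0 = float(self.values[0])
        if self.values.size > 1:
            d = np.diff(self.values)
            step = d[0]
            if step > 0 and np.allclose(d, step, rtol=1e-9, atol=0.0):
                self._step = float(step)

    def _index_window(self, a: np.ndarray, b: np.ndarray):
        """Index range [i0, i1) of values inside [a, b] (vectorised)."""
        q = self.values.size
        if self._step is not None:
            eps = 1e-9
            i0 = np.ceil((a - self._v0) / self._step - eps).astype(np.int64)
            i1 = np.floor((b - self._v0) / self._step + eps).astype(np.int64) + 1
            np.clip(i0, 0, q, out=i0)
            np.clip(i1, i0, q, out=i1)
            return i0, i1
        i0 = np.searchsorted(self.values, a, side="left")
        i1 = np.searchsorted(self.values, b, side="right")
        return i0, np.maximum(i1, i0)

    @property
    def total_weight(self) -> float:
        return self._total

    @classmethod
    def uniform_grid(cls, lo: float, hi: float, q: int) -> "WeightedPopulation":
        """Equispaced grid of q points on [lo, hi] (both endpoints included)
        with equal weights; a single unit-weight point when lo == hi."""
        if hi < lo:
            raise ValueError("need lo <= hi")
        if lo == hi or q == 1:
            return cls(np.array([lo]), np.array([1.0]), lo, hi)
        vals = np.linspace(lo, hi, q)
        return cls(vals, np.full(q, 1.0 / q), lo, hi)

    def window_mass(self, a: float, b: float) -> float:
        """Fraction of total population weight carried by values in [a, b]."""
        if b < a:
            return 0.0
        i0 = np.searchsorted(self.values, a, side="left")
        i1 = np.searchsorted(self.values, b, side="right")
        return (self._cum[i1] - self._cum[i0]) / self._total

    def density(self, x, bins: int = 50):
        """Piecewise-constant density estimate: population weights binned
        into ``bins`` equal-width bins over [lo, hi], normalised to integrate
        to one; evaluated at x (scalar or array).  Degenerate supports
        (lo == hi) return the indicator-like value 1.0 at the point."""
        x = np.asarray(x, dtype=float)
        if self.hi == self.lo:
            out = np.where(np.isclose(x, self.lo), 1.0, 0.0)
            return out if out.ndim else float(out)
        key = int(bins)
        if key not in self._dens_cache:
            hist, _ = np.histogram(
                self.values, bins=key, range=(self.lo, self.hi), weights=self.weights
            )
            width = (self.hi - self.lo) / key
            self._dens_cache[key] = (hist / (self._total * width), width)
        dens, width = self._dens_cache[key]
        idx = np.clip(((x - self.lo) / width).astype(int), 0, key - 1)
        inside = (x >= self.lo - _tol(self.lo, self.hi)) & (
            x <= self.hi + _tol(self.lo, self.hi)
        )
        out = np.where(inside, dens[idx], 0.0)
        return out if out.ndim else float(out)


def _tol(*vals: float) -> float:
    finite = [abs(v) for v in vals if np.isfinite(v)]
    return EMPTY_TOL * max([1.0] + finite)


@dataclass(frozen=True)
class LinearConstraint:
    """One linear constraint ``sum_l coefficients[l] * x_l  (= c | in [c_lo, c_hi])``.

    ``target`` is a float for a hard equality or a (lo, hi) pair for an
    interval constraint (the uniform-exchange-window case)."""

    variables: tuple
    coefficients: tuple
    target: float | tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.variables) == 0:
            raise ValueError("constraint needs at least one variable")
        if len(self.variables) != len(self.coefficients):
            raise ValueError("one coefficient per variable required")
        if any(c == 0 or not np.isfinite(c) for c in self.coefficients):
            raise ValueError("coefficients must be nonzero and finite")
        if isinstance(self.target, tuple):
            lo, hi = self.target
            if lo > hi:
                raise ValueError("interval target requires c_lo <= c_hi")

    @property
    def is_equality(self) -> bool:
        return not isinstance(self.target, tuple)

    def target_interval(self) -> tuple[float, float]:
        if self.is_equality:
            return (float(self.target), float(self.target))
        return (float(self.target[0]), float(self.target[1]))


@dataclass
class WeightedDraw:
    """One joint configuration with its importance weight.  Weight 0 marks a
    draw whose feasible window was empty at some step (never an exception)."""

    assignment: np.ndarray
    weight: float


# ---------------------------------------------------------------------------
# interval arithmetic


def achievable_range(
    coefficients: Sequence[float], supports: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Exact range of ``sum_l c_l x_l`` over the box of supports.  The empty
    sum has range [0, 0]."""
    lo = hi = 0.0
    for c, (a, b) in zip(coefficients, supports):
        lo += min(c * a, c * b)
        hi += max(c * a, c * b)
    return (lo, hi)


def feasible_window(
    residual: float | tuple[float, float],
    next_coeff: float,
    next_support: tuple[float, float],
    remaining_range: tuple[float, float],
) -> tuple[float, float] | None:
    """Values v of the next variable for which ``residual - next_coeff*v``
    can still be covered by the remaining variables.  ``residual`` is a
    scalar (equality constraint) or an interval.  Returns a closed interval
    or None when empty."""
    if isinstance(residual, tuple):
        r_lo, r_hi = residual
    else:
        r_lo = r_hi = float(residual)
    a, b = remaining_range
    # need next_coeff * v in [r_lo - b, r_hi - a]
    if next_coeff > 0:
        w_lo, w_hi = (r_lo - b) / next_coeff, (r_hi - a) / next_coeff
    else:
        w_lo, w_hi = (r_hi - a) / next_coeff, (r_lo - b) / next_coeff
    s_lo, s_hi = next_support
    w_lo, w_hi = max(w_lo, s_lo), min(w_hi, s_hi)
    tol = _tol(s_lo, s_hi, abs(r_lo), abs(r_hi))
    if w_hi < w_lo - tol:
        return None
    if w_hi < w_lo:  # float-thin window: collapse to its midpoint
        mid = 0.5 * (w_lo + w_hi)
        return (mid, mid)
    return (w_lo, w_hi)


def truncated_weighted_draw(
    pop: WeightedPopulation,
    window: tuple[float, float] | None,
    rng: np.random.Generator,
) -> tuple[float | None, float]:
    """Draw one value from ``pop`` restricted to ``window`` with probability
    proportional to its weight.  Returns (value, window_weight) where
    window_weight is the window's share of the total population mass; an
    empty window returns (None, 0.0)."""
    if rng is None:
        raise ValueError("an explicit rng is required")
    if window is None:
        return None, 0.0
    a, b = window
    i0 = np.searchsorted(pop.values, a, side="left")
    i1 = np.searchsorted(pop.values, b, side="right")
    mass = pop._cum[i1] - pop._cum[i0]
    if mass <= 0.0:
        return None, 0.0
    u = pop._cum[i0] + rng.random() * mass
    pos = int(np.clip(np.searchsorted(pop._cum, u, side="right") - 1, i0, i1 - 1))
    return float(pop.values[pos]), float(mass / pop.total_weight)


# ---------------------------------------------------------------------------
# scalar joint draw


def constrained_joint_sample(
    constraint: LinearConstraint,
    pops: Sequence[WeightedPopulation],
    solved_index: int | str = "auto",
    rng: np.random.Generator | None = None,
    density_bins: int = 50,
) -> WeightedDraw:
    """Draw one joint configuration satisfying ``constraint``.

    Equality targets: every variable but one (``solved_index``, or an
    automatic choice) is sampled via feasible windows; the solved variable is
    set exactly and contributes density/|coeff| to the weight.  Interval
    targets: all variables are sampled with windows guaranteeing the final
    sum lands in the interval.  Weight 0 iff some window was empty.
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    coeffs = np.asarray(constraint.coefficients, dtype=float)
    n = coeffs.size
    supports = [(p.lo, p.hi) for p in pops]
    if len(pops) != n:
        raise ValueError("one population per variable required")
    t_lo, t_hi = constraint.target_interval()

    if constraint.is_equality:
        solved = _pick_solved(coeffs, supports, t_lo, solved_index)
        order = [k for k in range(n) if k != solved]
    else:
        solved = None
        order = list(range(n))
    order = [order[k] for k in rng.permutation(len(order))]

    assignment = np.full(n, np.nan)
    weight = 1.0
    remaining = set(range(n)) - (set() if solved is None else set())
    r_lo, r_hi = t_lo, t_hi
    pending = set(order) | ({solved} if solved is not None else set())
    for j in order:
        pending.discard(j)
        rest = [k for k in pending]
        rem = achievable_range(coeffs[rest], [supports[k] for k in rest])
        win = feasible_window((r_lo, r_hi), coeffs[j], supports[j], rem)
        val, wj = truncated_weighted_draw(pops[j], win, rng)
        if val is None:
            return WeightedDraw(assignment, 0.0)
        assignment[j] = val
        weight *= wj
        r_lo -= coeffs[j] * val
        r_hi -= coeffs[j] * val
    if solved is not None:
        x = 0.5 * (r_lo + r_hi) / coeffs[solved]
        s_lo, s_hi = supports[solved]
        tol = _tol(s_lo, s_hi)
        if x < s_lo - tol or x > s_hi + tol:
            return WeightedDraw(assignment, 0.0)
        assignment[solved] = float(np.clip(x, s_lo, s_hi))
        weight *= pops[solved].density(assignment[solved], bins=density_bins)
        weight /= abs(coeffs[solved])
    if not np.isfinite(weight):
        raise FloatingPointError("non-finite draw weight")
    return WeightedDraw(assignment, float(weight))


def _pick_solved(coeffs, supports, target, solved_index) -> int:
    if solved_index != "auto":
        return int(solved_index)
    n = coeffs.size
    if n == 1:
        return 0
    widths = np.empty(n)
    for k in range(n):
        rest = [l for l in range(n) if l != k]
        rem = achievable_range(coeffs[rest], [supports[l] for l in rest])
        win = feasible_window(target, coeffs[k], supports[k], rem)
        widths[k] = -np.inf if win is None else win[1] - win[0]
    widest = np.max(widths)
    cand = np.flatnonzero(widths >= widest - _tol(widest))
    return int(cand[np.argmax(np.abs(coeffs[cand]))])


# ---------------------------------------------------------------------------
# vectorised batch engine (used by the message-passing solver)

_PERM_TABLES: dict[int, np.ndarray] = {}


def _random_permutations(m: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, m) array of uniform random permutations of range(m).  Small m uses
    a cached lookup table of all m! orders; larger m falls back to argsort."""
    if m == 1:
        return np.zeros((n, 1), dtype=np.int64)
    if m <= 7:
        if m not in _PERM_TABLES:
            from itertools import permutations

            _PERM_TABLES[m] = np.array(list(permutations(range(m))), dtype=np.int64)
        table = _PERM_TABLES[m]
        return table[rng.integers(table.shape[0], size=n)]
    return np.argsort(rng.random((n, m)), axis=1)


def sample_many(
    constraint: LinearConstraint,
    pops: Sequence[WeightedPopulation],
    n_draws: int,
    rng: np.random.Generator,
    solved_index: int | str = "auto",
    density_bins: int = 50,
    counter: DrawCounter | None = None,
    targets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised repeated joint draws.  Returns (assignments, weights) with
    shapes (n_draws, n_vars) and (n_draws,).

    ``targets`` optionally overrides the constraint target per draw (an
    (n_draws,) array for equalities, (n_draws, 2) for intervals) — this is
    what the message-passing engine uses to shift the residual by the pinned
    flux value.  The solved variable in 'auto' mode is fixed for the whole
    batch as the largest-|coefficient| variable (declaration-order
    tie-break), so the sequential windows vectorise across draws.
    """
    coeffs = np.asarray(constraint.coefficients, dtype=float)
    n = coeffs.size
    if len(pops) != n:
        raise ValueError("one population per variable required")
    lo = np.array([p.lo for p in pops])
    hi = np.array([p.hi for p in pops])
    t_lo, t_hi = constraint.target_interval()
    if targets is None:
        r_lo = np.full(n_draws, t_lo)
        r_hi = np.full(n_draws, t_hi)
    else:
        targets = np.asarray(targets, dtype=float)
        if targets.ndim == 1:
            r_lo = targets.astype(float).copy()
            r_hi = r_lo.copy()
        else:
            r_lo = targets[:, 0].copy()
            r_hi = targets[:, 1].copy()

    if constraint.is_equality:
        if solved_index == "auto":
            solved = int(np.argmax(np.abs(coeffs)))
        else:
            solved = int(solved_index)
        free = np.array([k for k in range(n) if k != solved], dtype=int)
    else:
        solved = None
        free = np.arange(n, dtype=int)

    cmin = np.minimum(coeffs * lo, coeffs * hi)
    cmax = np.maximum(coeffs * lo, coeffs * hi)
    scale = _tol(*lo, *hi, float(np.max(np.abs(r_lo), initial=1.0)))

    assignment = np.full((n_draws, n), np.nan)
    weight = np.ones(n_draws)
    alive = np.ones(n_draws, dtype=bool)

    m = free.size
    if m:
        perms = _random_permutations(m, n_draws, rng)  # fresh order per draw
        # remaining-range trackers start with every variable (incl. solved)
        rem_lo = np.full(n_draws, cmin.sum())
        rem_hi = np.full(n_draws, cmax.sum())
        for j in range(m):
            pj = perms[:, j]
            v = free[pj]
            rem_lo -= cmin[v]
            rem_hi -= cmax[v]
            u = rng.random(n_draws)
            for pos_l, l in enumerate(free):
                idx = np.flatnonzero((pj == pos_l) & alive)
                if idx.size == 0:
                    continue
                pop = pops[l]
                c = coeffs[l]
                rl, rh = r_lo[idx], r_hi[idx]
                a, b = rem_lo[idx], rem_hi[idx]
                if c > 0:
                    w_lo, w_hi = (rl - b) / c, (rh - a) / c
                else:
                    w_lo, w_hi = (rh - a) / c, (rl - b) / c
                np.maximum(w_lo, pop.lo, out=w_lo)
                np.minimum(w_hi, pop.hi, out=w_hi)
                thin = (w_hi < w_lo) & (w_hi >= w_lo - scale)
                if thin.any():
                    mid = 0.5 * (w_lo + w_hi)
                    w_lo = np.where(thin, mid, w_lo)
                    w_hi = np.where(thin, mid, w_hi)
                i0, i1 = pop._index_window(w_lo, w_hi)
                mass = pop._cum[i1] - pop._cum[i0]
                ok = mass > 0
                uu = pop._cum[i0] + u[idx] * mass
                pos = np.clip(
                    np.searchsorted(pop._cum, uu, side="right") - 1, i0,
                    np.maximum(i1 - 1, i0),
                )
                # dead draws (empty window) may carry an out-of-range index
                np.clip(pos, 0, pop.values.size - 1, out=pos)
                vals = pop.values[pos]
                assignment[idx, l] = vals
                weight[idx] *= np.where(ok, mass / pop.total_weight, 0.0)
                alive[idx] = ok
                shift = c * np.where(ok, vals, 0.0)
                r_lo[idx] = rl - shift
                r_hi[idx] = rh - shift
            if counter is not None:
                counter.add(int(alive.sum()))
            if not alive.any():
                break

    if solved is not None:
        x = 0.5 * (r_lo + r_hi) / coeffs[solved]
        tol = _tol(lo[solved], hi[solved])
        inside = (x >= lo[solved] - tol) & (x <= hi[solved] + tol)
        alive &= inside
        x = np.clip(x, lo[solved], hi[solved])
        assignment[:, solved] = np.where(alive, x, np.nan)
        dens = pops[solved].density(np.where(alive, x, lo[solved]), bins=density_bins)
        weight *= np.where(alive, dens / abs(coeffs[solved]), 0.0)
        if counter is not None:
            counter.add(int(alive.sum()))
    weight = np.where(alive, weight, 0.0)
    if not np.all(np.isfinite(weight)):
        raise FloatingPointError("non-finite draw weight in batch")
    return assignment, weight
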