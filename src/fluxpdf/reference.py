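"""Closed-form and quadrature reference marginals for the test fixtures.

These are deliberately independent of the sampling machinery: closed-form
geometry (triangle, simplex/Irwin-Hall) and dense-grid transfer integration
for chain pathways.  They serve as oracles when checking that the weighted
belief-propagation and kernel hit-and-run estimates converge to the truth.
"""

from __future__ import annotations

from math import comb, factorial

import numpy as np

from .wbp_engine import MarginalEstimate

__all__ = [
    "triangle_density",
    "triangle_weight",
    "irwin_hall_pdf",
    "simplex_marginal",
    "chain_exact_marginals",
    "rejection_triangle_sample",
]


def triangle_density(x: np.ndarray) -> np.ndarray:
    """Density of x = 1 - y - z with y, z uniform on [0,1] and x >= 0: the
    area of the line segment {y + z = 1 - x} inside the unit square grows
    linearly, giving 2(1 - x) on [0, 1]."""
    x = np.asarray(x, dtype=float)
    return np.where((x >= 0) & (x <= 1), 2.0 * (1.0 - x), 0.0)


def triangle_weight(y: np.ndarray) -> np.ndarray:
    """Truncated mass of the uniform z-density on [0, 1-y]: w(y) = 1 - y."""
    y = np.asarray(y, dtype=float)
    return np.clip(1.0 - y, 0.0, 1.0)


def irwin_hall_pdf(s, n: int):
    """Density of the sum of n independent U(0,1) variables."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    inside = (s >= 0) & (s <= n)
    sv = s[inside]
    acc = np.zeros_like(sv)
    for k in range(n + 1):
        acc += (-1.0) ** k * comb(n, k) * np.where(sv >= k, (sv - k) ** (n - 1), 0.0)
    out[inside] = acc / factorial(n - 1)
    return out


def simplex_marginal(x, n: int, total: float = 1.0, bound: float = 1.0):
    """Exact marginal density of one coordinate of the uniform law on
    {sum_{i=1..n} x_i = total, 0 <= x_i <= bound}.  For total = bound = 1
    this is Beta(1, n-1): (n-1)(1-x)^(n-2)."""
    x = np.asarray(x, dtype=float)
    dens = irwin_hall_pdf((total - x) / bound, n - 1)
    dens = np.where((x >= 0) & (x <= bound), dens, 0.0)
    grid = np.linspace(0.0, bound, 4001)
    z = np.trapezoid(irwin_hall_pdf((total - grid) / bound, n - 1), grid)
    return dens / z


def chain_exact_marginals(
    length: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    window: float = 0.25,
    grid_n: int = 1201,
) -> list[MarginalEstimate]:
    """Exact flux marginals of the chain pathway by dense-grid transfer
    integration: constraints are x_{j-1} - x_j = gamma_j with gamma_j
    uniform on [-window, window], so forward/backward messages propagate
    through the boxcar kernel 1[|u - v| <= window]."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, grid_n)
    h = grid[1] - grid[0]
    kern = (np.abs(grid[:, None] - grid[None, :]) <= window).astype(float)
    w = np.full(grid_n, h)
    w[0] = w[-1] = h / 2  # trapezoid weights

    n = length + 1
    fwd = [np.ones(grid_n)]
    for _ in range(1, n):
        fwd.append(kern.T @ (w * fwd[-1]))
    bwd = [np.ones(grid_n)]
    for _ in range(1, n):
        bwd.append(kern @ (w * bwd[-1]))
    bwd = bwd[::-1]
    out = []
    for j in range(n):
        dens = fwd[j] * bwd[j]
        z = np.trapezoid(dens, grid)
        out.append(MarginalEstimate(f"r{j}", "flux", grid.copy(), dens / z, z))
    return out


def chain_exact_exchange(
    length: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    window: float = 0.25,
    grid_n: int = 1201,
) -> list[MarginalEstimate]:
    """Exact posteriors of the chain's exchange rates gamma_j = x_{j-1} -
    x_j by the same transfer integration: the joint law of the two fluxes
    around metabolite j is fwd_{j-1}(u) 1[|u-v| <= window] bwd_j(v)."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, grid_n)
    h = grid[1] - grid[0]
    kern = (np.abs(grid[:, None] - grid[None, :]) <= window).astype(float)
    w = np.full(grid_n, h)
    w[0] = w[-1] = h / 2

    n = length + 1
    fwd = [np.ones(grid_n)]
    for _ in range(1, n):
        fwd.append(kern.T @ (w * fwd[-1]))
    bwd = [np.ones(grid_n)]
    for _ in range(1, n):
        bwd.append(kern @ (w * bwd[-1]))
    bwd = bwd[::-1]
    ggrid = np.linspace(-window, window, 401)
    out = []
    for j in range(1, n):  # metabolite M_j sits between r_{j-1} and r_j
        dens = np.empty(ggrid.size)
        a = w * fwd[j - 1]
        for k, g in enumerate(ggrid):
            v = grid - g  # x_j = x_{j-1} - gamma
            inside = (v >= lo) & (v <= hi)
            bv = np.where(inside, np.interp(v, grid, bwd[j]), 0.0)
            dens[k] = np.sum(a * bv)
        z = np.trapezoid(dens, ggrid)
        out.append(MarginalEstimate(f"M{j}", "exchange", ggrid.copy(), dens / z, z))
    return out


def rejection_triangle_sample(
    n_draws: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Naive rejection oracle for the triangle toy: draw (y, z) uniform on
    the unit square, reject when 1 - y - z < 0.  Returns the accepted x
    values and the number of rejections."""
    y = rng.random(n_draws)
    z = rng.random(n_draws)
    x = 1.0 - y - z
    keep = x >= 0
    return x[keep], int(n_draws - keep.sum())
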