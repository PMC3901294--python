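"""Distances between marginal estimates and cross-method comparison.

Agreement between the message-passing estimate and the uniform sampler is
quantified with the total-variation distance (half the integrated absolute
density difference on a common grid) and the Kolmogorov-Smirnov distance
(max CDF gap); both live in [0, 1] and are zero iff the densities match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .wbp_engine import MarginalEstimate

__all__ = [
    "total_variation",
    "ks_distance",
    "support_overlap",
    "ComparisonReport",
    "compare",
    "write_marginals_tsv",
    "read_marginals_tsv",
]


def _union_grid(p: MarginalEstimate, q: MarginalEstimate) -> np.ndarray:
    g = np.union1d(p.grid, q.grid)
    # refine so interpolation error is negligible relative to either grid
    fine = np.linspace(g[0], g[-1], max(4 * g.size, 512))
    return np.union1d(g, fine)


def _on_grid(m: MarginalEstimate, grid: np.ndarray) -> np.ndarray:
    if m.point_mass:
        raise ValueError("point masses have no density representation")
    return np.interp(grid, m.grid, m.density, left=0.0, right=0.0)


def _supports_disjoint(p: MarginalEstimate, q: MarginalEstimate) -> bool:
    return p.grid[-1] < q.grid[0] or q.grid[-1] < p.grid[0]


def total_variation(p: MarginalEstimate, q: MarginalEstimate) -> float:
    """TV = 1/2 integral |p - q| on the union support (linear interpolation
    onto a common refined grid), clipped to [0, 1].  Disjoint supports give
    1 with a warning; point masses match only at the same location."""
    if p.point_mass or q.point_mass:
        if p.point_mass and q.point_mass:
            same = np.isclose(p.grid[0], q.grid[0], rtol=1e-9, atol=1e-12)
            return 0.0 if same else 1.0
        return 1.0
    if _supports_disjoint(p, q):
        warnings.warn("disjoint supports: total variation is 1")
        return 1.0
    grid = _union_grid(p, q)
    tv = 0.5 * np.trapezoid(np.abs(_on_grid(p, grid) - _on_grid(q, grid)), grid)
    return float(np.clip(tv, 0.0, 1.0))


def _cdf_on(m: MarginalEstimate, grid: np.ndarray) -> np.ndarray:
    if m.point_mass:
        return (grid >= m.grid[0] - 1e-15).astype(float)
    from scipy.integrate import cumulative_trapezoid

    cdf = np.concatenate(([0.0], cumulative_trapezoid(_on_grid(m, grid), grid)))
    if cdf[-1] > 0:
        cdf = cdf / cdf[-1]
    return cdf


def ks_distance(p: MarginalEstimate, q: MarginalEstimate) -> float:
    """Kolmogorov-Smirnov distance: max |P - Q| between the CDFs on the
    union grid."""
    if p.point_mass and q.point_mass:
        same = np.isclose(p.grid[0], q.grid[0], rtol=1e-9, atol=1e-12)
        return 0.0 if same else 1.0
    lo = min(p.grid[0], q.grid[0])
    hi = max(p.grid[-1], q.grid[-1])
    grid = np.union1d(
        np.union1d(p.grid, q.grid), np.linspace(lo, hi, max(512, 4 * p.grid.size))
    )
    return float(np.clip(np.abs(_cdf_on(p, grid) - _cdf_on(q, grid)).max(), 0.0, 1.0))


def support_overlap(p: MarginalEstimate, q: MarginalEstimate) -> float:
    """Length of the support intersection over the union (Jaccard)."""
    a0, a1 = p.grid[0], p.grid[-1]
    b0, b1 = q.grid[0], q.grid[-1]
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = max(a1, b1) - min(a0, b0)
    if union <= 0:
        return 1.0 if np.isclose(a0, b0) else 0.0
    return float(inter / union)


@dataclass
class ComparisonReport:
    rows: pd.DataFrame  # id, kind, tv, ks, support_overlap
    max_tv: float
    mean_tv: float
    missing_in_a: list[str]
    missing_in_b: list[str]

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def compare(
    a: list[MarginalEstimate], b: list[MarginalEstimate]
) -> ComparisonReport:
    """Row per shared variable id with TV, KS and support overlap; ids
    present on one side only are listed explicitly."""
    da = {m.variable_id: m for m in a}
    db = {m.variable_id: m for m in b}
    shared = [k for k in da if k in db]
    rows = []
    for k in shared:
        rows.append(
            {
                "id": k,
                "kind": da[k].kind,
                "tv": total_variation(da[k], db[k]),
                "ks": ks_distance(da[k], db[k]),
                "support_overlap": support_overlap(da[k], db[k]),
            }
        )
    df = pd.DataFrame(rows, columns=["id", "kind", "tv", "ks", "support_overlap"])
    tvs = df["tv"].to_numpy(dtype=float)
    return ComparisonReport(
        rows=df,
        max_tv=float(np.max(tvs)) if tvs.size else float("nan"),
        mean_tv=float(np.mean(tvs)) if tvs.size else float("nan"),
        missing_in_a=[k for k in db if k not in da],
        missing_in_b=[k for k in da if k not in db],
    )


# ---------------------------------------------------------------------------
# marginal TSV IO (shared by the wbp/khr/compare commands)


def write_marginals_tsv(marginals: list[MarginalEstimate], path: str | Path) -> None:
    recs = []
    for m in marginals:
        for g, d in zip(np.atleast_1d(m.grid), np.atleast_1d(m.density)):
            recs.append((m.variable_id, m.kind, g, d))
    pd.DataFrame(
        recs, columns=["variable_id", "kind", "grid_value", "density"]
    ).to_csv(path, sep="\t", index=False)


def read_marginals_tsv(path: str | Path) -> list[MarginalEstimate]:
    df = pd.read_csv(path, sep="\t", dtype={"variable_id": str, "kind": str})
    out = []
    for (vid, kind), grp in df.groupby(["variable_id", "kind"], sort=False):
        grid = grp["grid_value"].to_numpy(dtype=float)
        dens = grp["density"].to_numpy(dtype=float)
        order = np.argsort(grid)
        out.append(
            MarginalEstimate(
                vid, kind, grid[order], dens[order], 1.0, point_mass=grid.size == 1
            )
        )
    return out
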