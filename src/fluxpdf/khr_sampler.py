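"""Kernel Hit-and-Run: uniform sampling of the flux polytope after
null-space reduction.

The internal mass-balance equalities ``S_int x = 0`` confine the flux vector
to the null space of the internal stoichiometry; with an orthonormal basis
``Phi`` (N x K, from SVD) every feasible flux is ``x = x_p + Phi y`` with
``y`` in a K-dimensional polytope cut out by the flux boxes and the
exchange-rate windows (rows of the projected matrix ``Psi``).  ``x_p`` is a
particular solution, nonzero only when some exchange rate is pinned to a
fixed nonzero value (those equalities are folded into the null-space step so
the projected polytope stays full-dimensional).  K is typically far smaller
than N — the hit-and-run chain, whose mixing time grows like the cube of
the dimension, therefore runs in K dimensions and the recorded points are
lifted back linearly, which preserves the uniform measure.

No artificial enclosing box is ever added: the finite flux bounds already
make the polytope bounded, and boundedness is certified at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

from .network_model import MetabolicNetwork, internal_submatrix, stoichiometric_matrix
from .wbp_engine import MarginalEstimate

__all__ = [
    "NullSpaceModel",
    "ProjectedPolytope",
    "ChainConfig",
    "KHRSamples",
    "PolytopeError",
    "null_space_basis",
    "project_constraints",
    "find_interior_point",
    "hit_and_run_step",
    "sample",
    "marginals_from_samples",
]


class PolytopeError(RuntimeError):
    """Infeasible, unbounded, or degenerate polytope."""


@dataclass
class NullSpaceModel:
    """Orthonormal basis of the null space of the internal stoichiometry."""

    basis: np.ndarray  # (N, K), orthonormal columns
    K: int
    rank: int
    tol_rel: float

    @property
    def is_point(self) -> bool:
        return self.K == 0


def null_space_basis(s_int: np.ndarray, tol_rel: float = 1e-10) -> NullSpaceModel:
    """SVD null space: rank counts singular values above tol_rel times the
    largest; K = N - rank.  A 0-row matrix has the full space as kernel."""
    s_int = np.asarray(s_int, dtype=float)
    if s_int.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n = s_int.shape[1]
    if s_int.shape[0] == 0 or not np.any(s_int):
        return NullSpaceModel(np.eye(n), n, 0, tol_rel)
    _, sv, vt = linalg.svd(s_int, full_matrices=True)
    rank = int(np.sum(sv > tol_rel * sv[0]))
    basis = vt[rank:].T
    return NullSpaceModel(basis, n - rank, rank, tol_rel)


@dataclass
class ProjectedPolytope:
    """{y : lo <= Psi y <= hi}; lifting is x = offset + basis @ y."""

    psi: np.ndarray  # (rows, K)
    lo: np.ndarray
    hi: np.ndarray
    basis: np.ndarray  # (N, K)
    offset: np.ndarray  # (N,) particular solution of the equality system
    row_labels: list[str] = field(default_factory=list)
    # set when the inequalities pin y to a single point (implicit equalities)
    point_solution: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.psi.shape[1]

    @property
    def scale(self) -> float:
        return float(max(1.0, np.abs(self.lo).max(), np.abs(self.hi).max()))

    def slacks(self, y: np.ndarray) -> np.ndarray:
        p = self.psi @ y
        return np.minimum(p - self.lo, self.hi - p)

    def contains(self, y: np.ndarray, tol: float | None = None) -> bool:
        tol = 1e-9 * self.scale if tol is None else tol
        return bool(self.slacks(y).min() >= -tol)

    def lift(self, y: np.ndarray) -> np.ndarray:
        return self.offset + y @ self.basis.T if y.ndim == 2 else self.offset + self.basis @ y


def project_constraints(
    net: MetabolicNetwork, nsm: NullSpaceModel | None = None
) -> ProjectedPolytope:
    """Project every flux box and exchange window into null-space
    coordinates.  Fixed nonzero exchange rates AND pinned fluxes (lb == ub)
    are appended to the equality system before the null-space step (affine
    offset via least squares), so they never appear as zero-width inequality
    rows and the projected polytope stays full-dimensional.  Boundedness of
    the result is certified by maximising each +/- coordinate of y with an
    LP."""
    net.require_valid()
    full = stoichiometric_matrix(net)
    lb, ub = net.bounds()
    n = net.n_reactions

    eq_rows, eq_rhs = [], []
    for mu, met in enumerate(net.metabolites):
        if met.prior.kind == "internal":
            eq_rows.append(full[mu])
            eq_rhs.append(0.0)
        elif met.prior.kind == "fixed":
            eq_rows.append(full[mu])
            eq_rhs.append(float(met.prior.z0))
    pinned = [i for i, r in enumerate(net.reactions) if r.lb == r.ub]
    for i in pinned:
        row = np.zeros(n)
        row[i] = 1.0
        eq_rows.append(row)
        eq_rhs.append(net.reactions[i].lb)
    has_fixed = any(m.prior.kind == "fixed" for m in net.metabolites) or bool(pinned)
    if nsm is None or has_fixed:
        a_eq = np.array(eq_rows) if eq_rows else np.zeros((0, n))
        nsm = null_space_basis(a_eq)
        if eq_rows:
            b = np.array(eq_rhs)
            x_p, *_ = np.linalg.lstsq(a_eq, b, rcond=None)
            if np.linalg.norm(a_eq @ x_p - b) > 1e-8 * max(
                1.0, float(np.abs(b).max())
            ):
                raise PolytopeError("inconsistent fixed exchange-rate equalities")
        else:
            x_p = np.zeros(n)
    else:
        x_p = np.zeros(n)

    psi_rows, los, his, labels = [], [], [], []
    for i, r in enumerate(net.reactions):
        if r.lb == r.ub:
            continue  # pinned flux: already an equality row
        psi_rows.append(nsm.basis[i, :])
        los.append(r.lb - x_p[i])
        his.append(r.ub - x_p[i])
        labels.append(f"flux:{r.id}")
    for mu, met in enumerate(net.metabolites):
        if met.prior.kind == "uniform":
            psi_rows.append(full[mu] @ nsm.basis)
            shift = float(full[mu] @ x_p)
            los.append(met.prior.lb - shift)
            his.append(met.prior.ub - shift)
            labels.append(f"exchange:{met.id}")

    poly = ProjectedPolytope(
        psi=np.array(psi_rows) if psi_rows else np.zeros((0, nsm.K)),
        lo=np.array(los),
        hi=np.array(his),
        basis=nsm.basis,
        offset=x_p,
        row_labels=labels,
    )
    if poly.K > 0:
        _certify_bounded(poly)
    return poly


def _certify_bounded(poly: ProjectedPolytope) -> None:
    """LP certification of boundedness; also detects the degenerate case of
    inequalities pinning every coordinate (a point polytope)."""
    a_ub = np.vstack([poly.psi, -poly.psi])
    b_ub = np.concatenate([poly.hi, -poly.lo])
    extremes = np.empty((poly.K, 2))
    for k in range(poly.K):
        for col, sign in enumerate((1.0, -1.0)):
            c = np.zeros(poly.K)
            c[k] = -sign
            res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=[(None, None)] * poly.K)
            if res.status == 3:
                raise PolytopeError(
                    f"polytope unbounded along {'+' if sign > 0 else '-'}y[{k}]"
                )
            if res.status == 2:
                raise PolytopeError("projected polytope is infeasible")
            extremes[k, col] = res.x[k]
    spans = np.abs(extremes[:, 0] - extremes[:, 1])
    if np.all(spans <= 1e-9 * poly.scale):
        poly.point_solution = extremes.mean(axis=1)


def find_interior_point(
    poly: ProjectedPolytope,
    method: str = "minover",
    max_iter: int = 50_000,
) -> np.ndarray:
    """Strictly interior point of the projected polytope.

    'minover': perceptron-style relaxation stepping along the inward normal
    of the currently worst (smallest-slack) row with a decreasing step
    schedule, followed by extra centering steps once feasible.  'chebyshev':
    center of the largest inscribed ball via linear programming."""
    if poly.K == 0:
        return np.zeros(0)
    eps = 1e-9 * poly.scale
    norms = np.linalg.norm(poly.psi, axis=1)
    norms[norms == 0] = 1.0

    if method == "chebyshev":
        a_ub = np.vstack([poly.psi, -poly.psi])
        b_ub = np.concatenate([poly.hi, -poly.lo])
        r_col = np.concatenate([norms, norms])[:, None]
        a = np.hstack([a_ub, r_col])
        c = np.zeros(poly.K + 1)
        c[-1] = -1.0
        res = linprog(
            c, A_ub=a, b_ub=b_ub, bounds=[(None, None)] * poly.K + [(0, None)]
        )
        if not res.success or res.x[-1] <= eps:
            raise PolytopeError(
                f"no strictly interior point (chebyshev radius "
                f"{res.x[-1] if res.success else 'n/a'})"
            )
        return res.x[:-1]

    if method != "minover":
        raise ValueError(f"unknown method {method!r}")
    y = np.zeros(poly.K)
    eta0 = poly.scale
    tau = 1e3
    best = -np.inf
    feasible_since = None
    for t in range(max_iter):
        p = poly.psi @ y
        slack = np.minimum(p - poly.lo, poly.hi - p) / norms
        j = int(np.argmin(slack))
        best = max(best, float(slack.min()))
        if slack[j] > eps:
            if feasible_since is None:
                feasible_since = t
            if t - feasible_since >= 100:  # extra centering steps
                return y
        else:
            feasible_since = None
        inward = poly.psi[j] / norms[j]
        if p[j] - poly.lo[j] > poly.hi[j] - p[j]:
            inward = -inward
        eta = eta0 / (1.0 + t / tau)
        if feasible_since is not None:
            eta = min(eta, 0.25 * slack[j])
        y = y + eta * inward
    if feasible_since is not None and poly.slacks(y).min() > eps:
        return y
    raise PolytopeError(
        f"minover failed after {max_iter} iterations (best slack {best:.3e})"
    )


# ---------------------------------------------------------------------------
# chain steps


def _chord(poly: ProjectedPolytope, p: np.ndarray, q: np.ndarray) -> tuple:
    """Chord parameter interval for positions p = Psi y and derivatives
    q = Psi d, batched over leading axes."""
    tiny = 1e-13 * max(1.0, float(np.abs(poly.psi).max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (poly.lo - p) / q
        t2 = (poly.hi - p) / q
    mask = np.abs(q) <= tiny
    t_lo = np.where(q > 0, t1, t2)
    t_hi = np.where(q > 0, t2, t1)
    t_lo = np.where(mask, -np.inf, t_lo)
    t_hi = np.where(mask, np.inf, t_hi)
    return t_lo.max(axis=-1), t_hi.min(axis=-1)


def hit_and_run_step(
    poly: ProjectedPolytope, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One hit-and-run move: isotropic random direction, uniform point on
    the feasible chord through y."""
    d = rng.standard_normal(poly.K)
    d /= np.linalg.norm(d)
    t_lo, t_hi = _chord(poly, poly.psi @ y, poly.psi @ d)
    if not (np.isfinite(t_lo) and np.isfinite(t_hi)) or t_hi < t_lo:
        raise PolytopeError("non-finite or empty chord: point outside polytope?")
    t = t_lo + rng.uniform(1e-12, 1.0 - 1e-12) * (t_hi - t_lo)
    return y + t * d


def _steps_batch(
    poly: ProjectedPolytope, ys: np.ndarray, rng: np.random.Generator, n_steps: int
) -> np.ndarray:
    """Advance a batch of chains (rows of ys) n_steps moves, vectorised."""
    c = ys.shape[0]
    for _ in range(n_steps):
        d = rng.standard_normal((c, poly.K))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        t_lo, t_hi = _chord(poly, ys @ poly.psi.T, d @ poly.psi.T)
        if not np.all(np.isfinite(t_lo)) or not np.all(np.isfinite(t_hi)):
            raise PolytopeError("non-finite chord during sampling")
        u = rng.uniform(1e-12, 1.0 - 1e-12, size=c)
        ys = ys + (t_lo + u * (t_hi - t_lo))[:, None] * d
    return ys


@dataclass
class ChainConfig:
    """Sampling protocol: total recorded samples, discarded initial steps,
    thinning interval (None = 10*K), independent chains averaged over
    initial conditions, and the interior-point initialiser."""

    n_samples: int = 10_000
    burn_in: int = 10_000
    thin: int | None = None
    n_chains: int = 3
    seed: int = 0
    init: str = "minover"

    def validate(self) -> None:
        if min(self.n_samples, self.burn_in, self.n_chains) < 1 or (
            self.thin is not None and self.thin < 1
        ):
            raise ValueError("all chain parameters must be positive")


@dataclass
class KHRSamples:
    """Uniform flux samples with provenance."""

    fluxes: np.ndarray  # (n, N)
    chain: np.ndarray  # (n,)
    step: np.ndarray  # (n,) chain step index at recording time
    reaction_ids: list[str]


def sample(net: MetabolicNetwork, config: ChainConfig | None = None) -> KHRSamples:
    """Full pipeline: null-space basis -> projected polytope -> interior
    point per chain -> burn-in -> thinned recording -> lift to flux space.
    Every returned flux vector satisfies the internal balances and all
    box/window constraints to tight tolerance."""
    config = config or ChainConfig()
    config.validate()
    net.require_valid()
    s_int = internal_submatrix(net)
    nsm = null_space_basis(s_int)
    poly = project_constraints(net, nsm)

    if poly.K == 0 or poly.point_solution is not None:
        x = poly.offset if poly.K == 0 else poly.lift(poly.point_solution)
        if not _check_fluxes(net, s_int, x[None, :]):
            raise PolytopeError("point polytope violates the box constraints")
        warnings.warn("polytope is a single point: returning the unique solution")
        return KHRSamples(
            x[None, :], np.zeros(1, int), np.zeros(1, int), net.reaction_ids
        )

    rng = np.random.default_rng(config.seed)
    thin = config.thin if config.thin is not None else 10 * poly.K
    y0 = find_interior_point(poly, method=config.init)
    chains = config.n_chains
    per_chain = -(-config.n_samples // chains)
    ys = np.tile(y0, (chains, 1))
    ys = _steps_batch(poly, ys, rng, config.burn_in)
    recs, chain_ids, steps = [], [], []
    for s in range(per_chain):
        ys = _steps_batch(poly, ys, rng, thin)
        recs.append(ys.copy())
        chain_ids.append(np.arange(chains))
        steps.append(np.full(chains, config.burn_in + (s + 1) * thin))
    y_all = np.concatenate(recs)[: config.n_samples]
    chain_all = np.concatenate(chain_ids)[: config.n_samples]
    step_all = np.concatenate(steps)[: config.n_samples]
    x_all = poly.lift(y_all)
    if not _check_fluxes(net, s_int, x_all):
        raise PolytopeError("emitted samples violate constraints")
    return KHRSamples(x_all, chain_all, step_all, net.reaction_ids)


def _check_fluxes(net: MetabolicNetwork, s_int: np.ndarray, x: np.ndarray) -> bool:
    scale = max(1.0, float(np.abs(s_int).max()) if s_int.size else 1.0)
    if s_int.size and np.abs(s_int @ x.T).max() > 1e-8 * scale:
        return False
    lb, ub = net.bounds()
    btol = 1e-9 * max(1.0, float(np.abs(lb).max()), float(np.abs(ub).max()))
    if (x < lb - btol).any() or (x > ub + btol).any():
        return False
    full = stoichiometric_matrix(net)
    for mu, met in enumerate(net.metabolites):
        g = full[mu] @ x.T
        if met.prior.kind == "uniform":
            wtol = 1e-9 * max(1.0, abs(met.prior.lb), abs(met.prior.ub))
            if (g < met.prior.lb - wtol).any() or (g > met.prior.ub + wtol).any():
                return False
        elif met.prior.kind == "fixed":
            if np.abs(g - met.prior.z0).max() > 1e-8 * max(1.0, abs(met.prior.z0)):
                return False
    return True


def marginals_from_samples(
    samples: KHRSamples | np.ndarray,
    bins: int = 50,
    reaction_ids: list[str] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[MarginalEstimate]:
    """Per-flux normalised histogram densities over the observed (or
    declared) support.  A flux that never varies becomes a point mass."""
    if isinstance(samples, KHRSamples):
        x = samples.fluxes
        ids = samples.reaction_ids
    else:
        x = np.asarray(samples, dtype=float)
        ids = reaction_ids or [f"x{k}" for k in range(x.shape[1])]
    if x.shape[0] < 2:
        return [
            MarginalEstimate(
                ids[k], "flux", x[:1, k].copy(), np.array([1.0]), 1.0, point_mass=True
            )
            for k in range(x.shape[1])
        ]
    out = []
    for k, rid in enumerate(ids):
        col = x[:, k]
        if bounds is not None:
            lo, hi = float(bounds[0][k]), float(bounds[1][k])
        else:
            lo, hi = float(col.min()), float(col.max())
        span = hi - lo
        if span <= 1e-12 * max(1.0, abs(hi), abs(lo)):
            out.append(
                MarginalEstimate(
                    rid, "flux", np.array([0.5 * (lo + hi)]), np.array([1.0]),
                    1.0, point_mass=True,
                )
            )
            continue
        hist, edges = np.histogram(col, bins=bins, range=(lo, hi))
        dens = hist / (col.size * (edges[1] - edges[0]))
        grid, dens = _pad_histogram(edges, dens)
        z = float(np.trapezoid(dens, grid))
        out.append(MarginalEstimate(rid, "flux", grid, dens / z, z))
    return out


def _pad_histogram(edges: np.ndarray, dens: np.ndarray):
    """Bin centers padded with the support endpoints, so the trapezoid
    integral of the returned polyline equals the histogram mass exactly and
    no edge mass is lost when interpolating onto other grids."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    grid = np.concatenate(([edges[0]], centers, [edges[-1]]))
    vals = np.concatenate(([dens[0]], dens, [dens[-1]]))
    return grid, vals
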