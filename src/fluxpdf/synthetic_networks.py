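"""Synthetic constraint-based network instances.

Two families: random sparse bipartite networks (for cost-scaling and
cross-method agreement studies, with M = N/2 metabolites by default), and
tiny fixtures whose flux marginals are known in closed form or by
low-dimensional quadrature (stars = scaled simplices, chains = linear
pathways with exchange windows, and the two-uniform triangle toy for the
rejection-free integration primitive).

Every generated network is validated, and random instances are certified
feasible with nonempty interior (Chebyshev radius of the projected polytope
strictly positive) and full-row-rank internal stoichiometry, regenerating up
to a retry cap otherwise.  Boundedness comes for free: all flux bounds are
finite boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constrained_sampling import LinearConstraint, WeightedPopulation
from .network_model import (
    ExchangePrior,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    internal_submatrix,
)

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "random_network",
    "star_network",
    "chain_network",
    "toy_triangle",
    "hrbc_shaped_network",
]


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """Ensemble parameters for random bipartite instances.

    ``mean_degree`` is the mean number of reactions per metabolite
    (realised as 2 + Poisson(mean_degree - 2), so every constraint couples
    at least two fluxes).  ``coefficient_law``: 'unit' gives signed +/-1
    stoichiometry, 'uniform' signed magnitudes on (0.1, 2).  Flux bounds are
    [0, u] with u = 10**Uniform(-bound_spread, bound_spread), so
    ``bound_spread`` > 0 spreads the boxes over orders of magnitude.  A
    fraction of metabolites is exchanged with the environment through a
    uniform window on the exchange rate, which is also what keeps the
    projected polytope comfortably full-dimensional."""

    N: int
    M: int | None = None
    mean_degree: float = 3.0
    coefficient_law: Literal["unit", "uniform"] = "unit"
    bound_spread: float = 0.0
    exchanged_fraction: float = 0.25
    exchange_window: float = 0.5
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.M is None:
            self.M = self.N // 2
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 1 <= self.M < self.N:
            raise ValueError("need 1 <= M < N")
        if self.mean_degree < 2:
            raise ValueError("mean_degree must be >= 2")


def _draw_instance(cfg: GeneratorConfig, rng: np.random.Generator) -> MetabolicNetwork:
    N, M = cfg.N, cfg.M
    degrees = 2 + rng.poisson(cfg.mean_degree - 2.0, size=M)
    degrees = np.minimum(degrees, N)
    triples: list[tuple[str, str, float]] = []
    touched = np.zeros(N, dtype=bool)
    membership: list[np.ndarray] = []
    for mu in range(M):
        members = rng.choice(N, size=degrees[mu], replace=False)
        membership.append(members)
        touched[members] = True
    # repair orphan reactions by swapping them into existing membership
    # slots (replacing a reaction that appears elsewhere), so metabolite
    # degrees — and hence the ensemble's mean degree — are preserved
    rxn_count = np.zeros(N, dtype=int)
    for members in membership:
        rxn_count[members] += 1
    for i in np.flatnonzero(~touched):
        order = rng.permutation(M)
        done = False
        for mu in order:
            members = membership[mu]
            swappable = np.flatnonzero(rxn_count[members] >= 2)
            if swappable.size:
                k = int(rng.choice(swappable))
                rxn_count[members[k]] -= 1
                members[k] = i
                rxn_count[i] += 1
                done = True
                break
        if not done:  # no slot to steal: fall back to adding an edge
            mu = int(rng.integers(M))
            membership[mu] = np.append(membership[mu], i)
            rxn_count[i] += 1
    for mu in range(M):
        members = membership[mu]
        if cfg.coefficient_law == "unit":
            mags = np.ones(members.size)
        else:
            mags = rng.uniform(0.1, 2.0, size=members.size)
        signs = rng.choice([-1.0, 1.0], size=members.size)
        # a balanced internal constraint needs both a producer and a consumer
        if np.all(signs > 0):
            signs[rng.integers(signs.size)] = -1.0
        elif np.all(signs < 0):
            signs[rng.integers(signs.size)] = 1.0
        for i, s, g in zip(members, signs, mags):
            triples.append((f"m{mu}", f"r{int(i)}", float(s * g)))

    ubs = 10.0 ** rng.uniform(-cfg.bound_spread, cfg.bound_spread, size=N)
    reactions = [Reaction(f"r{i}", 0.0, float(ubs[i])) for i in range(N)]
    n_ex = int(round(cfg.exchanged_fraction * M))
    exchanged = set(rng.choice(M, size=n_ex, replace=False).tolist()) if n_ex else set()
    mets = []
    for mu in range(M):
        if mu in exchanged:
            w = cfg.exchange_window
            prior = ExchangePrior("uniform", lb=-w, ub=w)
        else:
            prior = ExchangePrior()
        mets.append(Metabolite(f"m{mu}", prior))
    return MetabolicNetwork(reactions, mets, triples)


def random_network(cfg: GeneratorConfig) -> MetabolicNetwork:
    """Random sparse bipartite instance; deterministic given cfg.seed.
    Retries until the internal stoichiometry has full row rank and the
    projected polytope has a strictly interior point."""
    from .khr_sampler import find_interior_point, null_space_basis, project_constraints

    rng = np.random.default_rng(cfg.seed)
    last_err = "no attempt"
    for _ in range(cfg.max_retries):
        net = _draw_instance(cfg, rng)
        if net.require_valid() is None:  # pragma: no cover
            continue
        s_int = internal_submatrix(net)
        nsm = null_space_basis(s_int)
        if s_int.shape[0] and nsm.rank < s_int.shape[0]:
            last_err = "rank-deficient internal stoichiometry"
            continue
        if nsm.K == 0:
            last_err = "point polytope"
            continue
        try:
            poly = project_constraints(net, nsm)
            find_interior_point(poly, method="chebyshev")
        except Exception as e:  # infeasible or empty interior
            last_err = str(e)
            continue
        return net
    raise GenerationError(
        f"could not generate a feasible full-rank instance "
        f"(N={cfg.N}, M={cfg.M}, seed={cfg.seed}): {last_err}"
    )


def star_network(
    n: int, total: float = 1.0, bounds: tuple[float, float] = (0.0, 1.0)
) -> MetabolicNetwork:
    """One internal metabolite fed by n unit-coefficient reactions and
    drained by one pinned exchange reaction of magnitude ``total``: the flux
    polytope is the scaled (n-1)-simplex, whose marginals are Beta laws."""
    if n < 2:
        raise ValueError("need n >= 2 producers")
    lo, hi = bounds
    if not (n * lo <= total <= n * hi):
        raise ValueError(f"total {total} unreachable with {n} fluxes in {bounds}")
    reactions = [Reaction(f"v{i+1}", lo, hi) for i in range(n)]
    reactions.append(Reaction("out", total, total))
    triples = [("A", f"v{i+1}", 1.0) for i in range(n)] + [("A", "out", -1.0)]
    return MetabolicNetwork(reactions, [Metabolite("A")], triples).require_valid()


def chain_network(
    length: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    window: float = 0.25,
) -> MetabolicNetwork:
    """Linear pathway r0 -> M1 -> r1 -> M2 -> ... -> r_length with every
    intermediate metabolite exchanged through a uniform window [-window,
    window] on its exchange rate.  Exact marginals follow from dense-grid
    transfer integration, so chains are the smallest loopless fixtures with
    more than one coupled constraint."""
    if length < 2:
        raise ValueError("length must be >= 2")
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = bounds
    reactions = [Reaction(f"r{j}", lo, hi) for j in range(length + 1)]
    mets = [
        Metabolite(f"M{j}", ExchangePrior("uniform", lb=-window, ub=window))
        for j in range(1, length + 1)
    ]
    triples = []
    for j in range(1, length + 1):
        triples.append((f"M{j}", f"r{j-1}", 1.0))
        triples.append((f"M{j}", f"r{j}", -1.0))
    return MetabolicNetwork(reactions, mets, triples).require_valid()


def toy_triangle(q: int = 500) -> tuple[LinearConstraint, list[WeightedPopulation]]:
    """The two-uniform toy: y, z uniform on [0, 1] and x = 1 - y - z with
    x >= 0.  Feasible (y, z) form the lower triangle of the unit square, so
    the density of x is 2(1 - x) and the reweighting factor after fixing y
    is w(y) = 1 - y.  Returns the constraint y + z + x = 1 with uniform
    populations (solve for index 2, the x variable)."""
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, q)
    con = LinearConstraint(("y", "z", "x"), (1.0, 1.0, 1.0), 1.0)
    return con, [pop, pop, pop]


def hrbc_shaped_network(seed: int = 0) -> MetabolicNetwork:
    """Synthetic instance with the shape of the human red-blood-cell
    network: 34 internal metabolites constraining 46 reactions, full row
    rank, hence a 12-dimensional flux polytope.  The stoichiometry itself is
    random (the real network's coefficients are not bundled); only the shape
    and rank structure are emulated."""
    return random_network(
        GeneratorConfig(N=46, M=34, exchanged_fraction=0.0, seed=seed)
    )
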