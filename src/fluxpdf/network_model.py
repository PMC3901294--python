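"""Constraint-based metabolic network instances.

A network is a bipartite system of N reactions (variables) and M metabolites
(linear mass-balance constraints).  Each reaction ``i`` carries a flux
``x_i`` confined to a box ``[m_i, M_i]``; each metabolite ``mu`` imposes

    sum_i  xi_{i,mu} x_i = gamma_mu

where ``xi`` are signed stoichiometric coefficients (negative = substrate,
positive = product) and ``gamma_mu`` is the net exchange rate of the species
with the environment: exactly zero for internal metabolites, a fixed value,
or a random rate with a uniform prior on a window for exchanged species.
Reversibility is encoded purely through the bounds (``m_i < 0`` allows
reverse flux); flux units are opaque.

The stoichiometric matrix is oriented metabolites x reactions (rows are
constraints), which is the orientation consumed by the null-space reduction
and by the message-passing engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ExchangePrior",
    "Reaction",
    "Metabolite",
    "MetabolicNetwork",
    "NetworkValidationError",
    "Violation",
    "load_network",
    "save_network",
    "stoichiometric_matrix",
    "internal_submatrix",
    "validate",
]

PriorKind = Literal["internal", "fixed", "uniform"]


class NetworkValidationError(ValueError):
    """Raised when a network instance violates a structural invariant."""


@dataclass(frozen=True)
class ExchangePrior:
    """Prior on a metabolite's exchange rate gamma.

    kind='internal'  -> gamma = 0 exactly (pure mass balance)
    kind='fixed'     -> gamma = z0 exactly
    kind='uniform'   -> gamma uniform on [lb, ub], lb < ub
    """

    kind: PriorKind = "internal"
    z0: float | None = None
    lb: float | None = None
    ub: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "internal":
            if self.z0 is not None or self.lb is not None or self.ub is not None:
                raise NetworkValidationError("internal prior takes no parameters")
        elif self.kind == "fixed":
            if self.z0 is None or not np.isfinite(self.z0):
                raise NetworkValidationError("fixed prior requires finite z0")
        elif self.kind == "uniform":
            if self.lb is None or self.ub is None:
                raise NetworkValidationError("uniform prior requires lb and ub")
            if not (np.isfinite(self.lb) and np.isfinite(self.ub)):
                raise NetworkValidationError("uniform prior bounds must be finite")
            if not self.lb < self.ub:
                raise NetworkValidationError(
                    f"uniform prior requires lb < ub, got [{self.lb}, {self.ub}]"
                )
        else:  # pragma: no cover - guarded by Literal typing
            raise NetworkValidationError(f"unknown prior kind {self.kind!r}")

    @property
    def is_internal(self) -> bool:
        return self.kind == "internal"


@dataclass(frozen=True)
class Reaction:
    id: str
    lb: float
    ub: float


@dataclass(frozen=True)
class Metabolite:
    id: str
    prior: ExchangePrior = field(default_factory=ExchangePrior)


@dataclass(frozen=True)
class Violation:
    rule: str
    offender: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.offender}: {self.message}"


@dataclass
class MetabolicNetwork:
    """Reactions with flux bounds, metabolites with exchange priors, and a
    signed sparse stoichiometry given as (metabolite_id, reaction_id, coeff)
    triples.  Declaration order of reactions and metabolites is meaningful
    and preserved through IO round trips."""

    reactions: list[Reaction]
    metabolites: list[Metabolite]
    stoichiometry: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        self.reactions = [
            r if isinstance(r, Reaction) else Reaction(*r) for r in self.reactions
        ]
        mets = []
        for m in self.metabolites:
            if isinstance(m, Metabolite):
                mets.append(m)
            else:
                mid, prior = m
                mets.append(Metabolite(mid, prior))
        self.metabolites = mets
        self.stoichiometry = [
            (str(m), str(r), float(c)) for (m, r, c) in self.stoichiometry
        ]

    # -- indexing helpers -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_index(self) -> dict[str, int]:
        return {r.id: k for k, r in enumerate(self.reactions)}

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: k for k, m in enumerate(self.metabolites)}

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def require_valid(self) -> "MetabolicNetwork":
        problems = validate(self)
        if problems:
            raise NetworkValidationError("; ".join(str(v) for v in problems))
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.reactions == other.reactions
            and self.metabolites == other.metabolites
            and sorted(self.stoichiometry) == sorted(other.stoichiometry)
        )


# ---------------------------------------------------------------------------
# validation


def validate(net: MetabolicNetwork) -> list[Violation]:
    """Check every structural invariant; return a (possibly empty) list of
    violations.  Never raises: this is the reporting entry point."""
    out: list[Violation] = []
    rids = net.reaction_ids
    mids = net.metabolite_ids

    seen: set[str] = set()
    for rid in rids:
        if rid in seen:
            out.append(Violation("duplicate-reaction-id", rid, "declared twice"))
        seen.add(rid)
    seen = set()
    for mid in mids:
        if mid in seen:
            out.append(Violation("duplicate-metabolite-id", mid, "declared twice"))
        seen.add(mid)

    for r in net.reactions:
        if not (np.isfinite(r.lb) and np.isfinite(r.ub)):
            out.append(Violation("non-finite-bounds", r.id, f"[{r.lb}, {r.ub}]"))
        elif r.lb > r.ub:
            out.append(
                Violation("bounds-order", r.id, f"lower {r.lb} > upper {r.ub}")
            )

    rset, mset = set(rids), set(mids)
    pairs: set[tuple[str, str]] = set()
    touched_r: set[str] = set()
    touched_m: set[str] = set()
    for mid, rid, coeff in net.stoichiometry:
        if mid not in mset:
            out.append(Violation("dangling-metabolite", mid, "not declared"))
        if rid not in rset:
            out.append(Violation("dangling-reaction", rid, "not declared"))
        if (mid, rid) in pairs:
            out.append(
                Violation("duplicate-entry", f"{mid}/{rid}", "repeated triple")
            )
        pairs.add((mid, rid))
        if not np.isfinite(coeff) or coeff == 0.0:
            out.append(
                Violation("bad-coefficient", f"{mid}/{rid}", f"coefficient {coeff}")
            )
        touched_m.add(mid)
        touched_r.add(rid)

    for rid in rset - touched_r:
        out.append(Violation("isolated-reaction", rid, "touches no metabolite"))
    for mid in mset - touched_m:
        out.append(Violation("isolated-metabolite", mid, "no reaction processes it"))
    return out


# ---------------------------------------------------------------------------
# matrices


def stoichiometric_matrix(
    net: MetabolicNetwork, sparse_format: bool = False
) -> np.ndarray | sparse.csr_matrix:
    """Signed stoichiometric matrix, shape (M, N): rows follow metabolite
    declaration order, columns reaction order.  Entries absent from the
    triple list are exactly zero."""
    ridx = net.reaction_index()
    midx = net.metabolite_index()
    rows = [midx[m] for m, _, _ in net.stoichiometry]
    cols = [ridx[r] for _, r, _ in net.stoichiometry]
    data = [c for _, _, c in net.stoichiometry]
    mat = sparse.coo_matrix(
        (data, (rows, cols)), shape=(net.n_metabolites, net.n_reactions)
    ).tocsr()
    return mat if sparse_format else mat.toarray()


def internal_submatrix(
    net: MetabolicNetwork, sparse_format: bool = False
) -> np.ndarray | sparse.csr_matrix:
    """Rows of the stoichiometric matrix for internal metabolites only
    (exchange rate identically zero); column order unchanged.  These rows
    define the null space used by the kernel hit-and-run reduction."""
    full = stoichiometric_matrix(net, sparse_format=True)
    keep = [k for k, m in enumerate(net.metabolites) if m.prior.is_internal]
    sub = full[keep, :]
    return sub if sparse_format else sub.toarray()


# ---------------------------------------------------------------------------
# IO: JSON dialect and 3-file TSV dialect


def _prior_to_dict(p: ExchangePrior) -> dict:
    d: dict = {"kind": p.kind}
    if p.kind == "fixed":
        d["z0"] = p.z0
    elif p.kind == "uniform":
        d["lb"], d["ub"] = p.lb, p.ub
    return d


def _prior_from_dict(d: dict) -> ExchangePrior:
    kind = d.get("kind", "internal")
    if kind == "fixed":
        return ExchangePrior("fixed", z0=float(d["z0"]))
    if kind == "uniform":
        return ExchangePrior("uniform", lb=float(d["lb"]), ub=float(d["ub"]))
    return ExchangePrior("internal")


def _tsv_paths(path: Path) -> dict[str, Path]:
    base = path
    for suffix in (".reactions", ".metabolites", ".stoich"):
        if base.name.endswith(suffix + ".tsv"):
            base = base.with_name(base.name[: -len(suffix + ".tsv")])
    if base.suffix == ".tsv":
        base = base.with_suffix("")
    return {
        "reactions": base.with_name(base.name + ".reactions.tsv"),
        "metabolites": base.with_name(base.name + ".metabolites.tsv"),
        "stoich": base.with_name(base.name + ".stoich.tsv"),
    }


def save_network(
    net: MetabolicNetwork, path: str | Path, format: Literal["json", "tsv"] = "json"
) -> None:
    """Write a network to disk.  JSON: single file.  TSV: three files
    sharing ``path``'s basename (<base>.reactions.tsv, <base>.metabolites.tsv,
    <base>.stoich.tsv), tab-separated with header rows."""
    net.require_valid()
    path = Path(path)
    if format == "json":
        payload = {
            "reactions": [
                {"id": r.id, "lb": r.lb, "ub": r.ub} for r in net.reactions
            ],
            "metabolites": [
                {"id": m.id, "prior": _prior_to_dict(m.prior)}
                for m in net.metabolites
            ],
            "stoichiometry": [[m, r, c] for m, r, c in net.stoichiometry],
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return
    if format == "tsv":
        paths = _tsv_paths(path)
        pd.DataFrame(
            [(r.id, r.lb, r.ub) for r in net.reactions],
            columns=["id", "lb", "ub"],
        ).to_csv(paths["reactions"], sep="\t", index=False)
        rows = []
        for m in net.metabolites:
            p = m.prior
            p1 = p.z0 if p.kind == "fixed" else (p.lb if p.kind == "uniform" else "")
            p2 = p.ub if p.kind == "uniform" else ""
            rows.append((m.id, p.kind, p1, p2))
        pd.DataFrame(rows, columns=["id", "kind", "p1", "p2"]).to_csv(
            paths["metabolites"], sep="\t", index=False
        )
        pd.DataFrame(
            net.stoichiometry, columns=["met", "rxn", "coeff"]
        ).to_csv(paths["stoich"], sep="\t", index=False)
        return
    raise ValueError(f"unknown format {format!r}")


def load_network(
    path: str | Path, format: Literal["json", "tsv"] | None = None
) -> MetabolicNetwork:
    """Read and validate a network; declaration order is preserved.
    ``format`` defaults to 'tsv' when the path names one of the TSV triple
    files, else 'json'."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.name.endswith(".tsv") else "json"
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        net = MetabolicNetwork(
            reactions=[
                Reaction(str(r["id"]), float(r["lb"]), float(r["ub"]))
                for r in payload["reactions"]
            ],
            metabolites=[
                Metabolite(str(m["id"]), _prior_from_dict(m.get("prior", {})))
                for m in payload["metabolites"]
            ],
            stoichiometry=[tuple(t) for t in payload["stoichiometry"]],
        )
    elif format == "tsv":
        paths = _tsv_paths(path)
        rdf = pd.read_csv(paths["reactions"], sep="\t", dtype={"id": str},
                          float_precision="round_trip")
        mdf = pd.read_csv(
            paths["metabolites"], sep="\t", dtype={"id": str, "kind": str},
            float_precision="round_trip",
        )
        sdf = pd.read_csv(paths["stoich"], sep="\t", dtype={"met": str, "rxn": str},
                          float_precision="round_trip")
        mets = []
        for _, row in mdf.iterrows():
            kind = row["kind"]
            if kind == "fixed":
                prior = ExchangePrior("fixed", z0=float(row["p1"]))
            elif kind == "uniform":
                prior = ExchangePrior(
                    "uniform", lb=float(row["p1"]), ub=float(row["p2"])
                )
            else:
                prior = ExchangePrior("internal")
            mets.append(Metabolite(row["id"], prior))
        net = MetabolicNetwork(
            reactions=[
                Reaction(row["id"], float(row["lb"]), float(row["ub"]))
                for _, row in rdf.iterrows()
            ],
            metabolites=mets,
            stoichiometry=[
                (row["met"], row["rxn"], float(row["coeff"]))
                for _, row in sdf.iterrows()
            ],
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return net.require_valid()
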