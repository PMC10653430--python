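"""Minimal Active Reactions (MAR): which reactions must stay on at a target point.

Given an irreversible model and a (growth, production) target, the MILP

    minimize    sum_j z_j                      (j over non-exempt reactions)
    subject to  S v = 0
                0 <= v <= v_max
                v_j - v_j,max * z_j <= 0       (z_j binary)
                z_{j,f} + z_{j,b} <= 1         (per split reversible pair)
                biomass flux = target growth   (within tolerance)
                product flux = target production

finds the smallest set of reactions that can carry the network at the target.
Exchange pseudo-reactions and configured diffusion transports carry no z and
are never removed; biomass and maintenance reactions carry a z but it is
pinned to 1 (they count toward the objective and cannot be removed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint

from ._solver import SolverError, solve_milp
from .envelope import FLUX_TOL
from .model_io import MetabolicModel

__all__ = [
    "TargetPoint",
    "MARResult",
    "TargetInfeasibleError",
    "TARGET_EPS",
    "exempt_reactions",
    "never_removable",
    "find_mar",
    "reduce_to_mar",
]

#: half-width of the equality window used to pin target fluxes
TARGET_EPS = 1e-6

EXEMPT_ROLES = ("exchange", "diffusion_transport")
PROTECTED_ROLES = ("biomass", "maintenance")


class TargetInfeasibleError(ValueError):
    """The requested target point lies outside the feasible envelope."""


@dataclass
class TargetPoint:
    growth_rate: float
    production_rate: float
    growth_fraction: float | None = None    # fraction of wild-type max growth
    edge: str = "interior"                  # "upper_edge" | "interior"

    def as_tuple(self) -> tuple[float, float]:
        return (self.growth_rate, self.production_rate)


@dataclass
class MARResult:
    z: dict[str, int]             # non-exempt reaction -> 0/1
    active_set: list[str]         # z == 1 plus all exempt reactions
    removed_set: list[str]        # z == 0 (split-level ids)
    objective: int                # sum of z
    target: TargetPoint | None = None
    flux: dict[str, float] = field(default_factory=dict)

    def removed_sources(self, model: MetabolicModel) -> list[str]:
        """Removed reactions collapsed to source (reversible-level) ids."""
        seen: list[str] = []
        for rid in self.removed_set:
            src = model.source_id(rid)
            if src not in seen:
                seen.append(src)
        return seen

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "active_set": self.active_set,
            "removed_set": self.removed_set,
            "target": None
            if self.target is None
            else {
                "growth_rate": self.target.growth_rate,
                "production_rate": self.target.production_rate,
                "edge": self.target.edge,
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def exempt_reactions(model: MetabolicModel) -> list[str]:
    """Reactions that carry no activity indicator (exchanges, diffusion)."""
    return [
        rid for rid in model.reaction_ids if model.roles.get(rid) in EXEMPT_ROLES
    ]


def never_removable(model: MetabolicModel) -> list[str]:
    """Non-exempt reactions whose indicator is pinned active."""
    return [
        rid for rid in model.reaction_ids if model.roles.get(rid) in PROTECTED_ROLES
    ]


def find_mar(
    model: MetabolicModel,
    target: TargetPoint,
    biomass_id: str,
    product_id: str,
    target_eps: float = TARGET_EPS,
    production_as_minimum: bool = False,
) -> MARResult:
    """Solve the MAR MILP at the target point to proven optimality.

    ``production_as_minimum`` relaxes the production pin to ``>= target``
    (the growth pin stays an equality).
    """
    if not model.roles:
        raise ValueError("model has no reaction roles; run classify_roles first")
    if np.any(model.lower_bounds < -FLUX_TOL):
        raise ValueError("model must be irreversible; run to_irreversible first")

    n = model.n_reactions
    indicated = [
        rid for rid in model.reaction_ids if model.roles.get(rid) not in EXEMPT_ROLES
    ]
    k = len(indicated)
    z_of = {rid: i for i, rid in enumerate(indicated)}

    lb_v = model.lower_bounds.copy()
    ub_v = model.upper_bounds.copy()
    jb = model.index(biomass_id)
    jp = model.index(product_id)
    lb_v[jb] = target.growth_rate - target_eps
    ub_v[jb] = target.growth_rate + target_eps
    lb_v[jp] = target.production_rate - target_eps
    if not production_as_minimum:
        ub_v[jp] = min(ub_v[jp], target.production_rate + target_eps)
    lb_v = np.maximum(lb_v, 0.0)

    lb_z = np.zeros(k)
    ub_z = np.ones(k)
    for rid in never_removable(model):
        lb_z[z_of[rid]] = 1.0

    # variable vector x = [v (n), z (k)]
    rows_eq = sparse.hstack(
        [sparse.csr_matrix(model.S), sparse.csr_matrix((model.n_metabolites, k))]
    )
    eq = LinearConstraint(rows_eq, 0.0, 0.0)

    # v_j - ub_j * z_j <= 0
    data, ri, ci = [], [], []
    for row, rid in enumerate(indicated):
        j = model.index(rid)
        data += [1.0, -max(model.upper_bounds[j], 0.0)]
        ri += [row, row]
        ci += [j, n + z_of[rid]]
    link = LinearConstraint(
        sparse.csr_matrix((data, (ri, ci)), shape=(k, n + k)), -np.inf, 0.0
    )

    constraints = [eq, link]

    # z_f + z_b <= 1 per split pair (both halves must carry an indicator)
    pair_rows = [
        (z_of[f], z_of[b])
        for f, b in model.reversible_pairs.items()
        if f in z_of and b in z_of
    ]
    if pair_rows:
        data, ri, ci = [], [], []
        for row, (zf, zb) in enumerate(pair_rows):
            data += [1.0, 1.0]
            ri += [row, row]
            ci += [n + zf, n + zb]
        constraints.append(
            LinearConstraint(
                sparse.csr_matrix((data, (ri, ci)), shape=(len(pair_rows), n + k)),
                -np.inf,
                1.0,
            )
        )

    c = np.concatenate([np.zeros(n), np.ones(k)])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = solve_milp(
        c,
        integrality,
        np.concatenate([lb_v, lb_z]),
        np.concatenate([ub_v, ub_z]),
        constraints,
        sense="min",
    )
    if res.status == "infeasible":
        raise TargetInfeasibleError(
            f"target point (growth={target.growth_rate}, "
            f"production={target.production_rate}) is infeasible"
        )
    if not res.ok:
        raise SolverError(f"MAR MILP terminated {res.status}")

    v = res.x[:n]
    z = {rid: int(round(res.x[n + z_of[rid]])) for rid in indicated}
    active = [rid for rid in model.reaction_ids if z.get(rid, 1) == 1]
    removed = [rid for rid in indicated if z[rid] == 0]
    # sanity: no split pair simultaneously active in the witness flux
    # (1e-6 rather than FLUX_TOL: MILP feasibility tolerances are looser)
    for f, b in model.reversible_pairs.items():
        if abs(v[model.index(f)]) > 1e-6 and abs(v[model.index(b)]) > 1e-6:
            raise SolverError(f"split pair {f}/{b} both carry flux in MAR witness")
    return MARResult(
        z=z,
        active_set=active,
        removed_set=removed,
        objective=int(round(res.objective)),
        target=target,
        flux={rid: float(v[model.index(rid)]) for rid in model.reaction_ids},
    )


def reduce_to_mar(model: MetabolicModel, mar: MARResult) -> MetabolicModel:
    """Copy of the model with both bounds of every removed reaction set to 0."""
    out = model.copy()
    for rid in mar.removed_set:
        j = out.index(rid)
        out.lower_bounds[j] = 0.0
        out.upper_bounds[j] = 0.0
    return out
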