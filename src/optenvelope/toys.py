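"""Hand-analysable synthetic models and brute-force oracles.

The coupling toy is a 5-metabolite, 8-reaction irreversible network built so
that every envelope, MAR and knockout question has a closed-form answer:

    EX_A:  -> A          (uptake, ub = substrate_ub)
    R1:   A -> B
    R2:   A -> P + C
    R5:   A -> C
    R3:   B + C -> BM    (biomass, objective)
    ATPM: C ->           (maintenance, lb = maintenance_lb)
    EX_P:  P ->
    EX_BM: BM ->

Wild type: max growth (10 - maintenance_lb)/2, max product at zero growth
substrate_ub, min product 0 everywhere.  Knocking out R5 forces every unit of
maintenance and growth through the product-producing R2, giving strong
coupling with min product g + maintenance_lb.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ._solver import solve_lp
from .mar_milp import EXEMPT_ROLES, PROTECTED_ROLES, TARGET_EPS, TargetPoint
from .model_io import MetabolicModel, RoleConfig, classify_roles

__all__ = [
    "make_coupling_toy",
    "make_reversible_toy",
    "brute_force_mar",
    "brute_force_cap",
]


def make_coupling_toy(
    maintenance_lb: float = 1.0, substrate_ub: float = 10.0
) -> MetabolicModel:
    metabolite_ids = ["A", "B", "C", "P", "BM"]
    reaction_ids = ["EX_A", "R1", "R2", "R5", "R3", "ATPM", "EX_P", "EX_BM"]
    S = np.array(
        [
            # EX_A  R1  R2  R5  R3 ATPM EX_P EX_BM
            [1, -1, -1, -1, 0, 0, 0, 0],      # A
            [0, 1, 0, 0, -1, 0, 0, 0],        # B
            [0, 0, 1, 1, -1, -1, 0, 0],       # C
            [0, 0, 1, 0, 0, 0, -1, 0],        # P
            [0, 0, 0, 0, 1, 0, 0, -1],        # BM
        ],
        dtype=float,
    )
    lb = np.array([0, 0, 0, 0, 0, maintenance_lb, 0, 0], dtype=float)
    ub = np.array([substrate_ub, 1000, 1000, 1000, 1000, 1000, 1000, 1000], dtype=float)
    obj = np.zeros(8)
    obj[4] = 1.0  # R3
    model = MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coeffs=obj,
        model_id="coupling_toy",
    )
    return classify_roles(
        model, RoleConfig(biomass_id="R3", maintenance_ids=["ATPM"])
    )


def make_reversible_toy(
    maintenance_lb: float = 1.0, substrate_ub: float = 10.0
) -> MetabolicModel:
    """Coupling toy with R5 made reversible (A <-> C), for split-form tests."""
    model = make_coupling_toy(maintenance_lb, substrate_ub)
    model.lower_bounds[model.index("R5")] = -1000.0
    return model


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _feasible_at_target(
    model: MetabolicModel,
    target: TargetPoint,
    biomass_id: str,
    product_id: str,
    inactive: list[str],
    eps: float = TARGET_EPS,
) -> bool:
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rid in inactive:
        j = model.index(rid)
        lb[j] = 0.0
        ub[j] = 0.0
    jb, jp = model.index(biomass_id), model.index(product_id)
    lb[jb], ub[jb] = target.growth_rate - eps, target.growth_rate + eps
    lb[jp], ub[jp] = target.production_rate - eps, target.production_rate + eps
    lb = np.maximum(lb, 0.0)
    res = solve_lp(
        np.zeros(model.n_reactions),
        model.S,
        np.zeros(model.n_metabolites),
        lb,
        ub,
    )
    return res.ok


def brute_force_mar(
    model: MetabolicModel,
    target: TargetPoint,
    biomass_id: str,
    product_id: str,
    max_candidates: int = 15,
):
    """Enumerate every activity pattern over the knockout candidates.

    Returns ``(min_count, optimal_sets)`` where each optimal set is a frozenset
    of non-exempt reactions counted active (candidates allowed to carry flux
    plus the pinned biomass/maintenance reactions), or ``(None, [])`` when no
    pattern is feasible at the target.
    """
    pinned = [
        rid for rid in model.reaction_ids if model.roles.get(rid) in PROTECTED_ROLES
    ]
    candidates = [
        rid
        for rid in model.reaction_ids
        if model.roles.get(rid) not in EXEMPT_ROLES and rid not in pinned
    ]
    if len(candidates) > max_candidates:
        raise ValueError(f"{len(candidates)} candidates exceed oracle limit")

    best: int | None = None
    optima: list[frozenset] = []
    for size in range(len(candidates) + 1):
        if best is not None and size + len(pinned) > best:
            break
        for active in combinations(candidates, size):
            inactive = [r for r in candidates if r not in active]
            if _feasible_at_target(model, target, biomass_id, product_id, inactive):
                count = size + len(pinned)
                if best is None or count < best:
                    best = count
                    optima = []
                if count == best:
                    optima.append(frozenset(active) | frozenset(pinned))
    return best, optima


def brute_force_cap(
    model: MetabolicModel,
    protected: set[str],
    K: int,
    biomass_id: str,
    product_id: str,
    max_candidates: int = 15,
):
    """Exhaustive knockout-subset search maximising the minimum secretion at
    zero growth.  Returns ``(best_subset, best_value)``; subsets whose inner LP
    is infeasible are invalid and skipped."""
    from .envelope import min_production_at_zero_growth
    from .knockout_cap import knockout_candidates
    from ._solver import InfeasibleProblemError

    candidates = knockout_candidates(model, protected)
    if len(candidates) > max_candidates:
        raise ValueError(f"{len(candidates)} candidates exceed oracle limit")
    best_subset: tuple = ()
    best_value = None
    for size in range(min(K, len(candidates)) + 1):
        for subset in combinations(candidates, size):
            trial = model.copy()
            trial.knock_out(subset)
            try:
                value = min_production_at_zero_growth(trial, biomass_id, product_id)
            except InfeasibleProblemError:
                continue
            if best_value is None or value > best_value + 1e-9:
                best_value = value
                best_subset = subset
    return list(best_subset), best_value
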