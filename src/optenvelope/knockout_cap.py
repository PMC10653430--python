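"""Knockout budgets: maximise the guaranteed minimum secretion with at most K
knockouts, via a duality reformulation of the inner minimisation.

Outer problem: choose a binary knockout vector y (one per candidate source
reaction, both split directions removed together), sum(y) <= K.  Inner
problem: the metabolic minimum of product secretion at zero growth,

    min  p.v   s.t.  S v = 0,  lb <= v <= ub .(1 - y) ,

whose LP dual is

    max  lb.nu - sum_j ub_j (1 - y_{r(j)}) mu_j
    s.t. S^T lam + nu - mu = p,   mu, nu >= 0 .

The bilinear y*mu products are linearised with big-M variables
``w_j = y_{r(j)} mu_j`` (w <= mu, w <= M y), turning max-min into one MILP.
Because an over-small M (or an inner-infeasible y) silently distorts the
certificate, every solution is verified by re-solving the inner LP; a
mismatching y is excluded with a no-good cut and the MILP re-solved.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint

from ._solver import InfeasibleProblemError, SolverError, solve_milp
from .envelope import min_production_at_zero_growth
from .mar_milp import EXEMPT_ROLES, PROTECTED_ROLES
from .model_io import MetabolicModel
from .reinsertion import KnockoutDesign, design_from_model

__all__ = ["BigMError", "cap_knockouts", "knockout_candidates"]

log = logging.getLogger(__name__)

#: default big-M on dual variables of knockout-linked bound constraints
DEFAULT_BIG_M = 1e4
VERIFY_TOL = 1e-5


class BigMError(SolverError):
    """The big-M linearisation could not certify a consistent optimum."""


def knockout_candidates(
    model: MetabolicModel, protected: set[str] | None = None
) -> list[str]:
    """Source-level ids eligible for knockout: non-exempt, non-protected.

    ``protected`` may contain source or split ids; exchanges, diffusion
    transports, biomass and maintenance reactions are excluded always.
    """
    protected = set(protected or ())
    protected_sources = {
        model.source_id(rid) if model.has_reaction(rid) else rid for rid in protected
    }
    out: list[str] = []
    for rid in model.reaction_ids:
        role = model.roles.get(rid, "internal")
        if role in EXEMPT_ROLES or role in PROTECTED_ROLES:
            continue
        src = model.source_id(rid)
        if src in protected_sources or src in out:
            continue
        out.append(src)
    return out


def _inner_min_at_zero_growth(model, knockouts, biomass_id, product_id):
    trial = model.copy()
    trial.knock_out(knockouts)
    return min_production_at_zero_growth(trial, biomass_id, product_id)


def cap_knockouts(
    model: MetabolicModel,
    protected: set[str],
    K: int,
    biomass_id: str,
    product_id: str,
    big_m: float = DEFAULT_BIG_M,
    n_points: int = 100,
    max_cut_rounds: int = 50,
) -> KnockoutDesign:
    """Best knockout set of size <= K maximising the certified minimum secretion
    at zero growth.  ``protected`` should contain the MAR of the envelope under
    study (plus anything else that must stay)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    candidates = knockout_candidates(model, protected)
    if K > len(candidates):
        warnings.warn(
            f"K={K} exceeds the {len(candidates)} candidate reactions; clamping",
            stacklevel=2,
        )
        K = len(candidates)
    if K == 0 or not candidates:
        value = _inner_min_at_zero_growth(model, [], biomass_id, product_id)
        design = design_from_model(model, [], biomass_id, product_id, n_points=n_points)
        design.provenance = {"K": K, "certified_min": float(value)}
        return design

    # inner LP data: growth pinned to zero, everything else untouched
    inner = model.copy()
    jb = inner.index(biomass_id)
    inner.lower_bounds[jb] = 0.0
    inner.upper_bounds[jb] = 0.0
    m, n = inner.n_metabolites, inner.n_reactions
    lb = inner.lower_bounds
    ub = inner.upper_bounds
    p = np.zeros(n)
    p[inner.index(product_id)] = 1.0

    cand_index = {src: i for i, src in enumerate(candidates)}
    # split columns governed by each candidate's y
    linked: list[tuple[int, int]] = []  # (column j, candidate index)
    for j, rid in enumerate(inner.reaction_ids):
        src = inner.source_id(rid)
        if src in cand_index:
            linked.append((j, cand_index[src]))
    nc = len(candidates)
    nw = len(linked)

    # variables x = [lam (m, free), mu (n, >=0), nu (n, >=0), w (nw, >=0), y (nc, bin)]
    o_mu, o_nu, o_w, o_y = m, m + n, m + 2 * n, m + 2 * n + nw
    ntot = o_y + nc

    # duals are capped at big_m: an inner-infeasible y then yields a large but
    # finite certificate that the verification loop rejects with a cut, instead
    # of an unbounded MILP
    lo = np.concatenate(
        [np.full(m, -big_m), np.zeros(n), np.zeros(n), np.zeros(nw), np.zeros(nc)]
    )
    hi = np.concatenate(
        [np.full(m, big_m), np.full(n, big_m), np.full(n, big_m),
         np.full(nw, big_m), np.ones(nc)]
    )
    integrality = np.zeros(ntot)
    integrality[o_y:] = 1.0

    # dual feasibility: S^T lam + nu - mu = p
    A_dual = sparse.hstack(
        [
            sparse.csr_matrix(inner.S.T),
            -sparse.identity(n),
            sparse.identity(n),
            sparse.csr_matrix((n, nw)),
            sparse.csr_matrix((n, nc)),
        ]
    )
    constraints = [LinearConstraint(A_dual, p, p)]

    # w_j <= mu_j  and  w_j <= M y_{r(j)}
    data, ri, ci = [], [], []
    row = 0
    for k, (j, ci_cand) in enumerate(linked):
        data += [1.0, -1.0]
        ri += [row, row]
        ci += [o_w + k, o_mu + j]
        row += 1
        data += [1.0, -big_m]
        ri += [row, row]
        ci += [o_w + k, o_y + ci_cand]
        row += 1
    constraints.append(
        LinearConstraint(sparse.csr_matrix((data, (ri, ci)), shape=(row, ntot)), -np.inf, 0.0)
    )

    # sum(y) <= K
    budget = np.zeros(ntot)
    budget[o_y:] = 1.0
    constraints.append(LinearConstraint(budget, -np.inf, float(K)))

    # objective (maximise): lb.nu - ub.mu + sum over linked of ub_j w_j
    c = np.zeros(ntot)
    c[o_nu : o_nu + n] = lb
    c[o_mu : o_mu + n] = -ub
    for k, (j, _) in enumerate(linked):
        c[o_w + k] = ub[j]

    cuts: list[LinearConstraint] = []
    for round_no in range(max_cut_rounds):
        res = solve_milp(
            c, integrality, lo, hi, constraints + cuts, sense="max"
        )
        if res.status == "unbounded":
            raise BigMError(
                "dual MILP is unbounded; the inner LP is infeasible for some "
                "knockout choice and the duals are uncapped — increase protection "
                "or big_m"
            )
        if not res.ok:
            raise SolverError(f"knockout-cap MILP terminated {res.status}")
        y = res.x[o_y:]
        chosen = [candidates[i] for i in np.flatnonzero(y > 0.5)]
        certified = float(res.objective)
        try:
            actual = _inner_min_at_zero_growth(model, chosen, biomass_id, product_id)
        except InfeasibleProblemError:
            actual = None
        if actual is not None and abs(actual - certified) <= max(
            VERIFY_TOL, VERIFY_TOL * abs(certified)
        ):
            design = design_from_model(
                model, chosen, biomass_id, product_id, n_points=n_points
            )
            design.provenance = {
                "K": K,
                "certified_min": certified,
                "verification_rounds": round_no + 1,
            }
            return design
        log.info(
            "cut round %d: knockout set %s certified %.6g but verified %s; excluding",
            round_no + 1,
            chosen,
            certified,
            actual,
        )
        # no-good cut excluding exactly this y vector
        coeff = np.zeros(ntot)
        coeff[o_y:] = np.where(y > 0.5, 1.0, -1.0)
        cuts.append(LinearConstraint(coeff, -np.inf, float(np.sum(y > 0.5)) - 1.0))
    raise BigMError(
        f"no certified-consistent knockout set within {max_cut_rounds} cut rounds; "
        "big_m is likely too small"
    )
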