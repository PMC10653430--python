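"""Production envelopes: repeated LP over a growth grid, coupling class, MP point.

The envelope of a model is the feasible region in the (growth rate, product
secretion rate) plane, summarised as min/max product flux at each of
``n_points`` growth values (default 100, endpoints included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._solver import InfeasibleProblemError, solve_lp
from .model_io import MetabolicModel

__all__ = [
    "ProductionEnvelope",
    "FLUX_TOL",
    "COUPLING_TOL",
    "MOLECULAR_WEIGHTS",
    "fba",
    "flux_range",
    "compute_envelope",
    "classify_coupling",
    "mp_point",
    "min_production_at_zero_growth",
    "to_yield_units",
]

#: |v| above this counts as a nonzero flux
FLUX_TOL = 1e-9
#: minimum secretion above this counts as coupled
COUPLING_TOL = 1e-6

#: g/mmol, used for g/g yield conversion
MOLECULAR_WEIGHTS = {
    "glucose": 0.18016,
    "acetate": 0.06005,
    "glycerol": 0.09209,
    "ethanol": 0.04607,
    "succinate": 0.11809,
}


def fba(
    model: MetabolicModel,
    objective_id: str,
    sense: str = "max",
    fixed: list[tuple[str, float]] | None = None,
):
    """Optimise a single reaction flux subject to ``S v = 0`` and bounds.

    ``fixed`` pins additional reactions to exact values (equality via bounds).
    Returns ``(objective value, flux vector)``; raises
    :class:`InfeasibleProblemError` if the fixings are infeasible.
    """
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rid, value in fixed or []:
        j = model.index(rid)
        lb[j] = value
        ub[j] = value
    c = np.zeros(model.n_reactions)
    c[model.index(objective_id)] = 1.0
    res = solve_lp(c, model.S, np.zeros(model.n_metabolites), lb, ub, sense=sense)
    if not res.ok:
        raise InfeasibleProblemError(
            f"FBA {sense} {objective_id} is {res.status} under the given fixings"
        )
    return res.objective, res.x


def flux_range(model, reaction_id, fixed=None) -> tuple[float, float]:
    lo, _ = fba(model, reaction_id, "min", fixed)
    hi, _ = fba(model, reaction_id, "max", fixed)
    return lo, hi


@dataclass
class ProductionEnvelope:
    growth_grid: np.ndarray
    min_product: np.ndarray
    max_product: np.ndarray
    max_growth: float
    mp_point: tuple[float, float, float]   # (growth, min product, max product)
    min_production_at_zero_growth: float
    coupling: str = field(default="none")
    biomass_id: str = ""
    product_id: str = ""

    @property
    def max_production(self) -> float:
        """Largest product flux anywhere on the envelope."""
        return float(np.max(self.max_product))

    @property
    def min_production(self) -> float:
        """Guaranteed product flux (minimum over the whole envelope)."""
        return float(np.min(self.min_product))

    def to_dict(self) -> dict:
        return {
            "biomass_id": self.biomass_id,
            "product_id": self.product_id,
            "growth_grid": self.growth_grid.tolist(),
            "min_product": self.min_product.tolist(),
            "max_product": self.max_product.tolist(),
            "max_growth": self.max_growth,
            "mp_point": list(self.mp_point),
            "min_production_at_zero_growth": self.min_production_at_zero_growth,
            "coupling": self.coupling,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("growth\tmin_product\tmax_product\n")
            for g, lo, hi in zip(self.growth_grid, self.min_product, self.max_product):
                fh.write(f"{g:.10g}\t{lo:.10g}\t{hi:.10g}\n")


def min_production_at_zero_growth(model, biomass_id, product_id) -> float:
    """Guaranteed secretion with biomass flux pinned to zero (may be infeasible)."""
    value, _ = fba(model, product_id, "min", fixed=[(biomass_id, 0.0)])
    return value


def compute_envelope(
    model: MetabolicModel,
    biomass_id: str,
    product_id: str,
    n_points: int = 100,
) -> ProductionEnvelope:
    """Min/max product flux at ``n_points`` growth values spanning the feasible
    growth range (endpoints included)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    g_min, g_max = flux_range(model, biomass_id)
    grid = np.linspace(g_min, g_max, n_points)
    lo = np.empty(n_points)
    hi = np.empty(n_points)
    for i, g in enumerate(grid):
        lo[i], hi[i] = flux_range(model, product_id, fixed=[(biomass_id, g)])
    mp = (g_max, float(lo[-1]), float(hi[-1]))
    try:
        p0 = min_production_at_zero_growth(model, biomass_id, product_id)
    except InfeasibleProblemError:
        # zero growth outside the feasible range (biomass lower bound > 0)
        p0 = float(lo[0])
    env = ProductionEnvelope(
        growth_grid=grid,
        min_product=lo,
        max_product=hi,
        max_growth=float(g_max),
        mp_point=mp,
        min_production_at_zero_growth=float(p0),
        biomass_id=biomass_id,
        product_id=product_id,
    )
    env.coupling = classify_coupling(env)
    return env


def classify_coupling(env: ProductionEnvelope, tol: float = COUPLING_TOL) -> str:
    """strong / weak / none per the minimum-secretion criterion.

    Strong: secretion is guaranteed even without growth.  Weak: secretion is
    guaranteed somewhere on the envelope but not at zero growth.
    """
    if env.min_production_at_zero_growth > tol:
        return "strong"
    if np.any(env.min_product > tol):
        return "weak"
    return "none"


def mp_point(model, biomass_id, product_id) -> tuple[float, float, float]:
    """Envelope point of maximal growth: (growth, min product, max product)."""
    g_max, _ = fba(model, biomass_id, "max")
    lo, hi = flux_range(model, product_id, fixed=[(biomass_id, g_max)])
    return float(g_max), float(lo), float(hi)


def to_yield_units(
    rate: float,
    molecular_weight: float,
    substrate_uptake: float,
    substrate_weight: float,
) -> float:
    """Convert a secretion rate (mmol/gDCW/h) to a g/g substrate yield.

    For a biomass yield pass the growth rate with ``molecular_weight=1``
    (biomass flux already carries gDCW units).
    """
    if substrate_uptake <= 0:
        raise ValueError("substrate uptake must be > 0")
    return rate * molecular_weight / (substrate_uptake * substrate_weight)


def plot_envelopes(envelopes, labels, path, title=None) -> None:
    """Write a simple overlay plot of one or more envelopes (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for env, label in zip(envelopes, labels):
        g = np.concatenate([env.growth_grid, env.growth_grid[::-1], env.growth_grid[:1]])
        p = np.concatenate([env.max_product, env.min_product[::-1], env.max_product[:1]])
        ax.plot(g, p, label=label)
    ax.set_xlabel("growth rate (1/h)")
    ax.set_ylabel("product secretion (mmol/gDCW/h)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
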