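"""Sequential reinsertion of removed non-MAR reactions to minimise knockouts.

Starting from the reduced (MAR-only) model, each removed reaction is restored
(both directions at once) and kept whenever the guaranteed minimum secretion
at zero growth does not drop below the reduced model's baseline.  Whatever is
still removed at the end is the knockout set.  Only the minimum secretion is
guaranteed; the MP point may legitimately move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .envelope import (
    COUPLING_TOL,
    compute_envelope,
    min_production_at_zero_growth,
)
from .mar_milp import MARResult, TargetPoint, reduce_to_mar
from .model_io import MetabolicModel

__all__ = ["KnockoutDesign", "WeakCouplingError", "minimal_knockouts"]

#: slack allowed on the preserved minimum secretion rate
REINSERTION_TOL = 1e-6


class WeakCouplingError(ValueError):
    """Reinsertion requires a strongly coupled baseline (minimum secretion > 0)."""


@dataclass
class KnockoutDesign:
    knockouts: list[str]              # source (reversible-level) reaction ids
    count: int
    min_production: float             # guaranteed secretion at zero growth
    max_production: float             # largest secretion anywhere on the envelope
    mp_production: float              # minimum secretion at maximal growth
    mp_production_max: float          # maximum secretion at maximal growth
    mp_growth: float
    coupling: str
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "knockouts": self.knockouts,
            "count": self.count,
            "min_production": self.min_production,
            "max_production": self.max_production,
            "mp_production": self.mp_production,
            "mp_production_max": self.mp_production_max,
            "mp_growth": self.mp_growth,
            "coupling": self.coupling,
            "provenance": self.provenance,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def table_row(self) -> dict:
        """One row in the layout of the comparison table."""
        return {
            "knockout_count": self.count,
            "min_production": self.min_production,
            "max_production": self.max_production,
            "mp_production": self.mp_production,
            "mp_growth": self.mp_growth,
            "knockouts": ", ".join(self.knockouts),
        }


def design_from_model(
    model: MetabolicModel,
    knockouts: list[str],
    biomass_id: str,
    product_id: str,
    n_points: int = 100,
    provenance: dict | None = None,
) -> KnockoutDesign:
    """Apply ``knockouts`` to a copy of ``model`` and measure its envelope."""
    knocked = model.copy()
    knocked.knock_out(knockouts)
    env = compute_envelope(knocked, biomass_id, product_id, n_points=n_points)
    return KnockoutDesign(
        knockouts=list(knockouts),
        count=len(knockouts),
        min_production=env.min_production_at_zero_growth,
        max_production=env.max_production,
        mp_production=env.mp_point[1],
        mp_production_max=env.mp_point[2],
        mp_growth=env.mp_point[0],
        coupling=env.coupling,
        provenance=provenance or {},
    )


def minimal_knockouts(
    full_model: MetabolicModel,
    mar: MARResult,
    biomass_id: str,
    product_id: str,
    baseline_min: float | None = None,
    tol: float = REINSERTION_TOL,
    order: list[str] | None = None,
    rng: np.random.Generator | None = None,
    n_points: int = 100,
) -> KnockoutDesign:
    """Greedy reinsertion over ``mar.removed_set`` in model reaction order.

    ``order`` overrides the iteration order (source-level ids); ``rng``
    shuffles it instead, for seeded exploration of alternatives.
    """
    reduced = reduce_to_mar(full_model, mar)
    if baseline_min is None:
        baseline_min = min_production_at_zero_growth(reduced, biomass_id, product_id)
    if baseline_min <= COUPLING_TOL:
        raise WeakCouplingError(
            f"baseline minimum secretion {baseline_min:.3g} is not strong; "
            "reinsertion would not preserve any guaranteed production"
        )

    removed_sources = mar.removed_sources(full_model)
    if order is not None:
        unknown = set(order) - set(removed_sources)
        if unknown:
            raise ValueError(f"order contains non-removed reactions: {sorted(unknown)}")
        sequence = list(order)
    else:
        sequence = list(removed_sources)  # model reaction order, deterministic
        if rng is not None:
            rng.shuffle(sequence)

    current = reduced
    knocked_out = list(sequence)
    for src in sequence:
        trial = current.copy()
        trial.restore_bounds_from(full_model, [src])
        new_min = min_production_at_zero_growth(trial, biomass_id, product_id)
        if new_min >= baseline_min - tol:
            current = trial
            knocked_out.remove(src)

    final_min = min_production_at_zero_growth(current, biomass_id, product_id)
    assert final_min >= baseline_min - tol, "reinsertion broke the guaranteed minimum"

    design = design_from_model(
        full_model,
        knocked_out,
        biomass_id,
        product_id,
        n_points=n_points,
        provenance={
            "baseline_min": float(baseline_min),
            "mar_objective": mar.objective,
            "mar_removed": len(mar.removed_set),
            "target": None if mar.target is None else list(mar.target.as_tuple()),
        },
    )
    return design
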