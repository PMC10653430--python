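"""Interior target points and the candidate-envelope comparison table.

After the primary (upper-edge) design is found, the production span between
the primary envelope's MP point and the primary target is divided into
equally spaced interior productions at the primary growth rate.  The full
pipeline runs at each interior target; duplicate knockout sets are collapsed
and unfavourable rows (lower guaranteed minimum than the primary, or too many
knockouts) are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from ._solver import InfeasibleProblemError
from .mar_milp import TargetInfeasibleError, TargetPoint, find_mar
from .model_io import MetabolicModel
from .reinsertion import KnockoutDesign, WeakCouplingError, minimal_knockouts

__all__ = ["ComparisonTable", "make_interior_targets", "scan"]

log = logging.getLogger(__name__)


@dataclass
class ComparisonTable:
    designs: list[KnockoutDesign]     # primary first
    ratios: list[float]               # target production / primary max at zero growth
    skipped: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (design, ratio) in enumerate(zip(self.designs, self.ratios), start=1):
            row = {"envelope": i, **design.table_row(), "target_ratio": ratio}
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "designs": [d.to_dict() for d in self.designs],
            "ratios": self.ratios,
            "skipped": self.skipped,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def make_interior_targets(
    primary: TargetPoint, mp_production: float, n_mid: int
) -> list[TargetPoint]:
    """``n_mid`` equally spaced productions strictly between the MP production
    and the primary production, at the primary growth rate.

    Points below the MP production are never generated.  A degenerate span
    (primary production <= MP production) yields an empty list.
    """
    if n_mid < 0:
        raise ValueError("n_mid must be >= 0")
    if n_mid == 0:
        return []
    if primary.production_rate <= mp_production:
        log.warning(
            "primary production %.4g <= MP production %.4g; no interior targets",
            primary.production_rate,
            mp_production,
        )
        return []
    step = (primary.production_rate - mp_production) / (n_mid + 1)
    return [
        TargetPoint(
            growth_rate=primary.growth_rate,
            production_rate=mp_production + i * step,
            growth_fraction=primary.growth_fraction,
            edge="interior",
        )
        for i in range(1, n_mid + 1)
    ]


def scan(
    model: MetabolicModel,
    biomass_id: str,
    product_id: str,
    primary_design: KnockoutDesign,
    primary_target: TargetPoint,
    primary_mp_production: float,
    n_mid: int = 10,
    max_knockouts: int = 10,
    deduplicate: bool = True,
    min_production_tol: float = 1e-6,
    n_points: int = 100,
) -> ComparisonTable:
    """Run the pipeline at every interior target and build the comparison table.

    Retained rows have a guaranteed minimum at least the primary's and at most
    ``max_knockouts`` knockouts; the primary row itself is subject to the same
    knockout cap.  Infeasible or weakly coupled targets are skipped with a
    logged reason.
    """
    # the primary envelope's maximum production at zero growth normalises the
    # per-target location ratios
    primary_max_p0 = primary_design.max_production

    designs: list[KnockoutDesign] = []
    ratios: list[float] = []
    skipped: list[dict] = []
    seen: set[tuple[str, ...]] = set()

    def consider(design: KnockoutDesign, target: TargetPoint) -> None:
        key = tuple(sorted(design.knockouts))
        if deduplicate and key in seen:
            skipped.append(
                {"target": list(target.as_tuple()), "reason": "duplicate knockout set"}
            )
            return
        if design.count > max_knockouts:
            skipped.append(
                {
                    "target": list(target.as_tuple()),
                    "reason": f"{design.count} knockouts exceed cap {max_knockouts}",
                }
            )
            return
        if design.min_production < primary_design.min_production - min_production_tol:
            skipped.append(
                {
                    "target": list(target.as_tuple()),
                    "reason": "minimum production below the primary envelope",
                }
            )
            return
        seen.add(key)
        designs.append(design)
        ratios.append(
            target.production_rate / primary_max_p0 if primary_max_p0 > 0 else float("nan")
        )

    consider(primary_design, primary_target)

    for target in make_interior_targets(primary_target, primary_mp_production, n_mid):
        try:
            mar = find_mar(model, target, biomass_id, product_id)
            design = minimal_knockouts(
                model, mar, biomass_id, product_id, n_points=n_points
            )
        except (TargetInfeasibleError, WeakCouplingError, InfeasibleProblemError) as exc:
            log.info("skipping target %s: %s", target.as_tuple(), exc)
            skipped.append({"target": list(target.as_tuple()), "reason": str(exc)})
            continue
        consider(design, target)

    return ComparisonTable(designs=designs, ratios=ratios, skipped=skipped)
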