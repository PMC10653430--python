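"""Reference benchmark computations on the public BiGG models iJR904/iMM904.

The model files are not redistributable binaries but they are also not
bundled here; place ``iJR904.json`` / ``iMM904.json`` (BiGG JSON) in one of
the search locations (``optenvelope/data``, ``$OPTENVELOPE_MODEL_DIR``, or
``./data/bigg``), e.g. via ``scripts/fetch_models.py``.  Every function in
this module recomputes its quantity from scratch by plain LP on the prepared
model; nothing is hard-coded but the published knockout sets and the medium
definition (glucose uptake 10 mmol/gDCW/h, inorganic uptakes free at 1000,
all other uptakes closed).
"""

from __future__ import annotations

import os
from pathlib import Path

from .envelope import MOLECULAR_WEIGHTS, fba, flux_range, to_yield_units
from .model_io import (
    MediumSpec,
    MetabolicModel,
    RoleConfig,
    UnknownReactionError,
    apply_medium,
    classify_roles,
    load_model,
    to_irreversible,
)

__all__ = [
    "find_model_file",
    "prepare_bigg_model",
    "resolve_reaction",
    "ACETATE_8KO_DESIGN",
    "ACETATE_3KO_DESIGN",
    "GLUCOSE_UPTAKE",
]

GLUCOSE_UPTAKE = 10.0

#: published 8-knockout acetate design for E. coli (primary envelope)
ACETATE_8KO_DESIGN = [
    "GLCDe", "MTHFD_1", "F6PA", "PGL", "PFK", "SUCCt2r", "SUCD4", "AKGt2r",
]
#: published minimal (3-knockout) acetate design for E. coli
ACETATE_3KO_DESIGN = ["ATPS4r", "PGM", "SUCOAS"]

_GLC_IDS = ["EX_glc__D_e", "EX_glc_D_e", "EX_glc_e", "EX_glc(e)"]
_O2_IDS = ["EX_o2_e", "EX_o2(e)"]
#: cytochrome c oxidase in iMM904 (removed for anaerobiosis)
_YEAST_OXIDASE_IDS = ["CYOOm", "CYOR_u6m"]


def find_model_file(name: str) -> Path | None:
    """Locate ``<name>.json`` in the documented search path."""
    candidates = [Path(__file__).parent / "data"]
    env_dir = os.environ.get("OPTENVELOPE_MODEL_DIR")
    if env_dir:
        candidates.append(Path(env_dir))
    candidates.append(Path.cwd() / "data" / "bigg")
    for directory in candidates:
        path = directory / f"{name}.json"
        if path.is_file():
            return path
    return None


def resolve_reaction(model: MetabolicModel, rid: str) -> str:
    """Resolve a published reaction name against the model's ids.

    Published tables sometimes carry suffixes (e.g. ``_1``) from the authors'
    irreversible conversion; strip a trailing ``_<digits>`` as a fallback.
    """
    if model.has_reaction(rid):
        return rid
    base, _, suffix = rid.rpartition("_")
    if suffix.isdigit() and model.has_reaction(base):
        return base
    raise UnknownReactionError(f"reaction {rid!r} not found in {model.model_id}")


def _resolve_first(model: MetabolicModel, candidates: list[str], what: str) -> str:
    for rid in candidates:
        if model.has_reaction(rid):
            return rid
    raise UnknownReactionError(f"no {what} reaction among {candidates} in {model.model_id}")


def biomass_reaction(model: MetabolicModel) -> str:
    import numpy as np

    nz = np.flatnonzero(model.objective_coeffs)
    if len(nz) == 0:
        raise ValueError("model declares no objective reaction")
    return model.reaction_ids[int(nz[0])]


def prepare_bigg_model(
    name: str, aerobic: bool = True, glucose_uptake: float = GLUCOSE_UPTAKE
) -> tuple[MetabolicModel, dict[str, str]]:
    """Load a BiGG model and apply the benchmark glucose minimal medium.

    Returns the irreversible, medium-applied model and an id map with keys
    ``biomass``, ``glucose``, ``oxygen``.  Anaerobiosis closes oxygen uptake
    for the bacterium and deletes cytochrome c oxidase for the yeast.
    """
    path = find_model_file(name)
    if path is None:
        raise FileNotFoundError(
            f"{name}.json not found; fetch it with scripts/fetch_models.py or set "
            "OPTENVELOPE_MODEL_DIR"
        )
    model = to_irreversible(load_model(str(path), "json"))
    bio = biomass_reaction(model)
    model = classify_roles(
        model,
        RoleConfig(
            biomass_id=bio,
            maintenance_ids=[r for r in ("ATPM",) if model.has_reaction(r)],
        ),
    )
    glc = _resolve_first(model, _GLC_IDS, "glucose exchange")
    o2 = _resolve_first(model, _O2_IDS, "oxygen exchange")
    deletions: list[str] = []
    oxygen_exchange = None
    if not aerobic:
        if name.startswith("iMM904"):
            found = [r for r in _YEAST_OXIDASE_IDS if model.has_reaction(r)]
            if found:
                deletions = found[:1]
            else:
                oxygen_exchange = o2
        else:
            oxygen_exchange = o2
    medium = MediumSpec(
        substrate_exchange=glc,
        substrate_uptake=glucose_uptake,
        free_exchanges="auto-inorganic",
        aerobic=aerobic,
        oxygen_exchange=oxygen_exchange,
        anaerobic_deletions=deletions,
    )
    model = apply_medium(model, medium)
    return model, {"biomass": bio, "glucose": glc, "oxygen": o2}


# ---------------------------------------------------------------------------
# Recomputed benchmark quantities (plain LP; no MILP, hence deterministic)
# ---------------------------------------------------------------------------

def max_growth(model: MetabolicModel, ids: dict[str, str]) -> float:
    return fba(model, ids["biomass"])[0]


def knocked(model: MetabolicModel, design: list[str]) -> MetabolicModel:
    out = model.copy()
    out.knock_out([resolve_reaction(model, r) for r in design])
    return out


def production_range_at_zero_growth(model, ids, product_id) -> tuple[float, float]:
    return flux_range(model, product_id, fixed=[(ids["biomass"], 0.0)])


def production_at_max_growth(model, ids, product_id) -> tuple[float, float, float]:
    """(max growth, min product, max product) at the growth optimum."""
    g = max_growth(model, ids)
    lo, hi = flux_range(model, product_id, fixed=[(ids["biomass"], g)])
    return g, lo, hi


def max_product_yield(model, ids, product_id, product_mw, uptake=GLUCOSE_UPTAKE) -> float:
    rate, _ = fba(model, product_id, "max")
    return to_yield_units(rate, product_mw, uptake, MOLECULAR_WEIGHTS["glucose"])
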