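"""Constraint-based model I/O, irreversible conversion, media and reaction roles.

The in-memory representation is a plain stoichiometric-matrix model
(:class:`MetabolicModel`).  SBML (Level 3 + FBC) and BiGG-style JSON files are
parsed with cobrapy and converted; BiGG-style JSON can also be written back so
synthetic models round-trip through the same reader.

Reaction roles
--------------
``exchange``
    pseudo-reactions with a single nonzero stoichiometric entry; detected
    structurally.
``diffusion_transport``
    protein-free diffusion transports (CO2, O2, H2O, H+, NH4 and the like);
    not structurally detectable, supplied per model via :class:`RoleConfig`.
``biomass`` / ``maintenance``
    named in the config; maintenance reactions keep a positive lower bound.
``internal``
    everything else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MetabolicModel",
    "MediumSpec",
    "RoleConfig",
    "ModelReadError",
    "UnknownReactionError",
    "REVERSE_SUFFIX",
    "ROLES",
    "load_model",
    "save_json",
    "to_irreversible",
    "apply_medium",
    "classify_roles",
    "detect_exchanges",
    "inorganic_exchanges",
]

#: suffix appended to the backward half of a split reversible reaction
REVERSE_SUFFIX = "__rev"

ROLES = ("exchange", "diffusion_transport", "biomass", "maintenance", "internal")


class ModelReadError(ValueError):
    """The model file could not be parsed into a usable model."""


class UnknownReactionError(KeyError):
    """A configured reaction id does not exist in the model."""


@dataclass
class MetabolicModel:
    """Stoichiometric model: ``S v = 0``, ``lb <= v <= ub``, objective ``c.v``."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray                      # m x n
    lower_bounds: np.ndarray           # n
    upper_bounds: np.ndarray           # n
    objective_coeffs: np.ndarray       # n
    reversible_pairs: dict[str, str] = field(default_factory=dict)   # fwd -> bwd
    roles: dict[str, str] = field(default_factory=dict)              # rxn -> role
    original_ids: dict[str, str] = field(default_factory=dict)       # split -> source
    metabolite_formulas: dict[str, str] = field(default_factory=dict)
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ValueError(
                f"S has shape {self.S.shape}, expected "
                f"({len(self.metabolite_ids)}, {len(self.reaction_ids)})"
            )
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelReadError("duplicate reaction ids")
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self._index[reaction_id]
        except KeyError:
            raise UnknownReactionError(reaction_id) from None

    def has_reaction(self, reaction_id: str) -> bool:
        return reaction_id in self._index

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_coeffs=self.objective_coeffs.copy(),
            reversible_pairs=dict(self.reversible_pairs),
            roles=dict(self.roles),
            original_ids=dict(self.original_ids),
            metabolite_formulas=dict(self.metabolite_formulas),
        )

    # -- split-pair bookkeeping -------------------------------------------
    def partner(self, reaction_id: str) -> str | None:
        """Other direction of a split reversible reaction, if any."""
        if reaction_id in self.reversible_pairs:
            return self.reversible_pairs[reaction_id]
        for fwd, bwd in self.reversible_pairs.items():
            if bwd == reaction_id:
                return fwd
        return None

    def source_id(self, reaction_id: str) -> str:
        """Id of the source (reversible-level) reaction of a split column."""
        return self.original_ids.get(reaction_id, reaction_id)

    def directions_of(self, source_id: str) -> list[str]:
        """All split columns belonging to one source reaction id."""
        cols = [r for r in self.reaction_ids if self.source_id(r) == source_id]
        if not cols:
            raise UnknownReactionError(source_id)
        return cols

    def knock_out(self, reaction_ids) -> None:
        """Zero both flux directions of each (source or split) reaction id."""
        for rid in reaction_ids:
            for col in self.directions_of(rid if not self.has_reaction(rid) else self.source_id(rid)):
                i = self.index(col)
                self.lower_bounds[i] = 0.0
                self.upper_bounds[i] = 0.0

    def restore_bounds_from(self, other: "MetabolicModel", reaction_ids) -> None:
        """Reset bounds of the given source reactions to ``other``'s values."""
        for rid in reaction_ids:
            for col in self.directions_of(rid):
                i = self.index(col)
                j = other.index(col)
                self.lower_bounds[i] = other.lower_bounds[j]
                self.upper_bounds[i] = other.upper_bounds[j]

    def reactions_with_role(self, role: str) -> list[str]:
        return [r for r in self.reaction_ids if self.roles.get(r) == role]


@dataclass
class MediumSpec:
    """Growth-medium description applied to exchange reactions.

    ``free_exchanges`` may be the literal string ``"auto-inorganic"`` to open
    every exchange of a carbon-free metabolite (requires formulas).
    """

    substrate_exchange: str
    substrate_uptake: float = 10.0
    free_exchanges: list[str] | str = field(default_factory=list)
    free_bound: float = 1000.0
    aerobic: bool = True
    oxygen_exchange: str | None = None
    anaerobic_deletions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.substrate_uptake <= 0:
            raise ValueError("substrate uptake bound must be > 0")


@dataclass
class RoleConfig:
    biomass_id: str
    maintenance_ids: list[str] = field(default_factory=list)
    diffusion_transport_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

def _from_cobra(cmodel) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    metabolite_ids = [m.id for m in cmodel.metabolites]
    reaction_ids = [r.id for r in cmodel.reactions]
    if not reaction_ids:
        raise ModelReadError("model contains no reactions")
    S = create_stoichiometric_matrix(cmodel, array_type="dense")
    lb = np.array([r.lower_bound for r in cmodel.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cmodel.reactions], dtype=float)
    obj = np.array([r.objective_coefficient for r in cmodel.reactions], dtype=float)
    formulas = {
        m.id: m.formula for m in cmodel.metabolites if getattr(m, "formula", None)
    }
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective_coeffs=obj,
        metabolite_formulas=formulas,
        model_id=cmodel.id or "model",
    )


def load_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read an SBML L3/FBC or BiGG-style JSON model file.

    Gene metadata is ignored; ids, stoichiometry, bounds and the objective are
    preserved verbatim.  ``format`` defaults to the file extension.
    """
    import cobra.io

    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "sbml"
    if format not in ("sbml", "json"):
        raise ValueError(f"unknown model format {format!r}")
    try:
        if format == "json":
            cmodel = cobra.io.load_json_model(path)
        else:
            cmodel = cobra.io.read_sbml_model(path)
    except (OSError, ValueError, KeyError) as exc:
        raise ModelReadError(f"cannot read model file {path}: {exc}") from exc
    except Exception as exc:  # cobra raises its own CobraSBMLError subclass
        raise ModelReadError(f"cannot read model file {path}: {exc}") from exc
    return _from_cobra(cmodel)


def save_json(model: MetabolicModel, path: str) -> None:
    """Write a BiGG-style JSON file readable by :func:`load_model`."""
    mets = []
    compartments = set()
    for mid in model.metabolite_ids:
        compartment = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
        compartments.add(compartment)
        met = {"id": mid, "name": mid, "compartment": compartment}
        if mid in model.metabolite_formulas:
            met["formula"] = model.metabolite_formulas[mid]
        mets.append(met)
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: float(model.S[i, j])
            for i in np.flatnonzero(model.S[:, j])
        }
        rxns.append(
            {
                "id": rid,
                "name": rid,
                "metabolites": stoich,
                "lower_bound": float(model.lower_bounds[j]),
                "upper_bound": float(model.upper_bounds[j]),
                "objective_coefficient": float(model.objective_coeffs[j]),
                "gene_reaction_rule": "",
            }
        )
    doc = {
        "id": model.model_id,
        "metabolites": mets,
        "reactions": rxns,
        "genes": [],
        "compartments": {c: c for c in sorted(compartments)},
        "version": "1",
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Irreversible conversion
# ---------------------------------------------------------------------------

def to_irreversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reaction with a negative lower bound into fwd/bwd halves.

    The forward half keeps the original id and bounds ``[max(lb,0), max(ub,0)]``;
    the backward half gets the ``__rev`` suffix, the negated column and bounds
    ``[max(-ub,0), -lb]``.  Applying the operation twice is the identity.
    """
    if np.all(model.lower_bounds >= 0):
        return model.copy()

    met_ids = list(model.metabolite_ids)
    rxn_ids: list[str] = []
    cols: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []
    objs: list[float] = []
    pairs = dict(model.reversible_pairs)
    original = dict(model.original_ids)
    roles = {}

    for j, rid in enumerate(model.reaction_ids):
        lb, ub = model.lower_bounds[j], model.upper_bounds[j]
        col = model.S[:, j]
        role = model.roles.get(rid)
        if lb >= 0:
            rxn_ids.append(rid)
            cols.append(col.copy())
            lbs.append(lb)
            ubs.append(ub)
            objs.append(model.objective_coeffs[j])
            if role:
                roles[rid] = role
            continue
        bwd_id = rid + REVERSE_SUFFIX
        if bwd_id in model._index or bwd_id in rxn_ids:
            raise ModelReadError(f"reverse id {bwd_id} collides with an existing reaction")
        # forward half
        rxn_ids.append(rid)
        cols.append(col.copy())
        lbs.append(0.0)
        ubs.append(max(ub, 0.0))
        objs.append(model.objective_coeffs[j])
        # backward half
        rxn_ids.append(bwd_id)
        cols.append(-col)
        lbs.append(max(-ub, 0.0))
        ubs.append(-lb)
        objs.append(0.0)
        pairs[rid] = bwd_id
        src = model.original_ids.get(rid, rid)
        original[rid] = src
        original[bwd_id] = src
        if role:
            roles[rid] = role
            roles[bwd_id] = role

    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=np.column_stack(cols),
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        objective_coeffs=np.array(objs),
        reversible_pairs=pairs,
        roles=roles,
        original_ids=original,
        metabolite_formulas=dict(model.metabolite_formulas),
        model_id=model.model_id,
    )


# ---------------------------------------------------------------------------
# Exchanges and medium
# ---------------------------------------------------------------------------

def detect_exchanges(model: MetabolicModel) -> list[str]:
    """Reactions with a single nonzero stoichiometric entry (pseudo-reactions)."""
    nnz = np.count_nonzero(model.S, axis=0)
    return [model.reaction_ids[j] for j in np.flatnonzero(nnz == 1)]


def _carbon_free(formula: str) -> bool:
    # 'C' followed by a lowercase letter (Ca, Cl, Co, Cu ...) is not carbon
    for i, ch in enumerate(formula):
        if ch == "C" and not (i + 1 < len(formula) and formula[i + 1].islower()):
            return False
    return True


def inorganic_exchanges(model: MetabolicModel) -> list[str]:
    """Exchanges of metabolites whose formula contains no carbon."""
    out = []
    for rid in detect_exchanges(model):
        j = model.index(rid)
        i = int(np.flatnonzero(model.S[:, j])[0])
        formula = model.metabolite_formulas.get(model.metabolite_ids[i])
        if formula and _carbon_free(formula):
            out.append(rid)
    return out


def _uptake_columns(model: MetabolicModel, ex_id: str) -> list[int]:
    """Columns of this exchange (and its split partner) that import the metabolite."""
    cols = [ex_id]
    partner = model.partner(ex_id)
    if partner is not None:
        cols.append(partner)
    out = []
    for rid in cols:
        j = model.index(rid)
        i = int(np.flatnonzero(model.S[:, j])[0])
        if model.S[i, j] > 0:
            out.append(j)
    return out


def _set_uptake(model: MetabolicModel, ex_id: str, bound: float) -> None:
    up = _uptake_columns(model, ex_id)
    if up:
        for j in up:
            model.upper_bounds[j] = bound
            if model.lower_bounds[j] > bound:
                model.lower_bounds[j] = bound
    else:
        # unsplit exchange written as "met ->": uptake is negative flux
        j = model.index(ex_id)
        if model.lower_bounds[j] < 0 or bound > 0:
            model.lower_bounds[j] = -bound


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy with medium uptake bounds applied.

    The substrate uptake gets ``substrate_uptake``; the listed (or
    auto-detected inorganic) exchanges get ``free_bound``; the uptake of every
    other exchanged metabolite is set to zero.  Anaerobiosis either zeroes the
    oxygen uptake or deletes the configured reactions (both directions).
    """
    out = model.copy()
    exchanges = detect_exchanges(out)
    if out.roles:
        # single-entry sinks/demands classified otherwise (e.g. maintenance)
        # are not medium exchanges
        exchanges = [r for r in exchanges if out.roles.get(r) == "exchange"]
    exchange_sources = {out.source_id(r) for r in exchanges}

    if isinstance(medium.free_exchanges, str):
        if medium.free_exchanges != "auto-inorganic":
            raise ValueError(f"unknown free_exchanges mode {medium.free_exchanges!r}")
        free = {out.source_id(r) for r in inorganic_exchanges(out)}
    else:
        free = set(medium.free_exchanges)

    for rid in [medium.substrate_exchange, *free]:
        if not out.has_reaction(rid):
            raise UnknownReactionError(f"exchange {rid!r} not in model")
        if out.source_id(rid) not in exchange_sources:
            raise UnknownReactionError(f"{rid!r} is not an exchange reaction")

    seen_sources = set()
    for rid in exchanges:
        src = out.source_id(rid)
        if src in seen_sources:
            continue
        seen_sources.add(src)
        if src == medium.substrate_exchange:
            _set_uptake(out, rid, medium.substrate_uptake)
        elif src in free:
            _set_uptake(out, rid, medium.free_bound)
        else:
            _set_uptake(out, rid, 0.0)

    if not medium.aerobic:
        if medium.oxygen_exchange is not None:
            if not out.has_reaction(medium.oxygen_exchange):
                raise UnknownReactionError(medium.oxygen_exchange)
            _set_uptake(out, medium.oxygen_exchange, 0.0)
        for rid in medium.anaerobic_deletions:
            if not any(out.source_id(r) == rid for r in out.reaction_ids):
                raise UnknownReactionError(rid)
            out.knock_out([rid])
    return out


# ---------------------------------------------------------------------------
# Roles
# ---------------------------------------------------------------------------

def classify_roles(model: MetabolicModel, config: RoleConfig) -> MetabolicModel:
    """Return a copy with a total, disjoint role assigned to every reaction."""
    out = model.copy()
    if not out.has_reaction(config.biomass_id):
        raise UnknownReactionError(f"biomass reaction {config.biomass_id!r} not in model")
    roles = {rid: "internal" for rid in out.reaction_ids}
    for rid in detect_exchanges(out):
        roles[rid] = "exchange"
    for rid in config.diffusion_transport_ids:
        if out.has_reaction(rid):
            for col in out.directions_of(out.source_id(rid)):
                roles[col] = "diffusion_transport"
    for rid in config.maintenance_ids:
        if not out.has_reaction(rid):
            raise UnknownReactionError(f"maintenance reaction {rid!r} not in model")
        roles[rid] = "maintenance"
    for col in out.directions_of(out.source_id(config.biomass_id)):
        roles[col] = "biomass"
    out.roles = roles
    return out


def check_model_invariants(model: MetabolicModel, tol: float = 1e-12) -> None:
    """Raise AssertionError if structural invariants of the split form fail."""
    assert np.all(model.lower_bounds >= -tol), "negative lower bound in irreversible model"
    for fwd, bwd in model.reversible_pairs.items():
        a = model.S[:, model.index(fwd)]
        b = model.S[:, model.index(bwd)]
        assert np.allclose(a, -b, atol=tol), f"{fwd}/{bwd} columns are not negatives"
    if model.roles:
        assert set(model.roles) == set(model.reaction_ids), "role map is not total"
        assert all(r in ROLES for r in model.roles.values()), "unknown role label"
        biomass_sources = {
            model.source_id(r) for r, role in model.roles.items() if role == "biomass"
        }
        assert len(biomass_sources) == 1, "expected exactly one biomass reaction"
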