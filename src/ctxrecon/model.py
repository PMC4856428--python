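"""Genome-scale metabolic model container, I/O and reversible-reaction splitting.

The model is the standard constraint-based object: a stoichiometric matrix S
(compounds x reactions), per-reaction flux bounds, reversibility flags, GPR
rules and a designated biomass reaction.  For the reconstruction LP every
reversible reaction is split into two irreversible *steps* (forward/backward)
so that all fluxes are non-negative.

Exchange convention: an exchange reaction exports its metabolite in the
forward direction (stoichiometry -1) and takes it up in the backward
direction; medium definitions therefore cap the backward (uptake) step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .gpr import GPRExpr, GPRParseError, gpr_genes, gpr_to_string, parse_gpr


class ModelFormatError(ValueError):
    """Malformed model file (bad JSON schema, unparsable GPR, ...)."""


class ConfigurationError(ValueError):
    """Inconsistent run configuration (unknown exchange id, missing biomass, ...)."""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]           # compound -> coefficient
    lower_bound: float
    upper_bound: float
    gpr: GPRExpr | None = None            # None == no gene association
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    compounds: list[str]
    reactions: list[Reaction]
    biomass_id: str | None = None

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._rxn_index) != len(self.reactions):
            raise ModelFormatError("duplicate reaction ids")
        self._cpd_index = {c: i for i, c in enumerate(self.compounds)}
        if len(self._cpd_index) != len(self.compounds):
            raise ModelFormatError("duplicate compound ids")

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= gpr_genes(r.gpr)
        return frozenset(out)

    def stoichiometric_matrix(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for cpd, coeff in rxn.stoich.items():
                if cpd not in self._cpd_index:
                    raise ModelFormatError(f"reaction {rxn.id!r} references unknown compound {cpd!r}")
                if coeff != 0:
                    rows.append(self._cpd_index[cpd])
                    cols.append(j)
                    vals.append(float(coeff))
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.compounds), len(self.reactions))
        )

    def validate(self, require_biomass: bool = True) -> None:
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelFormatError(f"reaction {rxn.id!r}: lower bound exceeds upper bound")
            if not rxn.is_exchange and not any(v != 0 for v in rxn.stoich.values()):
                raise ModelFormatError(f"reaction {rxn.id!r}: empty stoichiometry")
        if require_biomass:
            if self.biomass_id is None:
                raise ConfigurationError("model has no biomass reaction id")
            if self.biomass_id not in self._rxn_index:
                raise ConfigurationError(f"biomass reaction {self.biomass_id!r} not in model")


@dataclass(frozen=True)
class Step:
    """One irreversible direction of a parent reaction in the split model."""

    id: str
    parent_id: str
    forward: bool                       # False only for backward steps of reversibles
    upper: float


@dataclass
class SplitModel:
    parent: MetabolicModel
    steps: list[Step]
    pair_map: dict[str, str]            # forward step id -> backward step id

    def __post_init__(self) -> None:
        self._step_index = {s.id: i for i, s in enumerate(self.steps)}
        self._reverse_pair = {b: f for f, b in self.pair_map.items()}
        by_parent: dict[str, list[str]] = {}
        for s in self.steps:
            by_parent.setdefault(s.parent_id, []).append(s.id)
        self._steps_of_parent = by_parent

    @property
    def step_ids(self) -> list[str]:
        return [s.id for s in self.steps]

    def step(self, sid: str) -> Step:
        return self.steps[self._step_index[sid]]

    def step_index(self, sid: str) -> int:
        return self._step_index[sid]

    def steps_of(self, parent_id: str) -> list[str]:
        return self._steps_of_parent.get(parent_id, [])

    def partner(self, sid: str) -> str | None:
        return self.pair_map.get(sid) or self._reverse_pair.get(sid)

    @property
    def biomass_step(self) -> str:
        bid = self.parent.biomass_id
        if bid is None:
            raise ConfigurationError("model has no biomass reaction id")
        for sid in self.steps_of(bid):
            if self.step(sid).forward:
                return sid
        raise ConfigurationError(f"biomass reaction {bid!r} has no forward step")

    def upper_bounds(self) -> np.ndarray:
        return np.array([s.upper for s in self.steps])

    def stoichiometric_matrix(self) -> sp.csr_matrix:
        S = self.parent.stoichiometric_matrix().tocsc()
        cols = []
        for s in self.steps:
            col = S[:, self.parent._rxn_index[s.parent_id]]
            cols.append(col if s.forward else -col)
        return sp.hstack(cols, format="csr") if cols else sp.csr_matrix((len(self.parent.compounds), 0))

    def net_fluxes(self, v: Mapping[str, float]) -> dict[str, float]:
        """Map step fluxes back to signed net fluxes on the parent reactions."""
        net: dict[str, float] = {r.id: 0.0 for r in self.parent.reactions}
        for s in self.steps:
            net[s.parent_id] += float(v.get(s.id, 0.0)) * (1.0 if s.forward else -1.0)
        return net

    def with_step_uppers(self, overrides: Mapping[str, float]) -> "SplitModel":
        steps = [
            replace(s, upper=float(overrides[s.id])) if s.id in overrides else s
            for s in self.steps
        ]
        return SplitModel(self.parent, steps, dict(self.pair_map))


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Split every reversible reaction into non-negative forward/backward steps.

    A reversible parent with bounds [l, u] (l < 0) yields a forward step with
    upper bound u and a backward step with upper bound -l; irreversible parents
    contribute a single step.
    """
    steps: list[Step] = []
    pair_map: dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.reversible:
            fid, bid = f"{rxn.id}__fwd", f"{rxn.id}__bwd"
            steps.append(Step(fid, rxn.id, True, max(rxn.upper_bound, 0.0)))
            steps.append(Step(bid, rxn.id, False, -rxn.lower_bound))
            pair_map[fid] = bid
        else:
            steps.append(Step(rxn.id, rxn.id, True, rxn.upper_bound))
    return SplitModel(model, steps, pair_map)


def apply_medium(
    split: SplitModel,
    medium: Mapping[str, float],
    restrict_secretion: bool = False,
) -> SplitModel:
    """Constrain uptake steps of exchange reactions to a growth-medium definition.

    Exchange reactions absent from `medium` get uptake bound 0; listed ones get
    the given maximum uptake.  Secretion (export) directions are left open
    unless `restrict_secretion` is set.
    """
    exchange_ids = set(split.parent.exchange_ids)
    unknown = set(medium) - exchange_ids
    if unknown:
        raise ConfigurationError(f"medium lists non-exchange reactions: {sorted(unknown)}")
    overrides: dict[str, float] = {}
    for rid in exchange_ids:
        uptake_sid = _uptake_step(split, rid)
        bound = float(medium.get(rid, 0.0))
        if bound < 0:
            raise ConfigurationError(f"negative uptake bound for {rid!r}")
        if uptake_sid is not None:
            overrides[uptake_sid] = min(bound, split.step(uptake_sid).upper)
        elif bound > 0:
            raise ConfigurationError(
                f"exchange {rid!r} has no uptake direction but a medium bound was given"
            )
        if restrict_secretion:
            for sid in split.steps_of(rid):
                if sid != uptake_sid:
                    overrides[sid] = 0.0
    return split.with_step_uppers(overrides)


def _uptake_step(split: SplitModel, rid: str) -> str | None:
    """The step of exchange `rid` that imports (produces) its metabolite."""
    rxn = split.parent.reaction(rid)
    produces_fwd = any(c > 0 for c in rxn.stoich.values())
    for sid in split.steps_of(rid):
        s = split.step(sid)
        if s.forward == produces_fwd:
            return sid
    return None


# --------------------------------------------------------------------------
# JSON dialect I/O
#
# {"compounds": [...],
#  "reactions": [{"id", "stoich": {cpd: coeff}, "lb", "ub", "gpr", "is_exchange"}],
#  "biomass_id": ...}
# --------------------------------------------------------------------------

def model_from_dict(data: Mapping) -> MetabolicModel:
    try:
        compounds = list(data["compounds"])
        raw_reactions = data["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"missing required model key: {exc}") from exc
    reactions = []
    for raw in raw_reactions:
        rid = raw.get("id")
        if not rid:
            raise ModelFormatError("reaction without id")
        try:
            gpr = parse_gpr(raw.get("gpr") or "")
        except GPRParseError as exc:
            raise ModelFormatError(f"reaction {rid!r}: bad GPR: {exc}") from exc
        reactions.append(
            Reaction(
                id=str(rid),
                stoich={str(k): float(v) for k, v in (raw.get("stoich") or {}).items()},
                lower_bound=float(raw["lb"]),
                upper_bound=float(raw["ub"]),
                gpr=gpr,
                is_exchange=bool(raw.get("is_exchange", False)),
            )
        )
    model = MetabolicModel(compounds, reactions, biomass_id=data.get("biomass_id"))
    model.validate(require_biomass=False)
    return model


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "compounds": list(model.compounds),
        "reactions": [
            {
                "id": r.id,
                "stoich": {k: v for k, v in r.stoich.items()},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": gpr_to_string(r.gpr),
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "biomass_id": model.biomass_id,
    }


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML (L3 + fbc) or the JSON dialect; format inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON: {exc}") from exc
        return model_from_dict(data)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n")
    elif format == "sbml":
        _save_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def _load_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc
    compounds = [m.id for m in cmodel.metabolites]
    reactions = []
    for crxn in cmodel.reactions:
        try:
            gpr = parse_gpr(crxn.gene_reaction_rule or "")
        except GPRParseError as exc:
            raise ModelFormatError(f"reaction {crxn.id!r}: bad GPR: {exc}") from exc
        reactions.append(
            Reaction(
                id=crxn.id,
                stoich={m.id: coeff for m, coeff in crxn.metabolites.items()},
                lower_bound=float(crxn.lower_bound),
                upper_bound=float(crxn.upper_bound),
                gpr=gpr,
                is_exchange=crxn.boundary,
            )
        )
    biomass_id = None
    objective_rxns = [r.id for r in cmodel.reactions if r.objective_coefficient]
    if objective_rxns:
        biomass_id = objective_rxns[0]
    return MetabolicModel(compounds, reactions, biomass_id=biomass_id)


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra
    import cobra.io

    cmodel = cobra.Model("ctxrecon_export")
    mets = {c: cobra.Metabolite(c, compartment="c") for c in model.compounds}
    for rxn in model.reactions:
        crxn = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        cmodel.add_reactions([crxn])
        crxn.add_metabolites({mets[c]: v for c, v in rxn.stoich.items()})
        if rxn.gpr is not None:
            crxn.gene_reaction_rule = gpr_to_string(rxn.gpr)
    if model.biomass_id is not None:
        cmodel.objective = model.biomass_id
    cobra.io.write_sbml_model(cmodel, str(path))


def induced_submodel(model: MetabolicModel, included: Sequence[str] | set[str]) -> MetabolicModel:
    """Restrict a model to the given reactions (compounds trimmed to those referenced)."""
    keep = set(included)
    reactions = [r for r in model.reactions if r.id in keep]
    used = {c for r in reactions for c in r.stoich}
    compounds = [c for c in model.compounds if c in used]
    biomass = model.biomass_id if model.biomass_id in keep else None
    return MetabolicModel(compounds, reactions, biomass_id=biomass)


def load_medium_tsv(path: str | Path) -> dict[str, float]:
    """Read a growth medium as a 2-column TSV: exchange_id <TAB> max_uptake."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["exchange_id", "max_uptake"])
    # tolerate a header row
    if len(df) and not _is_number(df.iloc[0]["max_uptake"]):
        df = df.iloc[1:]
    return {str(r.exchange_id): float(r.max_uptake) for r in df.itertuples()}


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
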