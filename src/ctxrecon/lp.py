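"""Linear programming layer: FBA and FVA on split models.

All LPs are solved with HiGHS dual simplex through scipy.optimize.linprog,
single-threaded and with fixed options, so that optimal bases — and hence the
reduced costs the reconstruction iteration relies on — are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import SplitModel

FEAS_TOL_DEFAULT = 1e-9
ACT_TOL_DEFAULT = 1e-6


class InfeasibleProblemError(RuntimeError):
    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


class UnboundedProblemError(RuntimeError):
    pass


@dataclass
class LPResult:
    x: np.ndarray
    objective: float
    reduced_costs: np.ndarray    # lower + upper bound marginals per variable
    duals_eq: np.ndarray
    status: int


def solve_lp(
    c: np.ndarray,
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    A_ub: sp.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
) -> LPResult:
    """Minimize c.x s.t. A_eq x = b_eq, A_ub x <= b_ub, bounds; HiGHS dual simplex."""
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs-ds",
        options={"presolve": True},
    )
    if res.status == 2:
        raise InfeasibleProblemError(f"LP infeasible (HiGHS status {res.status})", res.status)
    if res.status == 3:
        raise UnboundedProblemError("LP unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solve failed with status {res.status}: {res.message}")
    reduced = res.lower.marginals + res.upper.marginals
    duals = res.eqlin.marginals if res.eqlin is not None else np.zeros(A_eq.shape[0])
    return LPResult(x=res.x, objective=float(res.fun), reduced_costs=reduced,
                    duals_eq=duals, status=res.status)


@dataclass
class FluxState:
    """Non-negative step fluxes of a split model plus the LP objective value."""

    v: dict[str, float]
    objective: float

    def as_array(self, split: SplitModel) -> np.ndarray:
        return np.array([self.v[sid] for sid in split.step_ids])


@dataclass
class FVAResult:
    vmax: dict[str, float]
    blocked: frozenset[str]

    def blocked_parents(self, split: SplitModel) -> frozenset[str]:
        """Parents all of whose steps are blocked (cannot carry flux either way)."""
        out = []
        for rid in split.parent.reaction_ids:
            sids = split.steps_of(rid)
            if sids and all(s in self.blocked for s in sids):
                out.append(rid)
        return frozenset(out)


def _base_bounds(split: SplitModel, overrides: Mapping[str, float] | None = None) -> list[tuple[float, float]]:
    bounds = []
    overrides = overrides or {}
    for s in split.steps:
        ub = overrides.get(s.id, s.upper)
        bounds.append((0.0, max(ub, 0.0)))
    return bounds


def fba_max(
    split: SplitModel,
    objective_step: str | None = None,
    fixed_off: Mapping[str, float] | None = None,
    min_biomass: float | None = None,
) -> FluxState:
    """Maximize flux through one step under steady state and step bounds.

    `fixed_off` overrides individual step upper bounds (e.g. knockouts);
    `min_biomass` adds the minimum-growth constraint when given.
    """
    if objective_step is None:
        objective_step = split.biomass_step
    n = len(split.steps)
    c = np.zeros(n)
    c[split.step_index(objective_step)] = -1.0
    S = split.stoichiometric_matrix()
    A_ub = b_ub = None
    if min_biomass is not None and min_biomass > 0:
        row = sp.csr_matrix(([-1.0], ([0], [split.step_index(split.biomass_step)])), shape=(1, n))
        A_ub, b_ub = row, np.array([-float(min_biomass)])
    res = solve_lp(c, S, np.zeros(S.shape[0]), _base_bounds(split, fixed_off), A_ub, b_ub)
    return FluxState(v=dict(zip(split.step_ids, res.x.tolist())), objective=-res.objective)


def compute_fva_max(
    split: SplitModel,
    vbiomass_star: float,
    feas_tol: float = FEAS_TOL_DEFAULT,
    steps: Sequence[str] | None = None,
) -> FVAResult:
    """Per-step maximum flux under steady state, bounds and biomass >= v*.

    One LP per step; a step whose maximum is <= feas_tol is blocked (it can
    never carry flux in any feasible state of the constrained model).
    """
    n = len(split.steps)
    S = split.stoichiometric_matrix()
    bounds = _base_bounds(split)
    A_ub = b_ub = None
    if vbiomass_star > 0:
        row = sp.csr_matrix(([-1.0], ([0], [split.step_index(split.biomass_step)])), shape=(1, n))
        A_ub, b_ub = row, np.array([-float(vbiomass_star)])
    # feasibility check first, with an actionable message
    try:
        fba_max(split, min_biomass=vbiomass_star or None)
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"FVA base problem infeasible at biomass >= {vbiomass_star}; lower v*",
            exc.status,
        ) from exc
    vmax: dict[str, float] = {}
    target = list(steps) if steps is not None else split.step_ids
    for sid in target:
        j = split.step_index(sid)
        if bounds[j][1] <= 0:
            vmax[sid] = 0.0
            continue
        c = np.zeros(n)
        c[j] = -1.0
        res = solve_lp(c, S, np.zeros(S.shape[0]), bounds, A_ub, b_ub)
        vmax[sid] = max(-res.objective, 0.0)
    blocked = frozenset(sid for sid, vm in vmax.items() if vm <= feas_tol)
    return FVAResult(vmax=vmax, blocked=blocked)
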