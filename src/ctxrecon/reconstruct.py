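"""Context-specific network extraction by weighted LP with reduced-cost iteration.

The reconstruction selects a subnetwork of a reference model that is
consistent with the ternary H/M/L reaction classification and can still grow:
it minimizes flux through lowly-expressed (L) and medium (M) reactions while
rewarding activation of highly-expressed (H) reactions, subject to steady
state, flux bounds and a minimum biomass flux v*:

    min  W_L * sum_{i in L} v_i/(delta*vmax_i)
       + W_M * sum_{i in M} v_i/(delta*vmax_i)
       - W_H * sum_{i in H} z_i
    s.t. S v = 0,  0 <= v_i <= vmax_i,  v_biomass >= v*,
         0 <= z_i <= 1,  delta*vmax_i*z_i <= v_i   (z only on H steps)

vmax_i comes from FVA, which makes both the activation threshold
(delta*vmax_i) and the objective independent of the stoichiometric scaling of
each reaction.  The z variables are continuous, so the problem stays a pure
LP; the price is that a reversible H reaction can "cheat" by running its
forward and backward steps simultaneously at zero net flux, collecting the z
reward for both directions (a spurious cycle).  Those pairs are eliminated
iteratively: detect both-directions-active H pairs, pick a direction to keep
(net-flux sign, or the more favourable z reduced cost when the net flux is
zero), fix the other direction off, and re-solve.  A final verification pass
re-admits a fixed-off direction if re-opening it (with its partner off) is at
least as good as the converged objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .classify import ReactionClassification
from .lp import (
    ACT_TOL_DEFAULT,
    FEAS_TOL_DEFAULT,
    FVAResult,
    FluxState,
    InfeasibleProblemError,
    compute_fva_max,
    fba_max,
    solve_lp,
)
from .model import MetabolicModel, SplitModel, apply_medium, induced_submodel, split_reversible

#: Table of weighting schemas (W_H, W_M, W_L) as multiples of (alpha, 1, alpha):
#: schema 1 favours excluding L, schema 3 favours including H, schema 2 is balanced.
SCHEMA_WEIGHTS = {
    1: lambda a: (a, 1.0, a**2),
    2: lambda a: (a, 1.0, a),
    3: lambda a: (a**2, 1.0, a),
}


class NonConvergenceError(RuntimeError):
    def __init__(self, message: str, iteration_log: list):
        super().__init__(message)
        self.iteration_log = iteration_log


@dataclass
class ReconstructionConfig:
    """Tunable parameters of the reconstruction LP.

    delta scales the activation threshold delta*vmax_i that links z_i to v_i;
    alpha sets the spread between the H/M/L weights; schema picks one of the
    three weighting schemas (or pass explicit weights); vbiomass_star is the
    required minimum biomass flux (None -> 1% of the wild-type maximum).
    """

    delta: float = 0.1
    alpha: float = 1e3
    schema: int = 3
    weights: tuple[float, float, float] | None = None   # (W_H, W_M, W_L), overrides schema
    vbiomass_star: float | None = None
    act_tol: float = ACT_TOL_DEFAULT
    feas_tol: float = FEAS_TOL_DEFAULT
    obj_tol: float = 1e-6
    max_iterations: int = 100
    fix_all_pairs_per_round: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.delta <= 1):
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if self.alpha <= 1:
            raise ValueError(f"alpha must exceed 1, got {self.alpha}")
        if self.weights is None and self.schema not in SCHEMA_WEIGHTS:
            raise ValueError(f"schema must be one of {sorted(SCHEMA_WEIGHTS)}, got {self.schema}")
        if self.weights is not None and any(w <= 0 for w in self.weights):
            raise ValueError("explicit weights must be positive")

    def resolved_weights(self) -> tuple[float, float, float]:
        if self.weights is not None:
            return self.weights
        return SCHEMA_WEIGHTS[self.schema](self.alpha)


@dataclass
class LPSolution:
    flux: FluxState
    z: dict[str, float]
    reduced_costs_v: dict[str, float]
    reduced_costs_z: dict[str, float]
    objective: float


@dataclass
class ReconstructionResult:
    included: frozenset[str]
    flux_witness: dict[str, float]          # signed net flux per included parent
    iteration_log: list[dict]
    coverage: dict[str, float | None]
    objective: float
    vbiomass_star: float
    final_z: dict[str, float]
    fixed_off: frozenset[str]


# ----------------------------- LP assembly -----------------------------

def _step_labels(split: SplitModel, classification: ReactionClassification) -> dict[str, str]:
    return {s.id: classification.label[s.parent_id] for s in split.steps}


def build_objective(
    split: SplitModel,
    classification: ReactionClassification,
    fva: FVAResult,
    config: ReconstructionConfig,
) -> tuple[dict[str, float], list[str]]:
    """Per-step flux costs and the list of H steps that carry a z variable.

    L and M steps get cost W/(delta*vmax_i); unblocked H steps get a z
    variable rewarded with -W_H; blocked steps carry no objective term (they
    are bound-fixed to zero).
    """
    w_h, w_m, w_l = config.resolved_weights()
    labels = _step_labels(split, classification)
    costs: dict[str, float] = {}
    z_steps: list[str] = []
    for s in split.steps:
        sid = s.id
        if sid in fva.blocked:
            continue
        vmax = fva.vmax[sid]
        if vmax <= config.feas_tol:
            raise RuntimeError(f"step {sid!r} has vmax ~ 0 but is not marked blocked")
        lab = labels[sid]
        if lab == "L":
            costs[sid] = w_l / (config.delta * vmax)
        elif lab == "M":
            costs[sid] = w_m / (config.delta * vmax)
        else:
            z_steps.append(sid)
    return costs, z_steps


def _solve_reconstruction_lp(
    split: SplitModel,
    fva: FVAResult,
    config: ReconstructionConfig,
    costs: Mapping[str, float],
    z_steps: Sequence[str],
    vbiomass_star: float,
    off: frozenset[str],
) -> LPSolution:
    w_h, _, _ = config.resolved_weights()
    step_ids = split.step_ids
    n = len(step_ids)
    active_z = [sid for sid in z_steps if sid not in off]
    z_col = {sid: n + k for k, sid in enumerate(active_z)}
    nvar = n + len(active_z)

    c = np.zeros(nvar)
    bounds: list[tuple[float, float]] = []
    for j, sid in enumerate(step_ids):
        ub = 0.0 if (sid in off or sid in fva.blocked) else fva.vmax[sid]
        bounds.append((0.0, ub))
        c[j] = costs.get(sid, 0.0)
    for sid in active_z:
        bounds.append((0.0, 1.0))
        c[z_col[sid]] = -w_h

    S = split.stoichiometric_matrix()
    A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], len(active_z)))], format="csr")
    b_eq = np.zeros(S.shape[0])

    rows, cols, vals = [], [], []
    b_ub_list = []
    r = 0
    # biomass >= v*
    rows.append(r); cols.append(split.step_index(split.biomass_step)); vals.append(-1.0)
    b_ub_list.append(-vbiomass_star)
    r += 1
    # delta*vmax*z <= v  per active H step
    for sid in active_z:
        j = split.step_index(sid)
        rows += [r, r]
        cols += [z_col[sid], j]
        vals += [config.delta * fva.vmax[sid], -1.0]
        b_ub_list.append(0.0)
        r += 1
    A_ub = sp.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    b_ub = np.array(b_ub_list)

    res = solve_lp(c, A_eq, b_eq, bounds, A_ub, b_ub)
    v = dict(zip(step_ids, res.x[:n].tolist()))
    z = {sid: float(res.x[z_col[sid]]) for sid in active_z}
    rc_v = dict(zip(step_ids, res.reduced_costs[:n].tolist()))
    rc_z = {sid: float(res.reduced_costs[z_col[sid]]) for sid in active_z}
    return LPSolution(
        flux=FluxState(v=v, objective=res.objective),
        z=z,
        reduced_costs_v=rc_v,
        reduced_costs_z=rc_z,
        objective=res.objective,
    )


def solve_relaxed_lp(
    split: SplitModel,
    classification: ReactionClassification,
    fva: FVAResult,
    config: ReconstructionConfig,
    vbiomass_star: float,
    off: frozenset[str] = frozenset(),
) -> LPSolution:
    """Solve the relaxed reconstruction LP (no spurious-pair elimination)."""
    costs, z_steps = build_objective(split, classification, fva, config)
    return _solve_reconstruction_lp(split, fva, config, costs, z_steps, vbiomass_star, off)


# ------------------------- spurious-pair handling -------------------------

def detect_spurious_pairs(
    sol: LPSolution,
    split: SplitModel,
    classification: ReactionClassification,
    config: ReconstructionConfig,
) -> list[tuple[str, str]]:
    """Reversible H reactions running both directions above act_tol.

    Ordered by descending min(v_f, v_b), ties broken by parent reaction id.
    """
    pairs = []
    for fid, bid in split.pair_map.items():
        parent = split.step(fid).parent_id
        if classification.label[parent] != "H":
            continue
        vf, vb = sol.flux.v.get(fid, 0.0), sol.flux.v.get(bid, 0.0)
        if vf > config.act_tol and vb > config.act_tol:
            pairs.append((min(vf, vb), parent, fid, bid))
    pairs.sort(key=lambda t: (-t[0], t[1]))
    return [(fid, bid) for _, _, fid, bid in pairs]


def _choose_direction(
    sol: LPSolution, fid: str, bid: str, act_tol: float
) -> tuple[str, str]:
    """(keep, drop) for a spurious pair.

    A clear net flux decides; otherwise the step whose z has the more
    favourable (more negative) reduced cost — the larger potential objective
    improvement from its activation — is kept.  Ties keep the forward step.
    """
    vf, vb = sol.flux.v.get(fid, 0.0), sol.flux.v.get(bid, 0.0)
    net = vf - vb
    if net > act_tol:
        return fid, bid
    if net < -act_tol:
        return bid, fid
    rc_f = sol.reduced_costs_z.get(fid, 0.0)
    rc_b = sol.reduced_costs_z.get(bid, 0.0)
    if rc_b < rc_f - 1e-12:
        return bid, fid
    return fid, bid


def iterative_reconstruct(
    split: SplitModel,
    classification: ReactionClassification,
    fva: FVAResult,
    config: ReconstructionConfig,
    vbiomass_star: float,
) -> ReconstructionResult:
    """Run the full reduced-cost guided iteration and extract the subnetwork."""
    costs, z_steps = build_objective(split, classification, fva, config)

    def solve(off: frozenset[str]) -> LPSolution:
        return _solve_reconstruction_lp(split, fva, config, costs, z_steps, vbiomass_star, off)

    off: frozenset[str] = frozenset()
    drop_order: list[str] = []
    log: list[dict] = []
    sol = solve(off)
    iteration = 0
    while True:
        pairs = detect_spurious_pairs(sol, split, classification, config)
        if not pairs:
            break
        iteration += 1
        if iteration > config.max_iterations:
            raise NonConvergenceError(
                f"spurious pairs persist after {config.max_iterations} iterations", log
            )
        if not config.fix_all_pairs_per_round:
            pairs = pairs[:1]
        fixed = []
        new_off = set(off)
        for fid, bid in pairs:
            keep, drop = _choose_direction(sol, fid, bid, config.act_tol)
            new_off.add(drop)
            drop_order.append(drop)
            fixed.append({"parent": split.step(fid).parent_id, "kept": keep, "dropped": drop})
        off = frozenset(new_off)
        sol = solve(off)
        log.append({"iteration": iteration, "fixed": fixed, "objective": sol.objective})

    # Verification pass: re-open each fixed-off direction with its partner off;
    # re-admit when that orientation is at least as good as the converged one.
    readmitted = []
    for drop in list(drop_order):
        if drop not in off:
            continue
        partner = split.partner(drop)
        candidate = frozenset((set(off) - {drop}) | {partner})
        try:
            alt = solve(candidate)
        except InfeasibleProblemError:
            continue
        tol = config.obj_tol * max(1.0, abs(sol.objective))
        if alt.objective <= sol.objective + tol and alt.z.get(drop, 0.0) > config.feas_tol:
            off = candidate
            sol = alt
            readmitted.append({"readmitted": drop, "objective": alt.objective})
            # a re-admission can surface new spurious pairs; clean them up
            while True:
                pairs = detect_spurious_pairs(sol, split, classification, config)
                if not pairs:
                    break
                iteration += 1
                if iteration > config.max_iterations:
                    raise NonConvergenceError("non-convergence after re-admission", log)
                keep, drop2 = _choose_direction(sol, *pairs[0], config.act_tol)
                off = frozenset(set(off) | {drop2})
                sol = solve(off)
    if readmitted:
        log.append({"iteration": iteration, "fixed": [], "objective": sol.objective,
                    "readmitted": readmitted})

    net = split.net_fluxes(sol.flux.v)
    included = {rid for rid, f in net.items() if abs(f) > config.act_tol}
    included.add(split.parent.biomass_id)
    coverage = compute_coverage(included, classification, fva, split)
    return ReconstructionResult(
        included=frozenset(included),
        flux_witness={rid: net[rid] for rid in sorted(included)},
        iteration_log=log,
        coverage=coverage,
        objective=sol.objective,
        vbiomass_star=vbiomass_star,
        final_z=dict(sol.z),
        fixed_off=off,
    )


def compute_coverage(
    included: set[str] | frozenset[str],
    classification: ReactionClassification,
    fva: FVAResult,
    split: SplitModel,
) -> dict[str, float | None]:
    """Fraction of H and of L reactions retained, plus the feasibility ceiling.

    The ceiling is the fraction of H reactions that are not FVA-blocked under
    the medium — the best any reconstruction could reach.
    """
    blocked_parents = fva.blocked_parents(split)
    out: dict[str, float | None] = {}
    for lab in ("H", "L"):
        members = classification.reactions_with(lab)
        if not members:
            out[f"{lab}_coverage"] = None
            continue
        out[f"{lab}_coverage"] = len([r for r in members if r in included]) / len(members)
    h_members = classification.reactions_with("H")
    out["H_ceiling"] = (
        len([r for r in h_members if r not in blocked_parents]) / len(h_members)
        if h_members else None
    )
    return out


# ----------------------------- orchestration -----------------------------

def reconstruct(
    model: MetabolicModel,
    classification: ReactionClassification,
    medium: Mapping[str, float] | None = None,
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """End-to-end reconstruction: split, medium, v*, FVA, iterate, extract."""
    config = config or ReconstructionConfig()
    model.validate(require_biomass=True)
    split = split_reversible(model)
    if medium is not None:
        split = apply_medium(split, medium)
    vstar = resolve_vbiomass_star(split, config)
    fva = compute_fva_max(split, vstar, feas_tol=config.feas_tol)
    return iterative_reconstruct(split, classification, fva, config, vstar)


def resolve_vbiomass_star(split: SplitModel, config: ReconstructionConfig) -> float:
    """Configured v*, or 1% of the wild-type maximum biomass flux."""
    if config.vbiomass_star is not None:
        return float(config.vbiomass_star)
    wt = fba_max(split).objective
    if wt <= config.feas_tol:
        raise InfeasibleProblemError(
            "wild-type model cannot produce biomass under the given medium"
        )
    return 0.01 * wt


def subnetwork_biomass(model: MetabolicModel, result: ReconstructionResult) -> float:
    """Maximum biomass of the extracted subnetwork alone (validity check)."""
    sub = induced_submodel(model, result.included)
    sub.validate(require_biomass=True)
    return fba_max(split_reversible(sub)).objective
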