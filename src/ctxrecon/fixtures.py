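"""Synthetic models, expression profiles and exact oracles.

Everything here is generated programmatically so the whole pipeline is
testable without any external model or dataset:

* a hand-built 11-reaction network (10 reactions + biomass) whose relaxed
  reconstruction LP provably activates spurious net-zero cycles of reversible
  highly-expressed reactions — the canonical failure mode the iterative
  procedure exists to fix;
* a seeded random-model generator with planted structures (feasible biomass
  path, isolated reversible H pair, isozyme pair, blocked branch);
* a designed cohort model in which the H/L trade-off of the weighting
  schemas and context-dependent essentiality are built in by construction;
* a binary-z MILP oracle that solves the reconstruction problem exactly
  (with explicit one-direction-at-a-time constraints on reversible pairs)
  for gap measurement against the iterative LP heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .classify import ExpressionProfile, ReactionClassification
from .lp import FVAResult
from .model import MetabolicModel, Reaction, SplitModel
from .gpr import parse_gpr
from .reconstruct import ReconstructionConfig, build_objective


# ----------------------- the spurious-cycle showcase -----------------------

#: gene calls that reproduce the intended H/M/L labels through the GPRs:
#: H genes present (+1), L genes absent (-1), M reactions' genes unmeasured.
FIG1_CALLS = {"g3": 1, "g4": 1, "g5": 1, "g7": 1, "g9": 1, "g1": -1, "g6": -1}

FIG1_MEDIUM = {"r2": 10.0}

FIG1_LABELS = {
    "r1": "L", "r2": "M", "r3": "H", "r4": "H", "r5": "H",
    "r6": "L", "r7": "H", "r8": "M", "r9": "H", "r10": "M",
    "biomass": "M",
}


def make_fig1_analogue() -> tuple[MetabolicModel, ReactionClassification]:
    """Ten reactions plus biomass, engineered to exhibit spurious H cycles.

    Biomass requires precursors P and Q; the only sensible route is uptake of
    A (r2, M), conversion A->B (r3, H), B->P (r5, H) and the *backward*
    direction of the reversible r7 (H) for B->Q.  Reversible H reactions r4
    (D1<->D2) and r9 (E1<->E2) touch metabolites with no other producer or
    consumer, so they can only ever run as forward+backward cycles with zero
    net flux — exactly the configuration the relaxed LP rewards and the
    iterative procedure must eliminate.  r1 (L) is a worse route to P, r6 (L)
    is a dead end (FVA-blocked), r8/r10 (M) an optional secretion route.
    """
    def rxn(rid, stoich, lb, ub, gene=None, exchange=False):
        return Reaction(rid, stoich, lb, ub,
                        gpr=parse_gpr(gene) if gene else None, is_exchange=exchange)

    compounds = ["A", "B", "D1", "D2", "E1", "E2", "E3", "P", "Q", "W"]
    reactions = [
        rxn("r1", {"B": -1, "P": 1}, 0, 1000, gene="g1"),
        rxn("r2", {"A": -1}, -10, 1000, gene="g2", exchange=True),
        rxn("r3", {"A": -1, "B": 1}, 0, 1000, gene="g3"),
        rxn("r4", {"D1": -1, "D2": 1}, -1000, 1000, gene="g4"),
        rxn("r5", {"B": -1, "P": 1}, 0, 1000, gene="g5"),
        rxn("r6", {"B": -1, "E3": 1}, 0, 1000, gene="g6"),
        rxn("r7", {"Q": -1, "B": 1}, -1000, 1000, gene="g7"),
        rxn("r8", {"P": -1, "W": 1}, 0, 1000, gene="g8"),
        rxn("r9", {"E1": -1, "E2": 1}, -1000, 1000, gene="g9"),
        rxn("r10", {"W": -1}, 0, 1000, gene="g10", exchange=True),
        rxn("biomass", {"P": -1, "Q": -1}, 0, 1000),
    ]
    model = MetabolicModel(compounds, reactions, biomass_id="biomass")
    model.validate()
    return model, ReactionClassification(dict(FIG1_LABELS))


# -------------------------- random fixture models --------------------------

class FixtureGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random synthetic model + expression profile."""

    n_metabolites: int = 8
    n_reactions: int = 15
    reversible_fraction: float = 0.4
    h_fraction: float = 0.45
    l_fraction: float = 0.25
    uptake_bound: float = 10.0
    seed: int = 0
    plant_iso_pair: bool = True          # isolated reversible H pair
    plant_isozyme: bool = True           # backbone reaction with an OR of two genes
    plant_blocked: bool = True           # dead-end branch (FVA-blocked)

    def __post_init__(self) -> None:
        if self.h_fraction + self.l_fraction > 1:
            raise FixtureGenerationError("h_fraction + l_fraction must not exceed 1")
        if self.n_metabolites < 4 or self.n_reactions < 5:
            raise FixtureGenerationError("fixture too small for the planted biomass path")


def make_random_fixture(
    spec: FixtureSpec,
) -> tuple[MetabolicModel, ExpressionProfile, dict]:
    """Seeded random model with a planted feasible biomass path.

    The backbone (uptake -> M0 -> M1 -> M2 -> biomass) is always present with
    classification-independent bounds, so every generated model can grow
    regardless of the expression profile.  Returns construction metadata
    naming the planted structures.
    """
    rng = np.random.default_rng(spec.seed)
    mets = [f"M{i}" for i in range(spec.n_metabolites)]
    calls: dict[str, int] = {}
    reactions: list[Reaction] = []
    meta: dict = {"backbone": [], "planted": {}}

    def add(rid, stoich, lb, ub, gene=None, exchange=False):
        reactions.append(
            Reaction(rid, stoich, lb, ub,
                     gpr=parse_gpr(gene) if gene else None, is_exchange=exchange)
        )

    add("EX_M0", {"M0": -1}, -spec.uptake_bound, 1000, exchange=True)
    add("b1", {"M0": -1, "M1": 1}, 0, 1000, gene="gb1")
    calls["gb1"] = 1
    if spec.plant_isozyme:
        add("b2", {"M1": -1, "M2": 1}, 0, 1000, gene="giso_a or giso_b")
        calls["giso_a"] = 1
        calls["giso_b"] = 1
        meta["planted"]["isozyme"] = ("b2", ("giso_a", "giso_b"))
    else:
        add("b2", {"M1": -1, "M2": 1}, 0, 1000, gene="gb2")
        calls["gb2"] = 1
    add("biomass", {"M2": -1}, 0, 1000)
    meta["backbone"] = ["EX_M0", "b1", "b2", "biomass"]

    extra_mets: list[str] = []
    if spec.plant_blocked:
        extra_mets.append("MBLK")
        add("blk", {"M1": -1, "MBLK": 1}, 0, 1000, gene="gblk")
        calls["gblk"] = 1
        meta["planted"]["blocked"] = "blk"
    if spec.plant_iso_pair:
        extra_mets += ["XA", "XB"]
        add("hp", {"XA": -1, "XB": 1}, -1000, 1000, gene="ghp")
        calls["ghp"] = 1
        meta["planted"]["iso_pair"] = "hp"

    n_random = spec.n_reactions - len(reactions)
    gene_counter = 0
    for k in range(max(n_random, 0)):
        a, b = rng.choice(len(mets), size=2, replace=False)
        reversible = rng.random() < spec.reversible_fraction
        u = rng.random()
        gene = None
        if u < spec.h_fraction:
            gene = f"gr{gene_counter}"
            calls[gene] = 1
        elif u < spec.h_fraction + spec.l_fraction:
            gene = f"gr{gene_counter}"
            calls[gene] = -1
        gene_counter += 1
        add(f"rx{k}", {mets[a]: -1, mets[b]: 1},
            -1000 if reversible else 0, 1000, gene=gene)

    model = MetabolicModel(mets + extra_mets, reactions, biomass_id="biomass")
    model.validate()
    return model, ExpressionProfile(gene_call=calls), meta


# ------------------------------ cohort model ------------------------------

#: genes whose calls are held fixed across the cohort; the parallel-path pair
#: (gp1 present / gp2 absent) plants a context-dependent essential gene, g0 a
#: structural one, and the lc*/hc* chains plant the schema trade-off:
#: chain 1 buys two H reactions with one L reaction, chain 2 buys one H with
#: two L.
COHORT_FIXED_CALLS = {
    "gp1": 1, "gp2": -1, "g0": 1,
    "gl1": -1, "gh1": 1, "gh2": 1,
    "gl2": -1, "gl3": -1, "gh3": 1,
}

#: peripheral AND-complex genes; all present in samples.  They pad the call
#: multiset so that absent calls stay a ~1/5 minority, as in typical
#: present/absent calling, which keeps the permutation background honest.
COHORT_PERIPHERAL_GENES = tuple(
    [f"ga{i}" for i in range(1, 7)] + [f"gb{i}" for i in range(1, 7)]
)

COHORT_MEDIUM = {"EX_A": 10.0}


def make_cohort_model() -> MetabolicModel:
    """Designed model for schema-trade-off and permutation-background studies."""
    def rxn(rid, stoich, lb, ub, gene=None, exchange=False):
        return Reaction(rid, stoich, lb, ub,
                        gpr=parse_gpr(gene) if gene else None, is_exchange=exchange)

    compounds = ["A", "B", "P", "C", "D", "E", "F", "G", "Hx", "X1", "X2"]
    per_a = " and ".join(f"ga{i}" for i in range(1, 7))
    per_b = " and ".join(f"gb{i}" for i in range(1, 7))
    reactions = [
        rxn("EX_A", {"A": -1}, -10, 1000, exchange=True),
        rxn("p1", {"A": -1, "B": 1}, 0, 1000, gene="gp1"),
        rxn("p2", {"A": -1, "B": 1}, 0, 1000, gene="gp2"),
        rxn("bm_pre", {"B": -1, "P": 1}, 0, 1000, gene="g0"),
        rxn("biomass", {"P": -1}, 0, 1000),
        # chain 1: one L reaction unlocks two H reactions
        rxn("lc1", {"A": -1, "C": 1}, 0, 1000, gene="gl1"),
        rxn("hc1", {"C": -1, "D": 1}, 0, 1000, gene="gh1"),
        rxn("hc2", {"D": -1, "E": 1}, 0, 1000, gene="gh2"),
        rxn("EX_E", {"E": -1}, 0, 1000, exchange=True),
        # chain 2: two L reactions unlock one H reaction
        rxn("lc2", {"A": -1, "F": 1}, 0, 1000, gene="gl2"),
        rxn("lc3", {"F": -1, "G": 1}, 0, 1000, gene="gl3"),
        rxn("hc3", {"G": -1, "Hx": 1}, 0, 1000, gene="gh3"),
        rxn("EX_H", {"Hx": -1}, 0, 1000, exchange=True),
        # peripheral secretion routes gated by AND complexes
        rxn("perA", {"A": -1, "X1": 1}, 0, 1000, gene=per_a),
        rxn("EX_X1", {"X1": -1}, 0, 1000, exchange=True),
        rxn("perB", {"A": -1, "X2": 1}, 0, 1000, gene=per_b),
        rxn("EX_X2", {"X2": -1}, 0, 1000, exchange=True),
    ]
    model = MetabolicModel(compounds, reactions, biomass_id="biomass")
    model.validate()
    return model


def make_cohort_profiles(n_profiles: int = 20, seed: int = 0) -> list[ExpressionProfile]:
    """Cohort of expression profiles over the cohort model's genes.

    Planted calls are fixed; one peripheral complex gene per profile is
    flipped absent at random so coverage varies across the cohort without
    touching the planted structures.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_profiles):
        calls = dict(COHORT_FIXED_CALLS)
        for g in COHORT_PERIPHERAL_GENES:
            calls[g] = 1
        flip = rng.integers(0, len(COHORT_PERIPHERAL_GENES))
        calls[COHORT_PERIPHERAL_GENES[flip]] = int(rng.choice([1, -1]))
        profiles.append(ExpressionProfile(gene_call=calls))
    return profiles


# ------------------------------- MILP oracle -------------------------------

class OracleUnavailableError(RuntimeError):
    """The MILP oracle hit its time limit; the instance has no exact reference."""


def milp_oracle(
    split: SplitModel,
    classification: ReactionClassification,
    fva: FVAResult,
    config: ReconstructionConfig,
    vbiomass_star: float,
    time_limit: float = 60.0,
) -> tuple[float, frozenset[str]]:
    """Exact reconstruction optimum with binary z and one-direction constraints.

    Same data and objective as the iterative LP, but z variables are binary
    and every reversible pair carries a binary direction selector y with
    v_f <= ub_f*y and v_b <= ub_b*(1-y), which makes simultaneous
    forward+backward activity (spurious cycles) structurally impossible.
    Returns (optimal objective, included parent reactions).
    """
    w_h, _, _ = config.resolved_weights()
    costs, z_steps = build_objective(split, classification, fva, config)
    step_ids = split.step_ids
    n = len(step_ids)
    z_col = {sid: n + k for k, sid in enumerate(z_steps)}
    pairs = sorted(split.pair_map.items())
    y_col = {fid: n + len(z_steps) + k for k, (fid, _) in enumerate(pairs)}
    nvar = n + len(z_steps) + len(pairs)

    c = np.zeros(nvar)
    lb = np.zeros(nvar)
    ub = np.zeros(nvar)
    integrality = np.zeros(nvar)
    for j, sid in enumerate(step_ids):
        ub[j] = 0.0 if sid in fva.blocked else fva.vmax[sid]
        c[j] = costs.get(sid, 0.0)
    for sid in z_steps:
        ub[z_col[sid]] = 1.0
        c[z_col[sid]] = -w_h
        integrality[z_col[sid]] = 1
    for fid, _ in pairs:
        ub[y_col[fid]] = 1.0
        integrality[y_col[fid]] = 1

    constraints = []
    S = split.stoichiometric_matrix()
    A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], nvar - n))], format="csr")
    constraints.append(LinearConstraint(A_eq, 0.0, 0.0))

    rows, cols, vals, clo, chi = [], [], [], [], []
    r = 0
    rows.append(r); cols.append(split.step_index(split.biomass_step)); vals.append(1.0)
    clo.append(vbiomass_star); chi.append(np.inf); r += 1
    for sid in z_steps:
        rows += [r, r]; cols += [z_col[sid], split.step_index(sid)]
        vals += [config.delta * fva.vmax[sid], -1.0]
        clo.append(-np.inf); chi.append(0.0); r += 1
    for fid, bid in pairs:
        jf, jb = split.step_index(fid), split.step_index(bid)
        uf = 0.0 if fid in fva.blocked else fva.vmax[fid]
        ubk = 0.0 if bid in fva.blocked else fva.vmax[bid]
        rows += [r, r]; cols += [jf, y_col[fid]]; vals += [1.0, -uf]
        clo.append(-np.inf); chi.append(0.0); r += 1
        rows += [r, r]; cols += [jb, y_col[fid]]; vals += [1.0, ubk]
        clo.append(-np.inf); chi.append(ubk); r += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    constraints.append(LinearConstraint(A, np.array(clo), np.array(chi)))

    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": time_limit, "mip_rel_gap": 1e-9},
    )
    if res.status == 1:  # iteration/time limit
        raise OracleUnavailableError(f"MILP oracle hit its limit: {res.message}")
    if not res.success:
        raise RuntimeError(f"MILP oracle failed: {res.message}")
    v = dict(zip(step_ids, res.x[:n]))
    net = split.net_fluxes(v)
    included = {rid for rid, f in net.items() if abs(f) > config.act_tol}
    included.add(split.parent.biomass_id)
    return float(res.fun), frozenset(included)


# ------------------------- representation rescaling -------------------------

def rescale_reaction(model: MetabolicModel, rid: str, k: float) -> MetabolicModel:
    """Equivalent model with reaction `rid` written at a different scale.

    Stoichiometric coefficients are multiplied by k and flux bounds divided
    by k, so the reaction moves the same mass at 1/k times the flux — the
    same chemistry under a different representation.  Reconstruction results
    must not depend on this choice.
    """
    if k <= 0:
        raise ValueError("scale factor must be positive")
    reactions = []
    for rxn in model.reactions:
        if rxn.id == rid:
            rxn = replace(
                rxn,
                stoich={c: v * k for c, v in rxn.stoich.items()},
                lower_bound=rxn.lower_bound / k,
                upper_bound=rxn.upper_bound / k,
            )
        reactions.append(rxn)
    return MetabolicModel(list(model.compounds), reactions, biomass_id=model.biomass_id)
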