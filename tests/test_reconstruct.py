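"""Reconstruction LP, spurious-pair iteration, coverage and invariances."""

import numpy as np
import pytest

from ctxrecon.classify import ReactionClassification
from ctxrecon.fixtures import (
    FIG1_MEDIUM,
    FixtureSpec,
    make_fig1_analogue,
    make_random_fixture,
    milp_oracle,
    rescale_reaction,
)
from ctxrecon.lp import compute_fva_max, fba_max
from ctxrecon.model import apply_medium, induced_submodel, split_reversible
from ctxrecon.reconstruct import (
    LPSolution,
    ReconstructionConfig,
    build_objective,
    detect_spurious_pairs,
    iterative_reconstruct,
    reconstruct,
    resolve_vbiomass_star,
    solve_relaxed_lp,
    subnetwork_biomass,
)
from ctxrecon.lp import FluxState


def _setup(model, classification, medium=None, config=None):
    config = config or ReconstructionConfig()
    split = split_reversible(model)
    if medium:
        split = apply_medium(split, medium)
    vstar = resolve_vbiomass_star(split, config)
    fva = compute_fva_max(split, vstar)
    return split, fva, vstar, config


def test_config_validation():
    with pytest.raises(ValueError, match="delta"):
        ReconstructionConfig(delta=0)
    with pytest.raises(ValueError, match="alpha"):
        ReconstructionConfig(alpha=1)
    with pytest.raises(ValueError, match="schema"):
        ReconstructionConfig(schema=4)
    assert ReconstructionConfig(schema=1).resolved_weights() == (1e3, 1.0, 1e6)
    assert ReconstructionConfig(schema=2).resolved_weights() == (1e3, 1.0, 1e3)
    assert ReconstructionConfig(schema=3).resolved_weights() == (1e6, 1.0, 1e3)
    assert ReconstructionConfig(weights=(2, 1, 4)).resolved_weights() == (2, 1, 4)


def test_objective_coefficients(fig1):
    """L/M step costs are W/(delta*vmax); H steps carry a z reward instead."""
    model, cls = fig1
    split, fva, vstar, cfg = _setup(model, cls, FIG1_MEDIUM,
                                    ReconstructionConfig(schema=1, delta=0.1))
    costs, z_steps = build_objective(split, cls, fva, cfg)
    # L step r1 with vmax 10: cost = alpha^2 / (0.1 * 10) = 1e6
    assert costs["r1"] == pytest.approx(1e6 / (0.1 * fva.vmax["r1"]))
    # H steps have no flux cost, only z
    assert "r3" not in costs and "r3" in z_steps
    # blocked step r6 has neither a cost nor a z variable
    assert "r6" not in costs and "r6" not in z_steps


def test_relaxed_lp_spurious_cycles(fig1, fig1_split):
    """The relaxed LP activates reversible H pairs in both directions at zero net flux."""
    model, cls = fig1
    cfg = ReconstructionConfig(schema=3)
    vstar = resolve_vbiomass_star(fig1_split, cfg)
    fva = compute_fva_max(fig1_split, vstar)
    sol = solve_relaxed_lp(fig1_split, cls, fva, cfg, vstar)
    pairs = detect_spurious_pairs(sol, fig1_split, cls, cfg)
    parents = {fig1_split.step(f).parent_id for f, _ in pairs}
    assert {"r4", "r9"} <= parents
    zero_net = [
        (f, b) for f, b in pairs
        if abs(sol.flux.v[f] - sol.flux.v[b]) <= cfg.act_tol
    ]
    assert len(zero_net) >= 2
    # all-H irreversible biomass route reaches full z
    assert sol.z["r3"] == pytest.approx(1.0)
    assert sol.z["r5"] == pytest.approx(1.0)


def test_detector_requires_both_directions(fig1_split, fig1):
    _, cls = fig1
    cfg = ReconstructionConfig()
    flux = {sid: 0.0 for sid in fig1_split.step_ids}
    flux.update({"r4__fwd": 2.0, "r4__bwd": 2.0, "r7__fwd": 2.0})
    sol = LPSolution(FluxState(flux, 0.0), {}, {}, {}, 0.0)
    pairs = detect_spurious_pairs(sol, fig1_split, cls, cfg)
    assert pairs == [("r4__fwd", "r4__bwd")]   # r7 active one-way only


def test_l_pairs_not_spurious(fig1, fig1_split):
    """Flux minimisation keeps reversible L/M reactions one-directional already."""
    model, cls = fig1
    relabeled = dict(cls.label, r4="L", r9="M")
    cls2 = ReactionClassification(relabeled)
    cfg = ReconstructionConfig(schema=3)
    vstar = resolve_vbiomass_star(fig1_split, cfg)
    fva = compute_fva_max(fig1_split, vstar)
    sol = solve_relaxed_lp(fig1_split, cls2, fva, cfg, vstar)
    for fid, bid in (("r4__fwd", "r4__bwd"), ("r9__fwd", "r9__bwd")):
        assert min(sol.flux.v[fid], sol.flux.v[bid]) <= cfg.act_tol


@pytest.mark.parametrize("schema", [1, 2, 3])
def test_fig1_iterative_reconstruction(fig1, schema):
    """Iteration removes all spurious pairs and lands on the M+H biomass route."""
    model, cls = fig1
    cfg = ReconstructionConfig(schema=schema)
    result = reconstruct(model, cls, medium=FIG1_MEDIUM, config=cfg)
    assert {"r2", "r3", "r5", "r7", "biomass"} <= result.included
    assert "r4" not in result.included and "r9" not in result.included
    assert "r1" not in result.included and "r6" not in result.included
    # no originally-reversible reaction retains both active directions
    assert result.flux_witness["r7"] < 0      # the backward (B->Q) direction
    # the extracted subnetwork grows on its own
    assert subnetwork_biomass(model, result) >= result.vbiomass_star - 1e-9


def test_no_futile_two_cycles_on_random_fixtures(random_fixture_factory):
    for seed in range(8):
        model, _, cls, _ = random_fixture_factory(seed)
        cfg = ReconstructionConfig(schema=3)
        split, fva, vstar, cfg = _setup(model, cls, None, cfg)
        result = iterative_reconstruct(split, cls, fva, cfg, vstar)
        # re-solve bookkeeping: reconstruct the final flux per step
        final = solve_relaxed_lp(split, cls, fva, cfg, vstar, off=result.fixed_off)
        for fid, bid in split.pair_map.items():
            assert min(final.flux.v[fid], final.flux.v[bid]) <= cfg.act_tol * (1 + 1e-6)


def test_subnetwork_validity_random_fixtures(random_fixture_factory):
    for seed in range(8):
        model, _, cls, _ = random_fixture_factory(seed)
        result = reconstruct(model, cls, config=ReconstructionConfig(schema=3))
        sub = induced_submodel(model, result.included)
        assert fba_max(split_reversible(sub)).objective >= result.vbiomass_star - 1e-9


@pytest.mark.parametrize("seed", range(20))
def test_milp_oracle_gap(seed, random_fixture_factory):
    """The iterative LP objective lands within 5% of the exact binary-z optimum."""
    model, _, cls, _ = random_fixture_factory(seed)
    cfg = ReconstructionConfig(schema=3)
    split, fva, vstar, cfg = _setup(model, cls, None, cfg)
    result = iterative_reconstruct(split, cls, fva, cfg, vstar)
    obj_milp, _ = milp_oracle(split, cls, fva, cfg, vstar)
    relaxed = solve_relaxed_lp(split, cls, fva, cfg, vstar)
    # relaxation bound: the LP without integrality is at least as good
    assert relaxed.objective <= obj_milp + 1e-6 * max(1, abs(obj_milp))
    gap = abs(result.objective - obj_milp) / max(abs(obj_milp), 1e-9)
    assert gap <= 0.05


def test_milp_oracle_trivial_two_reaction_model(chain_model):
    """Hand enumeration: the only growth-capable subset is the full chain."""
    cls = ReactionClassification({"EX_A": "M", "conv": "H", "biomass": "M"})
    cfg = ReconstructionConfig(schema=3, vbiomass_star=0.1)
    split = split_reversible(chain_model)
    fva = compute_fva_max(split, 0.1)
    obj, included = milp_oracle(split, cls, fva, cfg, 0.1)
    assert included == frozenset({"EX_A", "conv", "biomass"})
    result = iterative_reconstruct(split, cls, fva, cfg, 0.1)
    assert result.included == included
    assert result.objective == pytest.approx(obj, rel=1e-6)


@pytest.mark.parametrize("k", [0.1, 10.0])
def test_scale_invariance(k, fig1):
    """Rewriting a reaction at a different stoichiometric scale changes nothing."""
    model, cls = fig1
    cfg = ReconstructionConfig(schema=3, vbiomass_star=0.05)
    base = reconstruct(model, cls, medium=FIG1_MEDIUM, config=cfg)
    for rid in ("r3", "r7", "r1"):
        scaled = rescale_reaction(model, rid, k)
        got = reconstruct(scaled, cls, medium=FIG1_MEDIUM, config=cfg)
        assert got.included == base.included, f"rescaling {rid} by {k} changed the network"


def test_coverage_fields(fig1):
    model, cls = fig1
    result = reconstruct(model, cls, medium=FIG1_MEDIUM, config=ReconstructionConfig(schema=3))
    cov = result.coverage
    assert cov["H_coverage"] == pytest.approx(3 / 5)    # r3, r5, r7 of 5 H reactions
    assert cov["L_coverage"] == pytest.approx(0.0)
    assert cov["H_ceiling"] == pytest.approx(1.0)


def test_coverage_missing_when_no_h(chain_model):
    cls = ReactionClassification({"EX_A": "M", "conv": "M", "biomass": "M"})
    result = reconstruct(chain_model, cls, config=ReconstructionConfig(vbiomass_star=0.1))
    assert result.coverage["H_coverage"] is None


def test_feasibility_preserved_across_iterations(fig1):
    """Every iteration's LP stays feasible; the final objective is a valid bound."""
    model, cls = fig1
    cfg = ReconstructionConfig(schema=3)
    split, fva, vstar, cfg = _setup(model, cls, FIG1_MEDIUM, cfg)
    relaxed = solve_relaxed_lp(split, cls, fva, cfg, vstar)
    result = iterative_reconstruct(split, cls, fva, cfg, vstar)
    # minimization: fixing directions can only cost objective value
    assert result.objective >= relaxed.objective - 1e-6 * abs(relaxed.objective)
    assert result.iteration_log, "the showcase requires at least one fixing round"
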