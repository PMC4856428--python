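"""Permutation backgrounds, frequency tables and the one-sided KS machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ctxrecon.classify import ExpressionProfile
from ctxrecon.compare import (
    essentiality_frequency,
    ks_one_sided,
    negative_fraction,
    permute_calls,
)
from ctxrecon.essentiality import EssentialityTable, GeneRecord


def test_permutation_preserves_multiset_and_is_seeded():
    profile = ExpressionProfile(gene_call={"A": 1, "B": -1, "C": 1, "D": -1})
    perms1 = permute_calls(profile, {"A", "B", "C", "D"}, 10, seed=42)
    perms2 = permute_calls(profile, {"A", "B", "C", "D"}, 10, seed=42)
    assert len(perms1) == 10
    for p1, p2 in zip(perms1, perms2):
        assert p1.gene_call == p2.gene_call
        assert sorted(p1.gene_call.values()) == sorted(profile.gene_call.values())
    assert any(p.gene_call != profile.gene_call for p in perms1)


def test_permutation_restricted_to_metabolic_genes():
    profile = ExpressionProfile(gene_call={"A": 1, "B": -1, "X": -1})
    for p in permute_calls(profile, {"A", "B"}, 20, seed=1):
        assert p.gene_call["X"] == -1                       # untouched
        assert sorted([p.gene_call["A"], p.gene_call["B"]]) == [-1, 1]


def test_permutation_rejects_bad_n():
    profile = ExpressionProfile(gene_call={"A": 1})
    with pytest.raises(ValueError):
        permute_calls(profile, {"A"}, 0, seed=0)


def _table(essential: dict[str, bool]) -> EssentialityTable:
    return EssentialityTable(
        [GeneRecord(g, e, 0.0 if e else 1.0, False) for g, e in essential.items()],
        wild_type_biomass=1.0,
    )


def test_essentiality_frequency():
    samples = [_table({"g1": True, "g2": False})] * 3 + [_table({"g1": False, "g2": False})]
    randoms = [_table({"g1": False, "g2": True})] * 2
    freq = essentiality_frequency(samples, randoms)
    assert freq.sample_frequency["g1"] == pytest.approx(0.75)
    assert freq.random_frequency["g2"] == pytest.approx(1.0)
    assert freq.n_sample == 4 and freq.n_random == 2
    # order invariance
    freq2 = essentiality_frequency(list(reversed(samples)), randoms)
    assert freq2.sample_frequency == freq.sample_frequency


def test_frequency_gene_missing_from_some_networks():
    """The denominator is the number of networks, not per-gene appearances."""
    samples = [_table({"g1": True}), _table({"g2": False})]
    freq = essentiality_frequency(samples, [_table({"g1": False})])
    assert freq.sample_frequency["g1"] == pytest.approx(0.5)


# ------------------------------ KS statistics ------------------------------

def _enumeration_oracle(ess, oth):
    """Independent exact p: all label assignments of the pooled sample."""
    pooled = list(ess) + list(oth)
    m = len(ess)

    def dplus(group1, group2):
        best = 0.0
        for x in pooled:
            f1 = sum(1 for v in group1 if v <= x) / len(group1)
            f2 = sum(1 for v in group2 if v <= x) / len(group2)
            best = max(best, f1 - f2)
        return best

    observed = dplus(ess, oth)
    hits = total = 0
    for labels in itertools.combinations(range(len(pooled)), m):
        chosen = set(labels)
        g1 = [pooled[i] for i in range(len(pooled)) if i in chosen]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if dplus(g1, g2) >= observed - 1e-12:
            hits += 1
    return observed, hits / total


def test_ks_identical_samples():
    d, p = ks_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert d == 0.0 and p == 1.0


def test_ks_fully_separated():
    d, p = ks_one_sided([-5, -4, -3, -2, -1], [1, 2, 3, 4, 5])
    assert d == 1.0
    assert p == pytest.approx(1 / math.comb(10, 5))


@pytest.mark.parametrize("m, n, seed", [(3, 4, 0), (4, 4, 1), (5, 6, 2), (2, 7, 3), (6, 6, 4)])
def test_ks_exact_matches_enumeration(m, n, seed):
    rng = np.random.default_rng(seed)
    ess = rng.normal(-0.5, 1, m).tolist()
    oth = rng.normal(0.5, 1, n).tolist()
    d, p = ks_one_sided(ess, oth)
    d_ref, p_ref = _enumeration_oracle(ess, oth)
    assert d == pytest.approx(d_ref, abs=1e-12)
    assert p == pytest.approx(p_ref, abs=1e-12)


def test_ks_exact_with_ties():
    ess, oth = [1.0, 1.0, 2.0], [1.0, 2.0, 3.0]
    d, p = ks_one_sided(ess, oth)
    d_ref, p_ref = _enumeration_oracle(ess, oth)
    assert (d, p) == (pytest.approx(d_ref), pytest.approx(p_ref))


def test_ks_statistic_matches_scipy():
    rng = np.random.default_rng(5)
    ess, oth = rng.normal(-1, 1, 12), rng.normal(0, 1, 15)
    d, _ = ks_one_sided(ess, oth)
    assert d == pytest.approx(
        stats.ks_2samp(ess, oth, alternative="greater").statistic
    )


def test_ks_asymptotic_formula_and_monotonicity():
    rng = np.random.default_rng(6)
    ess, oth = rng.normal(-1, 1, 20).tolist(), rng.normal(0, 1, 20).tolist()
    d, p = ks_one_sided(ess, oth)                   # m + n > 16 -> asymptotic
    m = n = 20
    assert p == pytest.approx(min(1.0, math.exp(-2 * m * n * d * d / (m + n))))
    # p decreases as D+ increases at fixed sample sizes
    shifted = [x - 5 for x in ess]
    d2, p2 = ks_one_sided(shifted, oth)
    assert d2 >= d and p2 <= p


def test_ks_rejects_empty():
    with pytest.raises(ValueError):
        ks_one_sided([], [1.0])


def test_negative_fraction():
    scores = {"g1": -1.0, "g2": 2.0, "g3": -3.0, "g4": 4.0}
    assert negative_fraction(scores, {"g1", "g2", "g3", "g4"}) == pytest.approx(0.5)
    assert negative_fraction({"g": -0.1}, {"g"}) == 1.0
    assert negative_fraction({"g": 0.0}, {"g"}) == 0.0   # zero counts non-negative
    # unscored genes are excluded from the denominator
    assert negative_fraction(scores, {"g1", "unscored"}) == 1.0
    with pytest.raises(ValueError):
        negative_fraction(scores, {"unscored"})
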