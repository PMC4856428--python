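"""Permutation backgrounds and comparison against external essentiality scores.

To separate genuinely context-dependent essential genes from artifacts of the
reference network, medium and biomass reaction, the gene expression calls of
each sample are randomly permuted among the metabolic genes (preserving the
multiset of calls) and the whole reconstruction + essentiality pipeline is
re-run on each permuted profile.  Per-gene essentiality frequencies in the
sample-derived and random groups are then compared, and predicted essential
genes are checked against external gene-silencing scores (lower = more
essential; score inputs are assumed already sign-flipped that way) with a
one-sided two-sample Kolmogorov-Smirnov test and a negative-score fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ExpressionProfile
from .essentiality import EssentialityTable

DEFAULT_N_PERMUTATIONS = 10   # permutations per sample used for the background
EXACT_KS_LIMIT = 16           # exact enumeration up to m + n of this size


@dataclass
class FrequencyTable:
    """Per-gene essentiality frequency in sample-derived vs random networks."""

    sample_frequency: dict[str, float]
    random_frequency: dict[str, float]
    n_sample: int
    n_random: int

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.sample_frequency) | set(self.random_frequency))
        return pd.DataFrame(
            {
                "gene_id": genes,
                "sample_frequency": [self.sample_frequency.get(g, 0.0) for g in genes],
                "random_frequency": [self.random_frequency.get(g, 0.0) for g in genes],
                "n_sample": self.n_sample,
                "n_random": self.n_random,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ScoreComparison:
    ks_statistic: float
    ks_pvalue: float
    negative_fraction_essential: float
    negative_fraction_all: float


def permute_calls(
    profile: ExpressionProfile,
    metabolic_genes: Iterable[str],
    n_permutations: int,
    seed: int,
) -> list[ExpressionProfile]:
    """Shuffle the +/-1 calls among the metabolic genes, n times.

    Only genes both in the profile and in `metabolic_genes` take part; the
    multiset of their calls is preserved exactly.  Deterministic given `seed`.
    """
    if n_permutations <= 0:
        raise ValueError(f"n_permutations must be positive, got {n_permutations}")
    target = sorted(set(metabolic_genes) & set(profile.gene_call))
    missing = set(metabolic_genes) - set(profile.gene_call)
    if missing and not target:
        raise ValueError("no metabolic gene has a call in the profile")
    rng = np.random.default_rng(seed)
    values = np.array([profile.gene_call[g] for g in target])
    out = []
    for _ in range(n_permutations):
        shuffled = values[rng.permutation(len(values))]
        calls = dict(profile.gene_call)
        calls.update(dict(zip(target, (int(v) for v in shuffled))))
        out.append(ExpressionProfile(gene_call=calls))
    return out


def essentiality_frequency(
    sample_tables: Sequence[EssentialityTable],
    random_tables: Sequence[EssentialityTable],
    include_never_essential: bool = False,
) -> FrequencyTable:
    """Fraction of networks in each group where each gene is essential."""
    if not sample_tables or not random_tables:
        raise ValueError("each group needs at least one essentiality table")

    def freqs(tables: Sequence[EssentialityTable]) -> dict[str, float]:
        # denominator is the number of networks: a gene absent from a
        # reconstruction simply was not essential there
        counts: dict[str, int] = {}
        seen: set[str] = set()
        for t in tables:
            for r in t.records:
                seen.add(r.gene)
                if r.essential:
                    counts[r.gene] = counts.get(r.gene, 0) + 1
        return {g: counts.get(g, 0) / len(tables) for g in seen}

    sample_f = freqs(sample_tables)
    random_f = freqs(random_tables)
    if not include_never_essential:
        keep = {g for g, f in sample_f.items() if f > 0} | {
            g for g, f in random_f.items() if f > 0
        }
        sample_f = {g: sample_f.get(g, 0.0) for g in keep}
        random_f = {g: random_f.get(g, 0.0) for g in keep}
    return FrequencyTable(sample_f, random_f, len(sample_tables), len(random_tables))


# ------------------------- one-sided two-sample KS -------------------------

def _dplus(essential: np.ndarray, other: np.ndarray) -> float:
    """D+ = sup_x [F_essential(x) - F_other(x)] over the pooled sample points."""
    pooled = np.unique(np.concatenate([essential, other]))
    f_e = np.searchsorted(np.sort(essential), pooled, side="right") / len(essential)
    f_o = np.searchsorted(np.sort(other), pooled, side="right") / len(other)
    return float(np.max(f_e - f_o))


def ks_one_sided(
    essential_scores: Sequence[float],
    other_scores: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """One-sided two-sample KS test: are essential scores stochastically smaller?

    Returns (D+, p).  The statistic is D+ = sup_x [F_ess(x) - F_other(x)];
    small p supports the alternative that the essential-gene scores sit lower.
    p is computed by exact enumeration over all label assignments of the
    pooled sample when m + n <= 16 (or mode="exact"), else by the asymptotic
    one-sided Smirnov tail exp(-2 m n D^2 / (m + n)), capped at 1.
    """
    ess = np.asarray(essential_scores, dtype=float)
    oth = np.asarray(other_scores, dtype=float)
    if len(ess) == 0 or len(oth) == 0:
        raise ValueError("both score samples must be non-empty")
    m, n = len(ess), len(oth)
    d = _dplus(ess, oth)
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    exact = mode == "exact" or (mode == "auto" and m + n <= EXACT_KS_LIMIT)
    if exact:
        p = _exact_pvalue(ess, oth, d)
    else:
        p = min(1.0, math.exp(-2.0 * m * n * d * d / (m + n)))
    return d, p


def _exact_pvalue(ess: np.ndarray, oth: np.ndarray, observed: float) -> float:
    """Permutation-exact tail: share of label assignments with D+ >= observed."""
    pooled = np.concatenate([ess, oth])
    m, total = len(ess), len(pooled)
    idx = range(total)
    hits = 0
    count = 0
    for combo in itertools.combinations(idx, m):
        mask = np.zeros(total, dtype=bool)
        mask[list(combo)] = True
        d = _dplus(pooled[mask], pooled[~mask])
        count += 1
        if d >= observed - 1e-12:
            hits += 1
    return hits / count


def negative_fraction(scores: Mapping[str, float], gene_set: Iterable[str]) -> float:
    """Share of the gene set's scored members with a strictly negative score.

    Scores of exactly 0 count as non-negative.
    """
    scored = [scores[g] for g in gene_set if g in scores]
    if not scored:
        raise ValueError("no gene in the set has a score")
    return sum(1 for s in scored if s < 0) / len(scored)


def compare_scores(
    scores: Mapping[str, float],
    essential_genes: Iterable[str],
    all_genes: Iterable[str],
) -> ScoreComparison:
    """KS test of essential vs other metabolic genes plus negative-score fractions."""
    essential_genes = set(essential_genes)
    all_genes = set(all_genes)
    ess = [scores[g] for g in sorted(essential_genes) if g in scores]
    oth = [scores[g] for g in sorted(all_genes - essential_genes) if g in scores]
    if not ess or not oth:
        raise ValueError("need scored genes in both the essential and the remaining set")
    d, p = ks_one_sided(ess, oth)
    return ScoreComparison(
        ks_statistic=d,
        ks_pvalue=p,
        negative_fraction_essential=negative_fraction(scores, essential_genes),
        negative_fraction_all=negative_fraction(scores, all_genes),
    )


def load_scores_tsv(path: str | Path) -> dict[str, float]:
    """Per-gene external essentiality scores (gene_id, score); lower = more essential."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["score"].astype(float)))
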