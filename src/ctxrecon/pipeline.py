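"""End-to-end workflows: profile -> classification -> reconstruction -> GEA.

These functions tie the modules together the way a cohort study uses them:
classify a sample's expression against the reference model, extract its
context-specific network, run the gene essentiality screen on the extracted
subnetwork, and repeat the whole chain on permuted expression calls to build
the random background.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .classify import ExpressionProfile, classify_reactions
from .compare import FrequencyTable, essentiality_frequency, permute_calls
from .essentiality import EssentialityTable, gene_essentiality
from .model import MetabolicModel, induced_submodel
from .reconstruct import ReconstructionConfig, ReconstructionResult, reconstruct


def reconstruct_profile(
    model: MetabolicModel,
    profile: ExpressionProfile,
    medium: Mapping[str, float] | None = None,
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    classification = classify_reactions(model, profile)
    return reconstruct(model, classification, medium=medium, config=config)


def essentiality_for_profile(
    model: MetabolicModel,
    profile: ExpressionProfile,
    medium: Mapping[str, float] | None = None,
    config: ReconstructionConfig | None = None,
    use_skip: bool = True,
) -> tuple[EssentialityTable, ReconstructionResult]:
    """Reconstruct a context-specific network, then screen its genes by FBA knockout."""
    config = config or ReconstructionConfig()
    result = reconstruct_profile(model, profile, medium=medium, config=config)
    sub = induced_submodel(model, result.included)
    table = gene_essentiality(
        sub,
        vbiomass_star=result.vbiomass_star,
        act_tol=config.act_tol,
        use_skip=use_skip,
    )
    return table, result


def background_frequencies(
    model: MetabolicModel,
    profiles: Sequence[ExpressionProfile],
    medium: Mapping[str, float] | None = None,
    config: ReconstructionConfig | None = None,
    n_permutations: int = 10,
    seed: int = 0,
    use_skip: bool = True,
) -> FrequencyTable:
    """Sample-vs-random essentiality frequencies across a cohort.

    Each sample profile contributes one sample-derived network and
    `n_permutations` networks reconstructed from call permutations over the
    model's metabolic genes (per-sample seeds derived from the master seed).
    """
    metabolic_genes = model.genes
    sample_tables: list[EssentialityTable] = []
    random_tables: list[EssentialityTable] = []
    for i, profile in enumerate(profiles):
        table, _ = essentiality_for_profile(model, profile, medium, config, use_skip)
        sample_tables.append(table)
        for perm in permute_calls(profile, metabolic_genes, n_permutations,
                                  seed=(seed * 100003 + i) % (2**31 - 1)):
            ptable, _ = essentiality_for_profile(model, perm, medium, config, use_skip)
            random_tables.append(ptable)
    return essentiality_frequency(sample_tables, random_tables)
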