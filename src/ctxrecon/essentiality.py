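"""FBA-based gene essentiality analysis with the wild-type skip optimization.

A gene is essential when its in-silico deletion — disabling every reaction
whose GPR evaluates false with that gene off — drops the maximal biomass flux
below a tolerance.  To avoid one FBA per gene, a reference flux distribution
is computed first: the wild-type optimum with minimal total flux through
gene-associated reactions.  If none of a gene's knockout reactions carries
flux in that distribution, deleting them cannot disturb the reference
optimum, so the gene is non-essential without another LP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gpr import eval_boolean, gpr_genes
from .lp import ACT_TOL_DEFAULT, InfeasibleProblemError, fba_max, solve_lp
from .model import MetabolicModel, SplitModel, split_reversible

import scipy.sparse as sp


@dataclass
class GeneRecord:
    gene: str
    essential: bool
    knockout_biomass: float
    skipped: bool
    error: str | None = None


@dataclass
class EssentialityTable:
    records: list[GeneRecord]
    wild_type_biomass: float

    @property
    def essential_genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.records if r.essential)

    def record(self, gene: str) -> GeneRecord:
        return next(r for r in self.records if r.gene == gene)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "gene_id": [r.gene for r in self.records],
                "essential": [r.essential for r in self.records],
                "knockout_biomass": [r.knockout_biomass for r in self.records],
                "skipped": [r.skipped for r in self.records],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, wild_type_biomass: float = float("nan")) -> "EssentialityTable":
        df = pd.read_csv(path, sep="\t")
        records = [
            GeneRecord(str(r.gene_id), bool(r.essential), float(r.knockout_biomass), bool(r.skipped))
            for r in df.itertuples()
        ]
        return cls(records, wild_type_biomass)


def knockout_reactions(model: MetabolicModel, gene: str) -> frozenset[str]:
    """Reactions whose GPR turns false when `gene` is deleted (others functional)."""
    knocked = frozenset([gene])
    out = []
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        if gene in gpr_genes(rxn.gpr) and not eval_boolean(rxn.gpr, knocked):
            out.append(rxn.id)
    return frozenset(out)


def _reference_distribution(split: SplitModel, wt_biomass: float) -> dict[str, float]:
    """Min total flux through gene-associated steps at biomass fixed to the optimum."""
    model = split.parent
    gene_assoc = {r.id for r in model.reactions if r.gpr is not None}
    n = len(split.steps)
    c = np.zeros(n)
    for j, s in enumerate(split.steps):
        if s.parent_id in gene_assoc:
            c[j] = 1.0
    S = split.stoichiometric_matrix()
    bounds = [(0.0, s.upper) for s in split.steps]
    j_bio = split.step_index(split.biomass_step)
    # biomass >= wt * (1 - 1e-9): fixes the optimum up to solver tolerance
    row = sp.csr_matrix(([-1.0], ([0], [j_bio])), shape=(1, n))
    res = solve_lp(c, S, np.zeros(S.shape[0]), bounds, row, np.array([-wt_biomass * (1 - 1e-9)]))
    return dict(zip(split.step_ids, res.x))


def gene_essentiality(
    model: MetabolicModel,
    genes: Sequence[str] | None = None,
    essential_tol: float | None = None,
    act_tol: float = ACT_TOL_DEFAULT,
    use_skip: bool = True,
    vbiomass_star: float | None = None,
) -> EssentialityTable:
    """Single-gene deletion screen on `model`.

    essential_tol defaults to min(1e-6, v*) when a v* is given, else 1e-6;
    a stricter "cannot reach v*" reading is available by passing
    essential_tol=vbiomass_star explicitly.
    """
    model.validate(require_biomass=True)
    if genes is None:
        genes = sorted(model.genes)
    if essential_tol is None:
        essential_tol = min(1e-6, vbiomass_star) if vbiomass_star else 1e-6

    split = split_reversible(model)
    wt = fba_max(split).objective
    if wt <= essential_tol:
        raise InfeasibleProblemError(
            f"wild-type biomass {wt:.3g} is below the essentiality tolerance"
        )
    reference = _reference_distribution(split, wt) if use_skip else None

    records: list[GeneRecord] = []
    for gene in genes:
        targets = knockout_reactions(model, gene)
        if not targets:
            records.append(GeneRecord(gene, False, wt, skipped=True))
            continue
        if reference is not None:
            active = any(
                reference[sid] > act_tol
                for rid in targets
                for sid in split.steps_of(rid)
            )
            if not active:
                records.append(GeneRecord(gene, False, wt, skipped=True))
                continue
        fixed_off = {sid: 0.0 for rid in targets for sid in split.steps_of(rid)}
        try:
            ko = fba_max(split, fixed_off=fixed_off)
            ko_biomass = ko.objective
            err = None
        except InfeasibleProblemError as exc:
            ko_biomass, err = 0.0, str(exc)
        records.append(
            GeneRecord(gene, ko_biomass < essential_tol, ko_biomass, skipped=False, error=err)
        )
    return EssentialityTable(records, wild_type_biomass=wt)
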