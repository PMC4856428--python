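"""Expression evidence -> ternary H/M/L reaction classification.

Probe-level z-scores are aggregated to genes by the median, genes are called
present (+1) / absent (-1) against a z threshold, and reactions inherit a
label through their GPR under the ternary algebra (AND=min, OR=max,
unmeasured gene = 0): GPR value +1 -> H (highly expressed), 0 -> M (medium),
-1 -> L (lowly expressed).  Reactions without any gene association
(spontaneous, orphan) are classified M.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .gpr import eval_ternary
from .model import MetabolicModel

DEFAULT_Z_THRESHOLD = 5.0

LABELS = ("H", "M", "L")
_SCORE_TO_LABEL = {1: "H", 0: "M", -1: "L"}


@dataclass
class ExpressionProfile:
    """Per-gene evidence: present/absent calls, optionally with the z-scores behind them."""

    gene_call: dict[str, int]
    gene_z: dict[str, float] | None = None

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.gene_call.items() if c not in (1, -1)}
        if bad:
            raise ValueError(f"gene calls must be +1/-1; offending entries: {bad}")

    @classmethod
    def from_z(cls, gene_z: Mapping[str, float], z_threshold: float = DEFAULT_Z_THRESHOLD) -> "ExpressionProfile":
        return cls(gene_call=call_genes(gene_z, z_threshold), gene_z=dict(gene_z))


@dataclass
class ReactionClassification:
    label: dict[str, str]

    def __post_init__(self) -> None:
        bad = {r: l for r, l in self.label.items() if l not in LABELS}
        if bad:
            raise ValueError(f"labels must be H/M/L; offending entries: {bad}")

    def reactions_with(self, label: str) -> list[str]:
        return [r for r, l in self.label.items() if l == label]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"reaction_id": list(self.label), "label": list(self.label.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReactionClassification":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["reaction_id"].astype(str), df["label"].astype(str))))


def aggregate_probes(
    probe_z: Mapping[str, float],
    probe2gene: Mapping[str, str | Iterable[str]],
) -> dict[str, float]:
    """Gene z-score = median of the z-scores of its mapped probe sets.

    A probe mapping to several genes contributes to each of them; genes with
    no measured probe are absent from the result (not zero-filled).
    """
    per_gene: dict[str, list[float]] = {}
    for probe, z in probe_z.items():
        genes = probe2gene.get(probe)
        if genes is None:
            raise KeyError(f"probe {probe!r} has no gene mapping")
        if isinstance(genes, str):
            genes = [genes]
        for g in genes:
            per_gene.setdefault(g, []).append(float(z))
    return {g: statistics.median(zs) for g, zs in per_gene.items()}


def call_genes(gene_z: Mapping[str, float], z_threshold: float = DEFAULT_Z_THRESHOLD) -> dict[str, int]:
    """Present/absent calls: z >= threshold -> +1 (present), else -1 (absent)."""
    return {g: (1 if z >= z_threshold else -1) for g, z in gene_z.items()}


def classify_reactions(model: MetabolicModel, profile: ExpressionProfile) -> ReactionClassification:
    labels: dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            labels[rxn.id] = "M"
        else:
            labels[rxn.id] = _SCORE_TO_LABEL[eval_ternary(rxn.gpr, profile.gene_call)]
    return ReactionClassification(labels)


# ------------------------------ tabular I/O ------------------------------

def load_expression_tsv(path: str | Path, z_threshold: float = DEFAULT_Z_THRESHOLD) -> ExpressionProfile:
    """Read gene-level expression: columns (gene_id, call) or (gene_id, z)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols:
        raise ValueError(f"{path}: expected a 'gene_id' column, found {list(df.columns)}")
    gid = df[cols["gene_id"]].astype(str)
    if "call" in cols:
        return ExpressionProfile(gene_call=dict(zip(gid, df[cols["call"]].astype(int))))
    if "z" in cols:
        return ExpressionProfile.from_z(dict(zip(gid, df[cols["z"]].astype(float))), z_threshold)
    raise ValueError(f"{path}: expected a 'call' or 'z' column, found {list(df.columns)}")


def load_probe_tsv(path: str | Path) -> tuple[dict[str, float], dict[str, list[str]]]:
    """Read probe-level z-scores: columns (probe_id, z); map: (probe_id, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["probe_id"].astype(str), df["z"].astype(float)))


def load_probe_map_tsv(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    mapping: dict[str, list[str]] = {}
    for probe, gene in zip(df["probe_id"].astype(str), df["gene_id"].astype(str)):
        mapping.setdefault(probe, []).append(gene)
    return mapping
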