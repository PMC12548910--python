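"""Causal-mask interpretability: key genes and critical genes.

After training, the causal node mask M_x of a (drug pair, cell line) record
scores how strongly each gene in the cell line's specific network drives
the synergy prediction. Genes in the top 25% of a record's mask are its
*key genes*; accumulating key-gene membership over all synergistic records
of a cell line and taking the top 20% of the count distribution gives the
cell line's *critical genes*. Ranked count tables are exported as plain
two-column files ready for external enrichment services.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SynergyNet, combine_pair
from .train import SynergyDataset

__all__ = [
    "GeneMaskProfile",
    "extract_mask",
    "select_key_genes",
    "accumulate_critical_genes",
    "export_ranked_genes",
]


@dataclass
class GeneMaskProfile:
    """Per-gene causal mask values for one (drug pair, cell line) record."""

    cell_line_id: str
    drug_pair: tuple[str, str]
    genes: list[str]
    mask: np.ndarray  # values in [0, 1], aligned with ``genes``

    def __post_init__(self):
        if len(self.genes) != len(self.mask):
            raise ValueError("gene list and mask length differ")


def extract_mask(net: SynergyNet, dataset: SynergyDataset, index: int) -> GeneMaskProfile:
    """Run one record forward in evaluation mode and read off M_x.

    The gene order follows the cell line's specific-network manifest, which
    is the order the model was trained with.
    """
    record = dataset.records[index]
    cell = record.cell_line
    if cell not in dataset.cell_graphs:
        raise ValueError(f"no network manifest for cell line {cell!r}")
    d_ij = combine_pair(
        net.encode_drug(dataset.drug_graphs[record.drug1]),
        net.encode_drug(dataset.drug_graphs[record.drug2]),
    )
    fused = net.fuse(
        net.encode_cell(dataset.cell_norm_adj[cell], dataset.cell_graphs[cell].features),
        d_ij,
        dataset.cell_graphs[cell].adjacency,
        dataset.cell_norm_adj[cell],
    )
    masks = net.masks(fused)
    return GeneMaskProfile(
        cell_line_id=cell,
        drug_pair=record.pair_key(),
        genes=list(dataset.cell_graphs[cell].nodes),
        mask=masks.node_mask.copy(),
    )


def select_key_genes(profile: GeneMaskProfile) -> set[str]:
    """Genes at or above the 75th percentile of the record's mask values.

    All genes tied at the cutoff are included, so the selected fraction is
    at least 25%.
    """
    if len(profile.genes) < 4:
        raise ValueError("need at least 4 genes to take a top-25% cut")
    cutoff = np.percentile(profile.mask, 75)
    return {g for g, v in zip(profile.genes, profile.mask) if v >= cutoff}


def accumulate_critical_genes(
    profiles: list[GeneMaskProfile],
) -> tuple[list[str], pd.Series]:
    """Critical genes of a cell line from its synergistic-record masks.

    Counts, per gene, how often it is a key gene across the given profiles
    (the caller restricts these to synergistic records of one cell line),
    then returns the genes in the top 20% of the count distribution (ties at
    the cutoff included, never-selected genes excluded) together with the
    full count table for distribution inspection.
    """
    if not profiles:
        raise ValueError("no profiles to accumulate")
    cell_ids = {p.cell_line_id for p in profiles}
    if len(cell_ids) > 1:
        raise ValueError(f"profiles span several cell lines: {sorted(cell_ids)}")
    genes = sorted({g for p in profiles for g in p.genes})
    counts = pd.Series(0, index=genes, dtype=int)
    for p in profiles:
        for g in select_key_genes(p):
            counts[g] += 1
    cutoff = np.percentile(counts.to_numpy(), 80)
    critical = [g for g in genes if counts[g] >= cutoff and counts[g] > 0]
    critical.sort(key=lambda g: (-counts[g], g))
    counts = counts.sort_values(ascending=False, kind="stable")
    return critical, counts


def gene_mean_mask(net: SynergyNet, dataset: SynergyDataset,
                   synergistic_only: bool = True) -> pd.Series:
    """Mean causal-mask value per gene across (synergistic) records."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for i, rec in enumerate(dataset.records):
        if synergistic_only and rec.label != 1:
            continue
        prof = extract_mask(net, dataset, i)
        for g, v in zip(prof.genes, prof.mask):
            sums[g] = sums.get(g, 0.0) + float(v)
            counts[g] = counts.get(g, 0) + 1
    return pd.Series({g: sums[g] / counts[g] for g in sorted(sums)})


def attribution_rank_auc(net: SynergyNet, dataset: SynergyDataset,
                         causal_genes: set[str]) -> float:
    """Rank-AUC of known causal genes vs the rest by mean mask value.

    Aggregates the causal node mask per gene over all synergistic records,
    then scores how well that ranking separates a reference causal gene set
    (e.g. a synthetic bundle's planted genes) from the other network genes.
    0.5 means no attribution signal; 1.0 means perfect separation.
    """
    from sklearn.metrics import roc_auc_score

    means = gene_mean_mask(net, dataset)
    flags = [int(g in causal_genes) for g in means.index]
    if len(set(flags)) < 2:
        raise ValueError("need both causal and non-causal genes in the networks")
    return float(roc_auc_score(flags, means.to_numpy()))


def export_ranked_genes(counts: pd.Series, path) -> None:
    """Write a (gene, count) table ranked by count for external enrichment."""
    df = counts.rename("count").rename_axis("gene").reset_index()
    df.to_csv(path, sep="\t", index=False)
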