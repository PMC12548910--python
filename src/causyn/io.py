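"""Readers, writers and validators for the five tabular/graph inputs.

A dataset bundle consists of:

* a drug table mapping drug id -> SMILES,
* a protein-protein interaction (PPI) edge list,
* a cell-line -> target-gene mapping,
* a genes x cell-lines expression matrix,
* a synergy table of (drug1, drug2, cell_line, score) records.

All files are plain-text delimited (TSV or CSV, delimiter sniffed). Loading
cross-references identifiers, drops records that cannot be resolved (with a
logged count), z-scores expression per gene across cell lines, and binarizes
synergy scores: score > 0 -> label 1, score < 0 -> label 0, score == 0 ->
undefined (excluded from classification).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import smiles_to_graph

logger = logging.getLogger(__name__)

__all__ = [
    "DrugRegistry",
    "PPINetwork",
    "CellLineProfile",
    "SynergyRecord",
    "DatasetBundle",
    "binarize_synergy",
    "standardize_expression",
    "load_dataset",
    "write_dataset",
]


def _sniff_delimiter(path: Path) -> str:
    sample = Path(path).read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    return df.map(lambda v: v.strip() if isinstance(v, str) else v)


@dataclass
class DrugRegistry:
    """Mapping drug id -> SMILES; every entry is guaranteed parseable."""

    entries: dict[str, str] = field(default_factory=dict)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def smiles(self, drug_id: str) -> str:
        return self.entries[drug_id]


@dataclass
class PPINetwork:
    """Undirected protein interaction graph: node set V, edge set E.

    Edges are stored as sorted tuples; no self-loops, no duplicates.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    @staticmethod
    def _key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            return
        self.nodes.add(u)
        self.nodes.add(v)
        self.edges.add(self._key(u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return self._key(u, v) in self.edges

    def neighbors(self, u: str) -> set[str]:
        return {b if a == u else a for a, b in self.edges if u in (a, b)}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        # sorted insertion keeps traversal order independent of hash seeds
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass
class CellLineProfile:
    """Targets T(i) and (standardized) expression for one cell line."""

    cell_line_id: str
    targets: set[str] = field(default_factory=set)
    expression: dict[str, float] = field(default_factory=dict)


@dataclass
class SynergyRecord:
    """One (drug1, drug2, cell line) measurement with its synergy score."""

    drug1: str
    drug2: str
    cell_line: str
    score: float
    label: int | None = None

    def __post_init__(self):
        if self.label is None:
            self.label = binarize_synergy(self.score)

    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.drug1, self.drug2)))


@dataclass
class DatasetBundle:
    """Everything load_dataset returns, cross-referenced and validated."""

    drugs: DrugRegistry
    ppi: PPINetwork
    profiles: dict[str, CellLineProfile]
    records: list[SynergyRecord]
    n_dropped: int = 0


def binarize_synergy(score: float) -> int | None:
    """Binary synergy label: 1 if score > 0, 0 if score < 0, None if exactly 0."""
    score = float(score)
    if not math.isfinite(score):
        raise ValueError(f"non-finite synergy score: {score!r}")
    if score > 0:
        return 1
    if score < 0:
        return 0
    return None


def standardize_expression(
    matrix: pd.DataFrame, scheme: str = "per_gene"
) -> pd.DataFrame:
    """Z-score an expression matrix (genes x cell lines).

    ``per_gene`` standardizes each gene (row) across cell lines — the usual
    preprocessing for real panels; ``per_cell_line`` standardizes each cell
    line (column) across genes, preserving within-sample gene ranking.
    Zero-variance slices map to 0. Population standard deviation (ddof=0).
    """
    if scheme not in ("per_gene", "per_cell_line"):
        raise ValueError(f"unknown standardization scheme {scheme!r}")
    axis = 1 if scheme == "per_gene" else 0
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=axis, keepdims=True)
    std = values.std(axis=axis, ddof=0, keepdims=True)
    flat = np.broadcast_to(std == 0, values.shape)
    std = np.where(std == 0, 1.0, std)
    out = np.where(flat, 0.0, (values - mean) / std)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _load_drugs(path) -> DrugRegistry:
    df = _read_table(path)
    reg = DrugRegistry()
    rejected = 0
    for _, row in df.iterrows():
        drug_id, smiles = str(row.iloc[0]), str(row.iloc[1])
        try:
            smiles_to_graph(smiles)
        except ValueError:
            rejected += 1
            logger.warning("rejecting drug %s: unparsable SMILES %r", drug_id, smiles)
            continue
        reg.entries[drug_id] = smiles
    if rejected:
        logger.info("rejected %d drug entries with malformed SMILES", rejected)
    return reg


def _load_ppi(path) -> PPINetwork:
    df = _read_table(path)
    net = PPINetwork()
    for _, row in df.iterrows():
        net.add_edge(str(row.iloc[0]), str(row.iloc[1]))
    return net


def load_dataset(
    drug_table,
    ppi_edges,
    target_table,
    expression_matrix,
    synergy_table,
    standardize: str | None = "per_gene",
) -> DatasetBundle:
    """Load and cross-reference the five inputs into a validated bundle.

    Synergy records referencing unknown drugs or cell lines are dropped and
    counted; duplicate unordered (drug1, drug2, cell) triples keep the first
    occurrence. Expression is z-scored according to ``standardize``
    ("per_gene", "per_cell_line", or None to keep raw values, e.g. when
    re-reading an already-standardized bundle). Raises if the synergy table
    is empty after parsing, or if a target gene has no expression row.
    """
    drugs = _load_drugs(drug_table)
    ppi = _load_ppi(ppi_edges)

    targets_df = _read_table(target_table)
    expr = pd.read_csv(
        Path(expression_matrix),
        sep=_sniff_delimiter(Path(expression_matrix)),
        index_col=0,
    )
    expr.index = [str(i).strip() for i in expr.index]
    expr.columns = [str(c).strip() for c in expr.columns]
    if standardize:
        expr = standardize_expression(expr, scheme=standardize)

    profiles: dict[str, CellLineProfile] = {}
    for _, row in targets_df.iterrows():
        cell, gene = str(row.iloc[0]), str(row.iloc[1])
        prof = profiles.setdefault(cell, CellLineProfile(cell_line_id=cell))
        if gene in ppi.nodes:
            prof.targets.add(gene)
        else:
            logger.warning("target %s of %s absent from PPI; ignored", gene, cell)
    for cell, prof in profiles.items():
        if cell not in expr.columns:
            raise ValueError(f"expression matrix missing cell line {cell!r}")
        for gene in prof.targets:
            if gene not in expr.index:
                raise ValueError(f"expression matrix missing required gene {gene!r}")
        prof.expression = {g: float(expr.at[g, cell]) for g in expr.index}

    syn_df = _read_table(synergy_table)
    if syn_df.empty:
        raise ValueError("synergy table is empty")
    records: list[SynergyRecord] = []
    seen: set[tuple] = set()
    dropped = 0
    for _, row in syn_df.iterrows():
        d1, d2, cell = str(row.iloc[0]), str(row.iloc[1]), str(row.iloc[2])
        score = float(row.iloc[3])
        if d1 not in drugs or d2 not in drugs or cell not in profiles:
            dropped += 1
            continue
        key = (tuple(sorted((d1, d2))), cell)
        if key in seen:
            dropped += 1
            logger.info("duplicate pair orientation (%s, %s, %s) dropped", d1, d2, cell)
            continue
        seen.add(key)
        records.append(SynergyRecord(d1, d2, cell, score))
    if dropped:
        logger.info("dropped %d synergy rows (unknown ids or duplicates)", dropped)
    return DatasetBundle(drugs, ppi, profiles, records, n_dropped=dropped)


def write_dataset(bundle: DatasetBundle, out_dir, sep: str = "\t") -> dict[str, Path]:
    """Write a bundle back to the five delimited files (expression unscaled).

    Expression is written as currently held in the profiles (i.e. already
    standardized if the bundle was loaded with standardization); reloading
    with ``standardize=None`` round-trips exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": out_dir / "drugs.tsv",
        "ppi": out_dir / "ppi_edges.tsv",
        "targets": out_dir / "targets.tsv",
        "expression": out_dir / "expression.tsv",
        "synergy": out_dir / "synergy.tsv",
    }
    pd.DataFrame(
        sorted(bundle.drugs.entries.items()), columns=["drug_id", "smiles"]
    ).to_csv(paths["drugs"], sep=sep, index=False)
    pd.DataFrame(sorted(bundle.ppi.edges), columns=["protein_a", "protein_b"]).to_csv(
        paths["ppi"], sep=sep, index=False
    )
    rows = [
        (cell, gene)
        for cell, prof in sorted(bundle.profiles.items())
        for gene in sorted(prof.targets)
    ]
    pd.DataFrame(rows, columns=["cell_line_id", "gene_id"]).to_csv(
        paths["targets"], sep=sep, index=False
    )
    cells = sorted(bundle.profiles)
    genes = sorted({g for p in bundle.profiles.values() for g in p.expression})
    mat = pd.DataFrame(
        {c: [bundle.profiles[c].expression[g] for g in genes] for c in cells},
        index=genes,
    )
    mat.index.name = "gene_id"
    mat.to_csv(paths["expression"], sep=sep)
    pd.DataFrame(
        [(r.drug1, r.drug2, r.cell_line, r.score) for r in bundle.records],
        columns=["drug1", "drug2", "cell_line", "score"],
    ).to_csv(paths["synergy"], sep=sep, index=False)
    return paths
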