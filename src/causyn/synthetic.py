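"""Self-contained synthetic datasets with a planted causal mechanism.

The generator emits the five inputs the loader expects (drug table, PPI
edge list, cell-line targets, expression matrix, synergy table) plus a
ground-truth manifest, so the whole pipeline — network extraction, model
training, causal-mask interpretation — can be exercised and scored without
any external download.

Planted mechanism
-----------------
A random connected PPI graph is drawn over ``n_genes`` genes and a set of
``n_planted`` *planted* genes is fixed. Every cell line targets all planted
genes plus a few random others (so planted genes are guaranteed to be seeds
of every specific network). A fraction of cell lines is *responsive*: their
planted-gene expression is shifted by the effect size ``w``; all other
expression is standard normal. The synergy score of (d1, d2, cell) is

    score = w * mean(planted expression in cell) * s(d1, d2) + eps

where ``s`` is a fixed symmetric descriptor of the two molecules (z-scored
heavy-atom-count sum plus an aromatic-ring term) and eps is Gaussian. The
label is the sign of the score; a fraction ``noise_rate`` of scores have
their sign flipped. Because the mechanism is known, the Bayes-optimal AUC
(the ceiling any model can reach against the noisy labels) is computable by
scoring the records with the true noiseless score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import smiles_to_graph
from .io import DatasetBundle, load_dataset, write_dataset  # noqa: F401
from rdkit import Chem

__all__ = ["BUNDLED_SMILES", "SyntheticSpec", "SyntheticBundle",
           "generate", "oracle_bayes_auc", "pair_descriptor"]

# Small, valid, drug-like molecules; six aromatic, six acyclic, with a
# spread of heavy-atom counts so the pair descriptor varies.
BUNDLED_SMILES: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "sulfanilamide": "Nc1ccc(S(N)(=O)=O)cc1",
    "benzylalcohol": "OCc1ccccc1",
    "glycerol": "OCC(O)CO",
    "citrate": "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "metformin": "CN(C)C(=N)NC(=N)N",
    "hexanoate": "CCCCCC(=O)O",
    "glycine": "NCC(=O)O",
    "urea": "NC(N)=O",
}


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the reference study conditions."""

    n_genes: int = 60
    edge_density: float = 0.07
    n_cell_lines: int = 8
    drug_names: tuple[str, ...] = tuple(sorted(BUNDLED_SMILES))
    n_planted: int = 6
    n_extra_targets: int = 8
    effect_size: float = 2.0
    score_noise_sd: float = 0.3
    responsive_fraction: float = 0.75
    noise_rate: float = 0.1
    n_records: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_planted >= self.n_genes:
            raise ValueError("planted gene count must be < gene count")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise rate must be in [0, 0.5)")
        unknown = [d for d in self.drug_names if d not in BUNDLED_SMILES]
        if unknown:
            raise ValueError(f"unknown bundled drugs: {unknown}")
        for name in self.drug_names:
            smiles_to_graph(BUNDLED_SMILES[name])  # raises if unparsable
        n_pairs = len(self.drug_names) * (len(self.drug_names) - 1) // 2
        if self.n_records > n_pairs * self.n_cell_lines:
            raise ValueError(
                f"cannot draw {self.n_records} unique (pair, cell) records "
                f"from {n_pairs} pairs x {self.n_cell_lines} cell lines"
            )


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth of the planted mechanism."""

    drug_table: pd.DataFrame
    ppi_edges: pd.DataFrame
    target_table: pd.DataFrame
    expression: pd.DataFrame          # genes x cell lines, raw (unstandardized)
    synergy_table: pd.DataFrame
    planted_genes: list[str]
    responsive: dict[str, bool]
    true_scores: np.ndarray           # noiseless generative score per record
    spec: SyntheticSpec
    descriptors: dict[str, dict] = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        """Write the five input files plus a ground-truth manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "drugs": out / "drugs.tsv",
            "ppi": out / "ppi_edges.tsv",
            "targets": out / "targets.tsv",
            "expression": out / "expression.tsv",
            "synergy": out / "synergy.tsv",
            "truth": out / "ground_truth.json",
        }
        self.drug_table.to_csv(paths["drugs"], sep="\t", index=False)
        self.ppi_edges.to_csv(paths["ppi"], sep="\t", index=False)
        self.target_table.to_csv(paths["targets"], sep="\t", index=False)
        self.expression.to_csv(paths["expression"], sep="\t")
        self.synergy_table.to_csv(paths["synergy"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps({
            "planted_genes": self.planted_genes,
            "responsive": self.responsive,
            "true_scores": self.true_scores.tolist(),
            "descriptors": self.descriptors,
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in self.spec.__dict__.items()},
        }, indent=1))
        return paths

    def load(self, tmp_dir=None, standardize: str | None = "per_cell_line"
             ) -> DatasetBundle:
        """Round-trip through the plain-text formats into a DatasetBundle.

        The default standardization here is per cell line: the planted
        mechanism is a between-cell-line shift of the planted genes, and
        per-gene z-scoring (the loader default for real panels) would force
        every gene's marginal distribution to mean 0 / sd 1, leaving a
        single-cell-line forward pass almost no per-node trace of
        planted-ness. Within-cell-line scaling preserves the gene ranking
        the attribution experiment is designed to recover.
        """
        import tempfile

        if tmp_dir is None:
            with tempfile.TemporaryDirectory() as td:
                paths = self.write(td)
                return load_dataset(paths["drugs"], paths["ppi"], paths["targets"],
                                    paths["expression"], paths["synergy"],
                                    standardize=standardize)
        paths = self.write(tmp_dir)
        return load_dataset(paths["drugs"], paths["ppi"], paths["targets"],
                            paths["expression"], paths["synergy"],
                            standardize=standardize)


def _molecule_descriptors(names) -> dict[str, dict]:
    out = {}
    for name in names:
        mol = Chem.MolFromSmiles(BUNDLED_SMILES[name])
        out[name] = {
            "heavy_atoms": mol.GetNumAtoms(),
            "aromatic": int(any(a.GetIsAromatic() for a in mol.GetAtoms())),
        }
    return out


def pair_descriptor(descriptors: dict[str, dict], d1: str, d2: str) -> float:
    """Symmetric molecular-pair descriptor s(d1, d2).

    s = 0.9 * z(heavy_1 + heavy_2) + 0.7 * (ring_1 + ring_2 - 1), where the
    z-score is over all unordered pairs of the drug list in ``descriptors``.
    """
    names = sorted(descriptors)
    sums = [descriptors[a]["heavy_atoms"] + descriptors[b]["heavy_atoms"]
            for i, a in enumerate(names) for b in names[i + 1:]]
    mu, sd = float(np.mean(sums)), float(np.std(sums))
    raw = descriptors[d1]["heavy_atoms"] + descriptors[d2]["heavy_atoms"]
    ring = descriptors[d1]["aromatic"] + descriptors[d2]["aromatic"] - 1
    return 0.9 * (raw - mu) / sd + 0.7 * ring


def _connected_gnp(n: int, p: float, rng) -> list[tuple[int, int]]:
    """Random graph: a random spanning tree plus Bernoulli(p) extra edges."""
    edges = set()
    order = rng.permutation(n)
    for k in range(1, n):
        parent = order[rng.integers(0, k)]
        edges.add(tuple(sorted((int(order[k]), int(parent)))))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((i, j))
    return sorted(edges)


def generate(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Draw a full synthetic bundle from the planted generative model."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    cells = [f"CL{i:02d}" for i in range(spec.n_cell_lines)]
    drugs = list(spec.drug_names)

    edges = _connected_gnp(spec.n_genes, spec.edge_density, rng)
    ppi = pd.DataFrame(
        [(genes[i], genes[j]) for i, j in edges], columns=["protein_a", "protein_b"]
    )
    planted = sorted(rng.choice(spec.n_genes, size=spec.n_planted, replace=False))
    planted_genes = [genes[i] for i in planted]

    # exact responsive count (stratified draw): both responsive and
    # non-responsive cell lines are guaranteed, so the differential-response
    # mechanism is present in every bundle
    n_resp = int(round(spec.responsive_fraction * spec.n_cell_lines))
    n_resp = min(max(n_resp, 1), spec.n_cell_lines - 1)
    resp_idx = set(rng.choice(spec.n_cell_lines, size=n_resp,
                              replace=False).tolist())
    responsive = {c: (j in resp_idx) for j, c in enumerate(cells)}
    expr = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_cell_lines))
    for j, c in enumerate(cells):
        if responsive[c]:
            expr[planted, j] += spec.effect_size
    expression = pd.DataFrame(expr, index=genes, columns=cells)
    expression.index.name = "gene_id"

    target_rows = []
    non_planted = [g for g in genes if g not in planted_genes]
    for c in cells:
        extra = rng.choice(len(non_planted), size=spec.n_extra_targets, replace=False)
        targets = planted_genes + [non_planted[i] for i in sorted(extra)]
        target_rows.extend((c, g) for g in targets)
    target_table = pd.DataFrame(target_rows, columns=["cell_line_id", "gene_id"])

    descriptors = _molecule_descriptors(drugs)
    triples = [
        (a, b, c)
        for i, a in enumerate(drugs)
        for b in drugs[i + 1:]
        for c in cells
    ]
    chosen = rng.choice(len(triples), size=spec.n_records, replace=False)
    mean_planted = {c: float(expr[planted, j].mean()) for j, c in enumerate(cells)}

    rows, true_scores = [], []
    for t in sorted(chosen):
        d1, d2, c = triples[t]
        s = pair_descriptor(descriptors, d1, d2)
        signal = spec.effect_size * mean_planted[c] * s
        score = signal + rng.normal(0.0, spec.score_noise_sd)
        while abs(score) < 1e-9:  # avoid undefined (exactly-zero) labels
            score = signal + rng.normal(0.0, spec.score_noise_sd)
        if rng.random() < spec.noise_rate:
            score = -score
        rows.append((d1, d2, c, round(float(score), 6)))
        true_scores.append(signal)
    synergy_table = pd.DataFrame(rows, columns=["drug1", "drug2", "cell_line", "score"])
    drug_table = pd.DataFrame(
        [(d, BUNDLED_SMILES[d]) for d in drugs], columns=["drug_id", "smiles"]
    )
    return SyntheticBundle(
        drug_table=drug_table,
        ppi_edges=ppi,
        target_table=target_table,
        expression=expression,
        synergy_table=synergy_table,
        planted_genes=planted_genes,
        responsive=responsive,
        true_scores=np.asarray(true_scores),
        spec=spec,
        descriptors=descriptors,
    )


def oracle_bayes_auc(bundle: SyntheticBundle) -> float:
    """AUC of the true generative score against the (noisy) stored labels.

    This is the ceiling any predictor can reach on the bundle: the true
    score carries all usable signal, and label flips bound the attainable
    separation.
    """
    from sklearn.metrics import roc_auc_score

    labels = (bundle.synergy_table["score"].to_numpy(dtype=float) > 0).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("bundle labels are single-class")
    return float(roc_auc_score(labels, bundle.true_scores))
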