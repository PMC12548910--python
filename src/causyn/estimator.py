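"""Scikit-learn-style estimator facade over the causal-attention network.

``CausalSynergyClassifier`` follows the sklearn estimator contract
(constructor stores hyperparameters unchanged, ``fit`` learns state into
trailing-underscore attributes, ``get_params``/``set_params`` work with
``sklearn.base.clone``), so it composes with sklearn model selection.

Samples are (drug1, drug2, cell_line) identifier triples; the molecular
graphs, PPI-derived specific networks and expression features they refer to
come from a ``DatasetBundle`` given to the constructor.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .io import DatasetBundle, SynergyRecord
from .model import ModelConfig, SynergyNet
from .train import (
    SplitPlan,
    SynergyDataset,
    TrainConfig,
    predict_scores,
    train,
)

__all__ = ["CausalSynergyClassifier"]


class CausalSynergyClassifier(BaseEstimator, ClassifierMixin):
    """Drug-combination synergy classifier with causal-attention decoupling.

    Parameters
    ----------
    bundle
        The cross-referenced dataset bundle supplying SMILES, the PPI
        network, targets and expression for every identifier appearing in
        the samples.
    hidden_dim, attn_dim, n_drug_layers, n_cell_layers, n_attn_layers,
    mask_hidden, pooling
        Architecture: GCN width h, cross-attention width b, encoder depths,
        number of cross-attention layers, mask-MLP width, subgraph readout.
    lambda_bias, lambda_interv
        Weights of the shortcut-disentanglement (KL to random labels) and
        backdoor-intervention consistency losses.
    n_interventions
        Number of shortcut strata sampled per step for the intervention loss.
    freeze_masks
        Pin causal masks at 1 (plain GCN + cross-attention ablation).
    induced_edges
        Use the full induced PPI subgraph per cell line instead of the
        minimal shortest-path topology.
    lr, batch_size, epochs, patience, validation_fraction
        Optimization settings; early stopping monitors validation AUC on an
        internal stratified hold-out of ``validation_fraction``.
    mask_phase_epochs, mask_lr_mult
        Length and learning-rate scale of the mask-only phase that follows
        trunk training (see causyn.train.train).
    weight_decay, node_dropout
        Trunk regularization: decoupled L2 and train-time dropout of gene
        expression values (counters cell-identity memorization).
    random_state
        Seeds parameter init, batching, random labels and interventions.

    Attributes
    ----------
    net_ : SynergyNet
        The fitted network (best validation state).
    dataset_ : SynergyDataset
        Compiled graphs and the fitted record list.
    history_ : dict
        Per-epoch loss components and validation AUC.
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        bundle: DatasetBundle | None = None,
        hidden_dim: int = 32,
        attn_dim: int = 16,
        n_drug_layers: int = 2,
        n_cell_layers: int = 2,
        n_attn_layers: int = 1,
        mask_hidden: int = 16,
        pooling: str = "mean",
        lambda_bias: float = 0.5,
        lambda_interv: float = 0.5,
        n_interventions: int = 1,
        freeze_masks: bool = False,
        induced_edges: bool = False,
        lr: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 200,
        patience: int = 20,
        mask_phase_epochs: int = 30,
        mask_lr_mult: float = 1.0,
        weight_decay: float = 1e-3,
        node_dropout: float = 0.3,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.bundle = bundle
        self.hidden_dim = hidden_dim
        self.attn_dim = attn_dim
        self.n_drug_layers = n_drug_layers
        self.n_cell_layers = n_cell_layers
        self.n_attn_layers = n_attn_layers
        self.mask_hidden = mask_hidden
        self.pooling = pooling
        self.lambda_bias = lambda_bias
        self.lambda_interv = lambda_interv
        self.n_interventions = n_interventions
        self.freeze_masks = freeze_masks
        self.induced_edges = induced_edges
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.mask_phase_epochs = mask_phase_epochs
        self.mask_lr_mult = mask_lr_mult
        self.weight_decay = weight_decay
        self.node_dropout = node_dropout
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            hidden_dim=self.hidden_dim,
            attn_dim=self.attn_dim,
            n_drug_layers=self.n_drug_layers,
            n_cell_layers=self.n_cell_layers,
            n_attn_layers=self.n_attn_layers,
            mask_hidden=self.mask_hidden,
            pooling=self.pooling,
            lambda_bias=self.lambda_bias,
            lambda_interv=self.lambda_interv,
            n_interventions=self.n_interventions,
            freeze_masks=self.freeze_masks,
            seed=self.random_state,
        )

    @staticmethod
    def _as_triples(X) -> list[tuple[str, str, str]]:
        arr = np.asarray(X, dtype=object)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("X must be an (n, 3) array of "
                             "(drug1, drug2, cell_line) identifiers")
        return [tuple(str(v) for v in row) for row in arr]

    def fit(self, X, y):
        """Fit on (drug1, drug2, cell_line) triples and binary labels."""
        if self.bundle is None:
            raise ValueError("a DatasetBundle must be supplied at construction")
        triples = self._as_triples(X)
        y = np.asarray(y, dtype=int)
        if len(triples) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if not np.isin(self.classes_, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")

        records = [
            SynergyRecord(d1, d2, c, score=(1.0 if lbl == 1 else -1.0))
            for (d1, d2, c), lbl in zip(triples, y)
        ]
        working = DatasetBundle(
            self.bundle.drugs, self.bundle.ppi, self.bundle.profiles, records
        )
        self.dataset_ = SynergyDataset.from_bundle(
            working, induced_edges=self.induced_edges
        )
        rng = np.random.default_rng(self.random_state)
        idx = np.arange(len(records))
        val: list[int] = []
        for cls in self.classes_:
            members = rng.permutation(idx[y == cls])
            n_val = max(1, int(round(self.validation_fraction * len(members))))
            val.extend(members[:n_val].tolist())
        train_idx = sorted(set(idx.tolist()) - set(val))
        plan = SplitPlan(train_idx, sorted(val), [], mode="random",
                         seed=self.random_state)
        net = SynergyNet(self.dataset_.feature_dim, self._model_config())
        self.net_, self.history_ = train(
            net, self.dataset_, plan,
            TrainConfig(lr=self.lr, batch_size=self.batch_size,
                        epochs=self.epochs, patience=self.patience,
                        mask_phase_epochs=self.mask_phase_epochs,
                        mask_lr_mult=self.mask_lr_mult,
                        weight_decay=self.weight_decay,
                        node_dropout=self.node_dropout,
                        seed=self.random_state),
        )
        return self

    # -------------------------------------------------------------- predict
    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise NotFittedError("call fit before predict")

    def decision_dataset(self, X) -> tuple[SynergyDataset, list[int]]:
        """Compile prediction triples against the fitted graph manifests."""
        self._check_fitted()
        triples = self._as_triples(X)
        records = [SynergyRecord(d1, d2, c, score=1.0) for d1, d2, c in triples]
        ds = SynergyDataset(
            records,
            self.dataset_.drug_graphs,
            self.dataset_.networks,
            self.dataset_.cell_graphs,
            self.dataset_.cell_norm_adj,
            self.dataset_.feature_dim,
        )
        for r in records:
            if r.drug1 not in ds.drug_graphs or r.drug2 not in ds.drug_graphs:
                raise ValueError(f"unknown drug in pair ({r.drug1}, {r.drug2})")
            if r.cell_line not in ds.cell_graphs:
                raise ValueError(f"unknown cell line {r.cell_line!r}")
        return ds, list(range(len(records)))

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities z_Gc for each triple."""
        ds, idx = self.decision_dataset(X)
        pos = predict_scores(self.net_, ds, idx)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
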