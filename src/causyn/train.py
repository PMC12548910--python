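"""Training loop, data splits (random / cross-validation / cold-start),
grid search and evaluation metrics.

Splits operate on indices into a list of SynergyRecords. Three cold-start
regimes are supported:

* ``drug_cold`` — 80% of drugs are "known"; training uses only pairs of
  known drugs, testing uses the remaining pairs (at least one novel drug).
* ``combination_cold`` — 10% of unordered drug pairs are held out; every
  record mentioning either drug of a held-out pair is removed from training.
* ``cell_cold`` — 80/20 split over cell lines; test cell lines never occur
  in training.

Metrics are AUC-ROC, AUC-PR, F1 and accuracy (threshold 0.5).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from .featurize import MolecularGraph, normalize_adjacency, smiles_to_graph
from .io import DatasetBundle, SynergyRecord
from .model import (
    LossBundle,
    ModelConfig,
    SynergyNet,
    bias_loss,
    causal_loss,
    combine_pair,
    intervention_loss,
)
from .autograd import Tensor, concat
from .network import (
    ExpressionGraph,
    SpecificNetwork,
    build_specific_network,
    induced_expression_graph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "MetricReport",
    "TrainConfig",
    "SynergyDataset",
    "make_split",
    "check_split",
    "cv_splits",
    "compute_metrics",
    "aggregate_metrics",
    "Adam",
    "train",
    "evaluate",
    "grid_search",
]

SPLIT_MODES = ("random", "cv", "drug_cold", "combination_cold", "cell_cold")


# ------------------------------------------------------------------- splits
@dataclass
class SplitPlan:
    """Disjoint train/validation/test index lists over a record list."""

    train: list[int]
    validation: list[int]
    test: list[int]
    mode: str
    seed: int
    repeat: int = 0

    def __post_init__(self):
        sets = [set(self.train), set(self.validation), set(self.test)]
        for a, b in itertools.combinations(sets, 2):
            if a & b:
                raise ValueError("split index lists overlap")


def _stratified_two_way(
    indices: list[int], labels: np.ndarray, frac_second: float, rng
) -> tuple[list[int], list[int]]:
    """Split indices into (1-frac, frac) parts, stratified on labels."""
    first: list[int] = []
    second: list[int] = []
    indices = np.asarray(indices)
    n_second_total = int(round(frac_second * len(indices)))
    per_class: dict[int, np.ndarray] = {}
    for cls in np.unique(labels[indices]):
        members = indices[labels[indices] == cls]
        per_class[cls] = rng.permutation(members)
    # largest-remainder allocation so the global count is exact
    quotas = {c: frac_second * len(m) for c, m in per_class.items()}
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftover = n_second_total - sum(base.values())
    order = sorted(per_class, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in order[:leftover]:
        base[c] += 1
    for c, members in per_class.items():
        second.extend(members[: base[c]].tolist())
        first.extend(members[base[c]:].tolist())
    return sorted(first), sorted(second)


def make_split(
    records: list[SynergyRecord],
    mode: str = "random",
    seed: int = 0,
    fold: int = 0,
    repeat: int = 0,
) -> SplitPlan:
    """Build a train/validation/test split over the labelled records.

    ``random`` is a label-stratified 8:1:1 split. ``cv`` fixes a stratified
    10% test set, then runs 5-fold cross-validation over the remaining pool
    (``fold`` selects the validation fold, ``repeat`` reshuffles).
    Cold-start modes enforce the exclusion constraints described in the
    module docstring; validation is carved out of the training portion
    (stratified, 1/9) so the ratio mirrors 8:1:1 where feasible.
    """
    if mode not in SPLIT_MODES:
        raise ValueError(f"unknown split mode {mode!r}")
    labelled = [i for i, r in enumerate(records) if r.label is not None]
    if len(labelled) < 10:
        raise ValueError("need at least 10 labelled records to split")
    labels = np.array([-1 if r.label is None else r.label for r in records])
    rng = np.random.default_rng(seed + 1_000_003 * repeat)

    if mode == "random":
        rest, test = _stratified_two_way(labelled, labels, 0.1, rng)
        train, val = _stratified_two_way(rest, labels, 1.0 / 9.0, rng)
        return SplitPlan(train, val, test, mode, seed, repeat)

    if mode == "cv":
        rest, test = _stratified_two_way(labelled, labels, 0.1, rng)
        pool = rng.permutation(rest)
        folds = np.array_split(pool, 5)
        if not 0 <= fold < 5:
            raise ValueError("fold must be in 0..4")
        val = sorted(folds[fold].tolist())
        train = sorted(int(i) for k, f in enumerate(folds) if k != fold for i in f)
        return SplitPlan(train, val, test, mode, seed, repeat)

    if mode == "drug_cold":
        drugs = sorted({d for i in labelled for d in (records[i].drug1, records[i].drug2)})
        if len(drugs) < 5:
            raise ValueError("drug_cold needs >= 5 distinct drugs")
        n_known = int(round(0.8 * len(drugs)))
        known = set(rng.permutation(drugs)[:n_known].tolist())
        train_pool = [
            i for i in labelled
            if records[i].drug1 in known and records[i].drug2 in known
        ]
        test = [
            i for i in labelled
            if records[i].drug1 not in known or records[i].drug2 not in known
        ]
        if not train_pool or not test:
            raise ValueError("drug_cold split infeasible for these records")
        train, val = _stratified_two_way(train_pool, labels, 1.0 / 9.0, rng)
        return SplitPlan(train, val, sorted(test), mode, seed, repeat)

    if mode == "combination_cold":
        pairs = sorted({records[i].pair_key() for i in labelled})
        if len(pairs) < 5:
            raise ValueError("combination_cold needs >= 5 distinct pairs")
        n_held = max(1, int(round(0.1 * len(pairs))))
        held = [tuple(p) for p in rng.permutation(pairs)[:n_held]]
        banned = {d for p in held for d in p}
        held_set = set(held)
        test = [i for i in labelled if records[i].pair_key() in held_set]
        train_pool = [
            i for i in labelled
            if records[i].drug1 not in banned and records[i].drug2 not in banned
        ]
        if not train_pool or not test:
            raise ValueError("combination_cold split infeasible for these records")
        train, val = _stratified_two_way(train_pool, labels, 1.0 / 9.0, rng)
        return SplitPlan(train, val, sorted(test), mode, seed, repeat)

    # cell_cold
    cells = sorted({records[i].cell_line for i in labelled})
    if len(cells) < 5:
        raise ValueError("cell_cold needs >= 5 distinct cell lines")
    n_train_cells = int(round(0.8 * len(cells)))
    train_cells = set(rng.permutation(cells)[:n_train_cells].tolist())
    train_pool = [i for i in labelled if records[i].cell_line in train_cells]
    test = [i for i in labelled if records[i].cell_line not in train_cells]
    if not train_pool or not test:
        raise ValueError("cell_cold split infeasible for these records")
    train, val = _stratified_two_way(train_pool, labels, 1.0 / 9.0, rng)
    return SplitPlan(train, val, sorted(test), mode, seed, repeat)


def check_split(records: list[SynergyRecord], plan: SplitPlan) -> int:
    """Count leakage violations of the plan's cold-start constraint."""
    train_ids = plan.train + plan.validation
    violations = 0
    if plan.mode == "drug_cold":
        train_drugs = {
            d for i in train_ids for d in (records[i].drug1, records[i].drug2)
        }
        for i in plan.test:
            if records[i].drug1 in train_drugs and records[i].drug2 in train_drugs:
                violations += 1
    elif plan.mode == "combination_cold":
        train_drugs = {
            d for i in train_ids for d in (records[i].drug1, records[i].drug2)
        }
        for i in plan.test:
            if records[i].drug1 in train_drugs or records[i].drug2 in train_drugs:
                violations += 1
    elif plan.mode == "cell_cold":
        train_cells = {records[i].cell_line for i in train_ids}
        for i in plan.test:
            if records[i].cell_line in train_cells:
                violations += 1
    return violations


def cv_splits(
    records: list[SynergyRecord], seed: int = 0, n_repeats: int = 5, n_folds: int = 5
):
    """Yield the five-times five-fold cross-validation plans."""
    for repeat in range(n_repeats):
        for fold in range(n_folds):
            yield make_split(records, "cv", seed=seed, fold=fold, repeat=repeat)


# ------------------------------------------------------------------ metrics
@dataclass
class MetricReport:
    """AUC-ROC, AUC-PR, F1 and accuracy for one evaluation."""

    auc: float | None
    aupr: float | None
    f1: float
    acc: float
    n: int

    def as_dict(self) -> dict:
        return {"auc": self.auc, "aupr": self.aupr, "f1": self.f1,
                "acc": self.acc, "n": self.n}


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Evaluate positive-class scores against binary labels.

    AUC/AUPR are reported as None when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    preds = (scores >= threshold).astype(int)
    both = len(np.unique(labels)) == 2
    return MetricReport(
        auc=float(roc_auc_score(labels, scores)) if both else None,
        aupr=float(average_precision_score(labels, scores)) if both else None,
        f1=float(f1_score(labels, preds, zero_division=0)),
        acc=float(accuracy_score(labels, preds)),
        n=len(labels),
    )


def aggregate_metrics(reports: list[MetricReport]) -> dict[str, tuple[float, float]]:
    """Mean and standard deviation of each metric across repeats."""
    out = {}
    for name in ("auc", "aupr", "f1", "acc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            out[name] = (float(np.mean(vals)), float(np.std(vals)))
    return out


# ------------------------------------------------------------------ dataset
@dataclass
class SynergyDataset:
    """A bundle compiled into model-ready graphs and index arrays."""

    records: list[SynergyRecord]
    drug_graphs: dict[str, MolecularGraph]
    networks: dict[str, SpecificNetwork]
    cell_graphs: dict[str, ExpressionGraph]
    cell_norm_adj: dict[str, np.ndarray]
    feature_dim: int

    @classmethod
    def from_bundle(cls, bundle: DatasetBundle,
                    induced_edges: bool = False) -> "SynergyDataset":
        drug_graphs = {
            d: smiles_to_graph(s) for d, s in sorted(bundle.drugs.entries.items())
        }
        networks = {}
        cell_graphs = {}
        cell_norm_adj = {}
        for cell, prof in sorted(bundle.profiles.items()):
            net = build_specific_network(
                bundle.ppi, prof.targets, cell_line_id=cell,
                induced_edges=induced_edges,
            )
            networks[cell] = net
            eg = induced_expression_graph(net, prof)
            cell_graphs[cell] = eg
            cell_norm_adj[cell] = normalize_adjacency(eg.adjacency)
        labelled = [r for r in bundle.records if r.label is not None]
        fdim = next(iter(drug_graphs.values())).feature_dim
        return cls(labelled, drug_graphs, networks, cell_graphs, cell_norm_adj, fdim)

    def labels(self, indices=None) -> np.ndarray:
        idx = range(len(self.records)) if indices is None else indices
        return np.array([self.records[i].label for i in idx], dtype=int)


# ----------------------------------------------------------------- training
@dataclass
class TrainConfig:
    """Optimization hyperparameters (the model's are in ModelConfig)."""

    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 200
    patience: int = 20
    mask_lr_mult: float = 3.0
    mask_phase_epochs: int = 30
    weight_decay: float = 0.0
    node_dropout: float = 0.0
    seed: int = 0


class Adam:
    """Adam optimizer over a SynergyNet's parameter dict.

    ``lr_scale`` maps parameter-name prefixes to learning-rate multipliers
    (used to train the mask MLPs faster than the encoders, whose gradients
    dwarf the soft-mask gradients).
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 lr_scale: dict[str, float] | None = None,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.lr_scale = lr_scale or {}
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad ** 2
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            scale = 1.0
            for prefix, mult in self.lr_scale.items():
                if k.startswith(prefix):
                    scale = mult
            p.data -= scale * self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps)
                + self.weight_decay * p.data
            )


def _forward_batch(net: SynergyNet, dataset: SynergyDataset, indices,
                   rng: np.random.Generator | None = None,
                   node_dropout: float = 0.0):
    """Forward pass over a batch; returns stacked tensors and per-record parts.

    Drug and cell encodings are computed once per unique id in the batch.
    ``node_dropout`` (training only) zeroes each gene's expression with the
    given probability (inverted scaling): a predictor that memorizes cell
    identity through one or two marker genes is penalized, while signal
    spread over several genes survives.
    """
    recs = [dataset.records[i] for i in indices]
    drug_ids = sorted({d for r in recs for d in (r.drug1, r.drug2)})
    drug_emb = {d: net.encode_drug(dataset.drug_graphs[d]) for d in drug_ids}
    cell_ids = sorted({r.cell_line for r in recs})
    cell_enc = {}
    for c in cell_ids:
        feats = dataset.cell_graphs[c].features
        if node_dropout > 0.0 and rng is not None:
            keep = rng.random(feats.shape) >= node_dropout
            feats = feats * keep / (1.0 - node_dropout)
        cell_enc[c] = net.encode_cell(dataset.cell_norm_adj[c], feats)
    d_rows, hc_rows, hs_rows, mask_sets = [], [], [], []
    for r in recs:
        d_ij = combine_pair(drug_emb[r.drug1], drug_emb[r.drug2])
        fused = net.fuse(
            cell_enc[r.cell_line], d_ij,
            dataset.cell_graphs[r.cell_line].adjacency,
            dataset.cell_norm_adj[r.cell_line],
        )
        masks = net.masks(fused)
        pair = net.decouple(fused, masks)
        d_rows.append(d_ij)
        hc_rows.append(pair.h_c)
        hs_rows.append(pair.h_s)
        mask_sets.append(masks)
    D = concat(d_rows, axis=0)
    Hc = concat(hc_rows, axis=0)
    Hs = concat(hs_rows, axis=0)
    return D, Hc, Hs, mask_sets


def batch_loss(net: SynergyNet, dataset: SynergyDataset, indices,
               rng: np.random.Generator,
               node_dropout: float = 0.0) -> tuple[LossBundle, Tensor]:
    """Compute the three-part objective on a batch of record indices."""
    cfg = net.config
    labels = dataset.labels(indices)
    D, Hc, Hs, _ = _forward_batch(net, dataset, indices, rng, node_dropout)
    from .model import predict  # local alias to keep the hot path flat

    z_c = predict(concat([D, Hc], axis=1), net._prefixed("head_c."))
    l_causal = causal_loss(z_c, labels)

    if cfg.freeze_masks or (cfg.lambda_bias == 0 and cfg.lambda_interv == 0):
        zero = Tensor(0.0)
        bundle = LossBundle(l_causal, zero, zero, cfg.lambda_bias, cfg.lambda_interv)
        return bundle, z_c

    y_rand = np.zeros((len(indices), 2))
    y_rand[np.arange(len(indices)), rng.integers(0, 2, size=len(indices))] = 1.0
    z_s = predict(Hs, net._prefixed("head_s."))
    l_bias = bias_loss(z_s, y_rand)

    z_interv = []
    for _ in range(cfg.n_interventions):
        perm = rng.permutation(len(indices))
        sel = np.zeros((len(indices), len(indices)))
        sel[np.arange(len(indices)), perm] = 1.0
        h_mix = Hc + (Tensor(sel) @ Hs)
        z_interv.append(predict(concat([D, h_mix], axis=1), net._prefixed("head_c.")))
    l_interv = intervention_loss(z_interv, labels)

    bundle = LossBundle(l_causal, l_bias, l_interv, cfg.lambda_bias, cfg.lambda_interv)
    return bundle, z_c


def predict_scores(net: SynergyNet, dataset: SynergyDataset, indices) -> np.ndarray:
    """Positive-class probabilities z_Gc[:, 1] in evaluation mode."""
    from .model import predict

    scores = np.empty(len(indices))
    step = 256
    indices = list(indices)
    for lo in range(0, len(indices), step):
        chunk = indices[lo:lo + step]
        D, Hc, _, _ = _forward_batch(net, dataset, chunk)
        z = predict(concat([D, Hc], axis=1), net._prefixed("head_c."))
        scores[lo:lo + len(chunk)] = z.data[:, 1]
    return scores


def evaluate(net: SynergyNet, dataset: SynergyDataset, indices) -> MetricReport:
    return compute_metrics(
        predict_scores(net, dataset, indices), dataset.labels(indices)
    )


def _run_epochs(net, dataset, split, config, opt, rng, history, n_epochs,
                early_stop: bool):
    """Inner loop shared by the two training phases.

    The early-stopping monitor is a 3-epoch moving average of validation
    AUC with a short burn-in: on a small validation set single-epoch AUC
    spikes are common, and restoring to a spuriously high early epoch
    discards most of the training.
    """
    best_auc, best_state, best_epoch = -np.inf, net.state_dict(), -1
    burn_in = min(10, max(0, n_epochs // 5))
    val_window: list[float] = []
    train_idx = np.asarray(split.train)
    for epoch in range(n_epochs):
        order = rng.permutation(train_idx)
        comp = np.zeros(4)
        n_batches = 0
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size].tolist()
            net.zero_grad()
            bundle, _ = batch_loss(net, dataset, batch, rng,
                                   node_dropout=config.node_dropout)
            if not np.isfinite(bundle.total.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={bundle.total.data!r}"
                )
            bundle.total.backward()
            opt.step()
            comp += [bundle.l_causal.data, bundle.l_bias.data,
                     bundle.l_interv.data, bundle.total.data]
            n_batches += 1
        comp /= max(n_batches, 1)
        history["l_causal"].append(float(comp[0]))
        history["l_bias"].append(float(comp[1]))
        history["l_interv"].append(float(comp[2]))
        history["total"].append(float(comp[3]))

        val_report = evaluate(net, dataset, split.validation)
        val_auc = val_report.auc if val_report.auc is not None else val_report.acc
        history["val_auc"].append(float(val_auc))
        val_window.append(float(val_auc))
        monitored = float(np.mean(val_window[-3:]))
        if epoch >= burn_in and monitored > best_auc + 1e-6:
            best_auc, best_state, best_epoch = monitored, net.state_dict(), epoch
        elif early_stop and best_epoch >= 0 and epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    if early_stop:
        net.load_state_dict(best_state)
    return best_auc, best_epoch


def train(
    net: SynergyNet,
    dataset: SynergyDataset,
    split: SplitPlan,
    config: TrainConfig,
) -> tuple[SynergyNet, dict]:
    """Two-phase optimization of the total objective with Adam.

    Phase 1 trains the predictive trunk (encoders, attention, heads) with
    the soft masks pinned at their symmetric point, early-stopping on
    validation AUC. Phase 2 freezes the trunk and trains only the mask
    MLPs for ``mask_phase_epochs`` epochs. Because the mask networks score
    nodes from their features alone, they cannot memorize individual cell
    lines; against a frozen trunk the only feature rule that consistently
    lowers the objective across cell lines is to route label-informative
    expression into the causal subgraph — which makes the learned
    attribution direction reproducible instead of dependent on the random
    interplay of trunk and mask updates.

    With ``freeze_masks`` or both loss weights at zero, phase 2 is skipped.
    Returns the network and a history dict with per-epoch loss components
    and validation AUC across both phases.
    """
    rng = np.random.default_rng(config.seed)
    history = {"l_causal": [], "l_bias": [], "l_interv": [], "total": [],
               "val_auc": []}
    opt = Adam(net.params, lr=config.lr,
               lr_scale={"node_mlp.": 0.0, "edge_mlp.": 0.0},
               weight_decay=config.weight_decay)
    best_auc, best_epoch = _run_epochs(
        net, dataset, split, config, opt, rng, history,
        config.epochs, early_stop=True,
    )
    history["best_epoch"] = best_epoch
    history["best_val_auc"] = float(best_auc)

    skip_masks = (net.config.freeze_masks or config.mask_phase_epochs <= 0
                  or (net.config.lambda_bias == 0
                      and net.config.lambda_interv == 0))
    if not skip_masks:
        mask_opt = Adam(net.params, lr=config.lr * config.mask_lr_mult)
        for k in mask_opt.params:
            if not (k.startswith("node_mlp.") or k.startswith("edge_mlp.")):
                mask_opt.lr_scale[k] = 0.0
        # stochastic weight averaging over the mask phase: the averaged mask
        # MLPs retain the consistent (feature-driven) component of the
        # updates while epoch-to-epoch jitter cancels
        swa: dict[str, np.ndarray] = {}
        n_swa = 0
        burn_in = config.mask_phase_epochs // 3
        for ep in range(config.mask_phase_epochs):
            _run_epochs(net, dataset, split, config, mask_opt, rng, history,
                        1, early_stop=False)
            if ep >= burn_in:
                for k, p_ in net.params.items():
                    if k.startswith(("node_mlp.", "edge_mlp.")):
                        swa[k] = swa.get(k, 0.0) + p_.data
                n_swa += 1
        if n_swa:
            for k, acc in swa.items():
                net.params[k].data = acc / n_swa
        history["mask_phase_val_auc"] = history["val_auc"][-1]
    return net, history


# -------------------------------------------------------------- grid search
DEFAULT_GRID = {
    "lr": [1e-2, 1e-3, 1e-4, 1e-5],
    "batch_size": [16, 32, 64, 128, 256],
    "n_attn_layers": [1, 2, 3],
    "pooling": ["max", "mean"],
}


def grid_search(
    dataset: SynergyDataset,
    split: SplitPlan,
    config_space: dict[str, list] | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
):
    """Exhaustive search over the hyperparameter grid.

    Each cell is trained on the training set and scored by validation AUC;
    ties break toward lower learning rate, then smaller batch. Returns
    (best settings dict, winner's test MetricReport, per-cell report list).
    """
    space = dict(config_space) if config_space else dict(DEFAULT_GRID)
    if not space or any(not v for v in space.values()):
        raise ValueError("empty config space")
    base_mc = model_config or ModelConfig()
    base_tc = train_config or TrainConfig()
    keys = sorted(space)
    results = []
    for values in itertools.product(*(space[k] for k in keys)):
        cell = dict(zip(keys, values))
        mc = ModelConfig(**{**base_mc.__dict__,
                            **{k: v for k, v in cell.items()
                               if k in ModelConfig.__dataclass_fields__},
                            "seed": seed})
        tc = TrainConfig(**{**base_tc.__dict__,
                            **{k: v for k, v in cell.items()
                               if k in TrainConfig.__dataclass_fields__},
                            "seed": seed})
        net = SynergyNet(dataset.feature_dim, mc)
        net, history = train(net, dataset, split, tc)
        results.append({
            "settings": cell,
            "val_auc": history["best_val_auc"],
            "net": net,
        })
    results.sort(
        key=lambda r: (
            -r["val_auc"],
            r["settings"].get("lr", np.inf),
            r["settings"].get("batch_size", np.inf),
        )
    )
    winner = results[0]
    test_report = evaluate(winner["net"], dataset, split.test)
    report = [{"settings": r["settings"], "val_auc": r["val_auc"]} for r in results]
    return winner["settings"], test_report, report
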