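"""The causal-attention synergy network.

Architecture, end to end:

1. Each drug's molecular graph is encoded by a shared GCN stack
   (``H^(l) = relu(A_hat H^(l-1) W^(l))``) followed by global max pooling,
   giving a 1 x h vector; a drug pair is the elementwise sum
   ``D_ij = D_i + D_j`` (symmetric in the pair order).
2. The cell line's key-gene expression graph is encoded by its own GCN stack
   over the normalized specific-network adjacency, giving Ce' (Gn x h).
3. Cross-attention fuses the pair with the cell: Q = Ce' W_Q,
   K = D_ij^T W_K, V = Ce' W_V; attention scores softmax(Q K^T / sqrt(b))
   over the gene axis are projected (h -> b) and applied as a Hadamard gate
   V' = A (.) V; the residual concat Cre = [V' || Ce'] keeps the raw cell
   features alongside. Each additional cross-attention layer re-fuses the
   widened features, so the fused width is h + L_att * b.
4. Two MLPs score every node and every edge with complementary
   causal/shortcut attention (softmax over two logits), yielding soft masks
   M_x (nodes) and M_a (edges) with complements 1 - M.
5. Hadamard masking splits the fused graph into a causal subgraph G_c and a
   shortcut subgraph G_s; each is summarized by a GCN + readout into h_Gc,
   h_Gs. Predictions: z_Gc = Phi_c(D_ij || h_Gc) (supervised,
   cross-entropy), z_Gs = Phi_s(h_Gs) (pushed toward random labels via KL),
   and intervened predictions z_G' = Phi_c(D_ij || (h_Gc + h_Gs')) with
   shortcut representations h_Gs' sampled from other samples in the batch
   (backdoor-adjustment surrogate). Total loss:
   L = L_causal + lambda1 * L_bias + lambda2 * L_interv.

The propagation matrix of a masked subgraph is the fixed normalized
adjacency of Asp gated elementwise by the edge mask (self-loops unmasked),
so mask gradients flow through the gate but not through degree
renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, log_clipped, scatter_symmetric
from .featurize import MolecularGraph, normalize_adjacency

__all__ = [
    "ModelConfig",
    "SynergyNet",
    "FusedGraph",
    "MaskSet",
    "SubgraphPair",
    "LossBundle",
    "gcn_forward",
    "encode_drug",
    "combine_pair",
    "cross_attention_fuse",
    "compute_masks",
    "decouple",
    "predict",
    "causal_loss",
    "bias_loss",
    "intervention_loss",
    "total_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and objective hyperparameters.

    ``pooling`` controls the subgraph readout (drug pooling is always global
    max); ``n_interventions`` is the number of shortcut strata |T_hat|
    sampled per step; ``freeze_masks`` pins the causal scores at 1 (the
    plain GCN + cross-attention ablation).
    """

    hidden_dim: int = 32
    attn_dim: int = 16
    n_drug_layers: int = 2
    n_cell_layers: int = 2
    n_attn_layers: int = 1
    mask_hidden: int = 16
    pooling: str = "mean"
    lambda_bias: float = 0.5
    lambda_interv: float = 0.5
    n_interventions: int = 1
    freeze_masks: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1 or self.attn_dim < 1 or self.mask_hidden < 1:
            raise ValueError("dimensions must be >= 1")
        if self.lambda_bias < 0 or self.lambda_interv < 0:
            raise ValueError("loss weights must be >= 0")
        if self.pooling not in ("mean", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.n_attn_layers < 1:
            raise ValueError("need at least one cross-attention layer")

    @property
    def fused_dim(self) -> int:
        return self.hidden_dim + self.n_attn_layers * self.attn_dim


@dataclass
class FusedGraph:
    """Fused drug-aware cell graph G' = (Cre, Asp)."""

    node_features: Tensor          # Gn x (h + L*b)
    adjacency: np.ndarray          # Asp, binary
    normalized_adjacency: np.ndarray
    attention: Tensor | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class MaskSet:
    """Complementary causal/shortcut soft masks for nodes and edges."""

    alpha_c: Tensor                # Gn x 1 causal node scores
    alpha_s: Tensor                # Gn x 1 shortcut node scores
    beta_c: Tensor                 # E causal edge scores (unordered edges)
    beta_s: Tensor
    edge_index: np.ndarray         # E x 2 (i < j), indices into node order

    @property
    def node_mask(self) -> np.ndarray:
        """M_x as a flat array of causal node scores."""
        return self.alpha_c.data.ravel()

    def edge_mask_matrix(self, n: int) -> np.ndarray:
        """M_a: symmetric matrix of causal edge scores on the edge support."""
        m = np.zeros((n, n))
        if len(self.edge_index):
            r, c = self.edge_index[:, 0], self.edge_index[:, 1]
            m[r, c] = m[c, r] = self.beta_c.data
        return m


@dataclass
class SubgraphPair:
    """Causal and shortcut subgraphs with their pooled readouts."""

    features_c: Tensor
    features_s: Tensor
    propagation_c: Tensor
    propagation_s: Tensor
    h_c: Tensor                    # 1 x h readout of G_c
    h_s: Tensor


@dataclass
class LossBundle:
    """The three objective components and their weighted total."""

    l_causal: Tensor
    l_bias: Tensor
    l_interv: Tensor
    lambda_bias: float
    lambda_interv: float
    total: Tensor = field(init=False)

    def __post_init__(self):
        self.total = total_loss(self)


# --------------------------------------------------------------- functional
def gcn_forward(a_hat, h0, weights: list[Tensor]) -> Tensor:
    """Stack of GCN layers H^(l) = relu(A_hat H^(l-1) W^(l))."""
    a_hat = a_hat if isinstance(a_hat, Tensor) else Tensor(a_hat)
    h = h0 if isinstance(h0, Tensor) else Tensor(h0)
    for i, w in enumerate(weights):
        if h.shape[1] != w.shape[0]:
            raise ValueError(
                f"layer {i}: feature dim {h.shape[1]} != weight rows {w.shape[0]}"
            )
        h = (a_hat @ h @ w).relu()
    return h


def _pool(h: Tensor, how: str) -> Tensor:
    pooled = h.max(axis=0) if how == "max" else h.mean(axis=0)
    return pooled.reshape(1, -1)


def encode_drug(graph: MolecularGraph, weights: list[Tensor]) -> Tensor:
    """GCN over the normalized bond adjacency, then global max pooling."""
    a_hat = normalize_adjacency(graph.A)
    h = gcn_forward(a_hat, graph.X, weights)
    return _pool(h, "max")


def combine_pair(d_i: Tensor, d_j: Tensor) -> Tensor:
    """Drug-pair embedding D_ij = D_i + D_j (order-symmetric)."""
    if d_i.shape != d_j.shape:
        raise ValueError(f"dim mismatch: {d_i.shape} vs {d_j.shape}")
    return d_i + d_j


def cross_attention_fuse(
    cell_features: Tensor,
    d_ij: Tensor,
    layer_params: list[dict[str, Tensor]],
    attn_dim: int,
) -> tuple[Tensor, Tensor]:
    """Fuse drug-pair and cell features through cross-attention layers.

    Per layer: Q = Ce W_Q, K = D_ij^T W_K, V = Ce W_V, attention
    softmax(Q K^T / sqrt(b)) normalized over the gene axis, reduced h -> b by
    W_R, gated into V by Hadamard product, and concatenated to the input
    (residual). Returns (fused features, last attention matrix).
    """
    h = cell_features
    if h.shape[0] == 0:
        raise ValueError("cell graph has no nodes")
    attn_red = None
    for params in layer_params:
        k = d_ij.T @ params["Wk"]  # h x b
        q = h @ params["Wq"]
        v = h @ params["Wv"]
        scores = (q @ k.T) / float(np.sqrt(attn_dim))   # Gn x h
        # softmax over the gene axis, rescaled by Gn so the average gate is
        # 1: Hadamard gating would otherwise shrink V' by ~1/Gn relative to
        # the residual stream
        attn = scores.T.softmax_rows().T * float(h.shape[0])
        attn_red = attn @ params["Wr"]                  # Gn x b
        v_prime = attn_red * v
        h = concat([v_prime, h], axis=1)
    return h, attn_red


def _mlp2(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    return ((x @ p["W1"] + p["b1"]).relu() @ p["W2"] + p["b2"])


def compute_masks(
    fused: FusedGraph,
    node_mlp: dict[str, Tensor],
    edge_mlp: dict[str, Tensor],
    freeze: bool = False,
) -> MaskSet:
    """Score nodes and edges with complementary causal/shortcut attention.

    Each node's feature row goes through the node MLP and a 2-way softmax,
    giving (alpha_c, alpha_s) with alpha_c + alpha_s = 1; each unordered
    edge (i, j), i < j, is scored once from the concatenated endpoint
    features, so the edge mask is symmetric by construction. ``freeze``
    replaces all causal scores with 1 (no gradient).
    """
    n = fused.n_nodes
    rows, cols = np.nonzero(np.triu(fused.adjacency, k=1))
    edge_index = np.stack([rows, cols], axis=1) if len(rows) else np.empty((0, 2), int)

    if freeze:
        ones_n = Tensor(np.ones((n, 1)))
        zeros_n = Tensor(np.zeros((n, 1)))
        ones_e = Tensor(np.ones(len(edge_index)))
        zeros_e = Tensor(np.zeros(len(edge_index)))
        return MaskSet(ones_n, zeros_n, ones_e, zeros_e, edge_index)

    node_scores = _mlp2(fused.node_features, node_mlp).softmax_rows()  # Gn x 2
    alpha_c = node_scores @ Tensor([[1.0], [0.0]])
    alpha_s = node_scores @ Tensor([[0.0], [1.0]])

    if len(edge_index):
        hf = fused.node_features
        # gather endpoint rows via selection matrices (keeps autograd simple)
        sel_i = np.zeros((len(edge_index), n))
        sel_j = np.zeros((len(edge_index), n))
        sel_i[np.arange(len(edge_index)), edge_index[:, 0]] = 1.0
        sel_j[np.arange(len(edge_index)), edge_index[:, 1]] = 1.0
        pair_feat = concat([Tensor(sel_i) @ hf, Tensor(sel_j) @ hf], axis=1)
        edge_scores = _mlp2(pair_feat, edge_mlp).softmax_rows()        # E x 2
        beta_c = (edge_scores @ Tensor([[1.0], [0.0]])).reshape(-1)
        beta_s = (edge_scores @ Tensor([[0.0], [1.0]])).reshape(-1)
    else:
        beta_c = Tensor(np.empty(0))
        beta_s = Tensor(np.empty(0))
    return MaskSet(alpha_c, alpha_s, beta_c, beta_s, edge_index)


def decouple(
    fused: FusedGraph,
    masks: MaskSet,
    gcn_weights: list[Tensor],
    pooling: str = "mean",
) -> SubgraphPair:
    """Split the fused graph into causal/shortcut subgraphs and read them out.

    Node features are gated by the node masks (causal: alpha_c, shortcut:
    alpha_s = 1 - alpha_c), so the two feature sets sum exactly to the fused
    features. The propagation matrices gate the fixed normalized adjacency
    by the corresponding edge mask, leaving self-loops intact.
    """
    n = fused.n_nodes
    feats_c = fused.node_features * masks.alpha_c
    feats_s = fused.node_features * masks.alpha_s

    a_hat = Tensor(fused.normalized_adjacency)
    eye = Tensor(np.eye(n))
    if len(masks.edge_index):
        rows, cols = masks.edge_index[:, 0], masks.edge_index[:, 1]
        gate_c = scatter_symmetric(masks.beta_c, rows, cols, n) + eye
        gate_s = scatter_symmetric(masks.beta_s, rows, cols, n) + eye
    else:
        gate_c = gate_s = eye
    prop_c = a_hat * gate_c
    prop_s = a_hat * gate_s

    h_c = _pool(gcn_forward(prop_c, feats_c, gcn_weights), pooling)
    h_s = _pool(gcn_forward(prop_s, feats_s, gcn_weights), pooling)
    return SubgraphPair(feats_c, feats_s, prop_c, prop_s, h_c, h_s)


def predict(inputs: Tensor, head: dict[str, Tensor]) -> Tensor:
    """Classifier head -> 2-class probability row vector(s).

    The head is a one-hidden-layer MLP; the synergy label depends on the
    *product* of cell responsiveness and the drug-pair effect, which a
    purely linear readout cannot represent.
    """
    return _mlp2(inputs, head).softmax_rows()


def causal_loss(z: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy -(1/|D|) sum y^T log z over the batch."""
    y = np.zeros(z.shape)
    y[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return -(Tensor(y) * log_clipped(z)).sum() / z.shape[0]


def bias_loss(z: Tensor, y_rand: np.ndarray) -> Tensor:
    """Mean KL(y_rand || z): push shortcut predictions toward random targets.

    Rows of ``y_rand`` are probability vectors; entropy terms with y = 0
    contribute zero (0 log 0 := 0).
    """
    y = np.asarray(y_rand, dtype=float)
    with np.errstate(divide="ignore"):
        ent = np.where(y > 0, y * np.log(np.maximum(y, 1e-300)), 0.0).sum()
    cross = -(Tensor(y) * log_clipped(z)).sum()
    return (cross + ent) / z.shape[0]


def intervention_loss(z_interv: list[Tensor], labels: np.ndarray) -> Tensor:
    """Cross-entropy of intervened predictions, averaged over strata.

    ``z_interv`` holds one batch of predictions per sampled shortcut stratum
    t' in T_hat; the loss averages over both the batch and the strata.
    """
    if not z_interv:
        raise ValueError("empty intervention pool")
    terms = [causal_loss(z, labels) for z in z_interv]
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out / len(terms)


def total_loss(bundle: LossBundle) -> Tensor:
    """L = L_causal + lambda1 * L_bias + lambda2 * L_interv."""
    return (
        bundle.l_causal
        + bundle.lambda_bias * bundle.l_bias
        + bundle.lambda_interv * bundle.l_interv
    )


# ------------------------------------------------------------------ network
class SynergyNet:
    """Parameter container + forward pass for the full model."""

    def __init__(self, feature_dim: int, config: ModelConfig):
        self.config = config
        self.feature_dim = feature_dim
        rng = np.random.default_rng(config.seed)
        c = config
        self.params: dict[str, Tensor] = {}

        def glorot(name, shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            self.params[name] = Tensor(
                rng.uniform(-limit, limit, size=shape), requires_grad=True
            )

        def zeros(name, shape):
            self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

        dims_d = [feature_dim] + [c.hidden_dim] * c.n_drug_layers
        for i in range(c.n_drug_layers):
            glorot(f"drug_gcn.{i}", (dims_d[i], dims_d[i + 1]))
        dims_c = [1] + [c.hidden_dim] * c.n_cell_layers
        for i in range(c.n_cell_layers):
            glorot(f"cell_gcn.{i}", (dims_c[i], dims_c[i + 1]))
        width = c.hidden_dim
        for l in range(c.n_attn_layers):
            glorot(f"attn.{l}.Wq", (width, c.attn_dim))
            glorot(f"attn.{l}.Wk", (1, c.attn_dim))
            glorot(f"attn.{l}.Wv", (width, c.attn_dim))
            glorot(f"attn.{l}.Wr", (c.hidden_dim, c.attn_dim))
            width += c.attn_dim
        fd = c.fused_dim
        # mask MLPs: output layers start at zero so every node/edge begins
        # at exactly (0.5, 0.5) — the causal/shortcut assignment is then set
        # by the first consistent gradients instead of the random init
        glorot("node_mlp.W1", (fd, c.mask_hidden))
        zeros("node_mlp.b1", (1, c.mask_hidden))
        zeros("node_mlp.W2", (c.mask_hidden, 2))
        zeros("node_mlp.b2", (1, 2))
        glorot("edge_mlp.W1", (2 * fd, c.mask_hidden))
        zeros("edge_mlp.b1", (1, c.mask_hidden))
        zeros("edge_mlp.W2", (c.mask_hidden, 2))
        zeros("edge_mlp.b2", (1, 2))
        glorot("dec_gcn.0", (fd, c.hidden_dim))
        glorot("head_c.W1", (2 * c.hidden_dim, c.hidden_dim))
        zeros("head_c.b1", (1, c.hidden_dim))
        glorot("head_c.W2", (c.hidden_dim, 2))
        zeros("head_c.b2", (1, 2))
        glorot("head_s.W1", (c.hidden_dim, c.hidden_dim))
        zeros("head_s.b1", (1, c.hidden_dim))
        glorot("head_s.W2", (c.hidden_dim, 2))
        zeros("head_s.b2", (1, 2))

    # -- parameter views ---------------------------------------------------
    def _prefixed(self, prefix: str) -> dict[str, Tensor]:
        return {
            k[len(prefix):]: v for k, v in self.params.items() if k.startswith(prefix)
        }

    @property
    def drug_weights(self) -> list[Tensor]:
        return [
            self.params[f"drug_gcn.{i}"] for i in range(self.config.n_drug_layers)
        ]

    @property
    def cell_weights(self) -> list[Tensor]:
        return [
            self.params[f"cell_gcn.{i}"] for i in range(self.config.n_cell_layers)
        ]

    @property
    def attn_layers(self) -> list[dict[str, Tensor]]:
        return [
            self._prefixed(f"attn.{l}.") for l in range(self.config.n_attn_layers)
        ]

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- forward pieces ----------------------------------------------------
    def encode_drug(self, graph: MolecularGraph) -> Tensor:
        return encode_drug(graph, self.drug_weights)

    def encode_cell(self, a_hat: np.ndarray, features: np.ndarray) -> Tensor:
        return gcn_forward(a_hat, features, self.cell_weights)

    def fuse(self, cell_encoding: Tensor, d_ij: Tensor, adjacency: np.ndarray,
             a_hat: np.ndarray) -> FusedGraph:
        fused_feats, attn = cross_attention_fuse(
            cell_encoding, d_ij, self.attn_layers, self.config.attn_dim
        )
        return FusedGraph(fused_feats, adjacency, a_hat, attention=attn)

    def masks(self, fused: FusedGraph) -> MaskSet:
        return compute_masks(
            fused,
            self._prefixed("node_mlp."),
            self._prefixed("edge_mlp."),
            freeze=self.config.freeze_masks,
        )

    def decouple(self, fused: FusedGraph, masks: MaskSet) -> SubgraphPair:
        return decouple(
            fused, masks, [self.params["dec_gcn.0"]], self.config.pooling
        )

    def predict_causal(self, d_ij: Tensor, h_c: Tensor) -> Tensor:
        return predict(concat([d_ij, h_c], axis=1), self._prefixed("head_c."))

    def predict_shortcut(self, h_s: Tensor) -> Tensor:
        return predict(h_s, self._prefixed("head_s."))


def save_checkpoint(net: SynergyNet, path,
                    node_manifests: dict[str, list[str]] | None = None) -> None:
    """Serialize parameters, config and the specific-network node orders.

    The node manifests are required to interpret the causal node mask M_x
    later: mask positions are meaningful only relative to the node order
    the model was trained with.
    """
    import json

    meta = {
        "config": net.config.__dict__,
        "feature_dim": net.feature_dim,
        "node_manifests": node_manifests or {},
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **net.state_dict())


def load_checkpoint(path) -> tuple[SynergyNet, dict[str, list[str]]]:
    """Restore a SynergyNet (and its node manifests) from save_checkpoint."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net = SynergyNet(meta["feature_dim"], ModelConfig(**meta["config"]))
    net.load_state_dict(state)
    return net, meta["node_manifests"]
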