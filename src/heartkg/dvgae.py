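"""Directed variational graph auto-encoder (DVGAE).

A VGAE variant whose encoder consumes four signals the plain model ignores:
node type, node properties, edge properties, and edge direction.  Direction
enters through two-channel message passing — each graph-convolution layer
aggregates in-neighbors and out-neighbors with separate weight matrices —
and edge properties gate messages through a learned scalar per edge.  The
decoder is the standard inner product: p(u -> v) = sigmoid(z_u . z_v).

Losses:

* reconstruction: -(1/|E+|) sum log(sigmoid(z_u . z_v) + eps) over observed
  edges (a symmetric term over sampled non-edges joins it during training —
  negatives provide the contrastive signal, otherwise the inner-product
  objective is unbounded);
* KL: per node, -1/2 sum_j (1 + log s_j^2 - m_j^2 - s_j^2), averaged over
  nodes (the standard VGAE normalization);
* total: reconstruction + KL / N with N the node count.

Everything runs on CPU in numpy; gradients are derived by hand and the
optimizer is Adam.  All randomness flows from a single integer seed, so
training is reproducible bit-for-bit on fixed hardware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .graph import NODE_TYPES, KnowledgeGraph

logger = logging.getLogger(__name__)

LEARNING_RATE_GRID = (0.001, 0.01, 0.1)
EPOCHS_GRID = (50, 100, 200)
LATENT_DIM_GRID = (25, 50, 100)

NODE_TYPE_ORDER = tuple(sorted(NODE_TYPES))


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of one DVGAE fit.

    The grid defaults mirror the search space used for model selection:
    learning rate in {0.001, 0.01, 0.1}, epochs in {50, 100, 200}, latent
    dimension in {25, 50, 100}; the selected configuration is lr 0.001,
    100 epochs, J = 50.
    """

    learning_rate: float = 0.001
    epochs: int = 100
    latent_dim: int = 50
    layers: int = 2
    seed: int = 0
    epsilon: float = 1e-15
    hidden_dim: int | None = None  # default 2 * latent_dim
    batch_size: int = 512
    #: width of the learned per-node input embedding concatenated to the
    #: type/property features (node identity signal; default latent_dim)
    node_embedding_dim: int | None = None
    #: extra multiplier on the KL term (1.0 = the standard objective);
    #: mainly a diagnostic knob
    kl_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.layers < 1:
            raise ValueError("need at least one graph-convolution layer")

    @property
    def hidden(self) -> int:
        return self.hidden_dim if self.hidden_dim is not None else 2 * self.latent_dim

    @property
    def node_emb(self) -> int:
        return self.node_embedding_dim if self.node_embedding_dim is not None else self.latent_dim

    def key(self) -> str:
        return f"lr={self.learning_rate:g},epochs={self.epochs},J={self.latent_dim}"


def default_grid(seed: int = 0) -> list[EncoderConfig]:
    """The full 27-point hyperparameter grid."""
    return [
        EncoderConfig(learning_rate=lr, epochs=ep, latent_dim=j, seed=seed)
        for lr in LEARNING_RATE_GRID
        for ep in EPOCHS_GRID
        for j in LATENT_DIM_GRID
    ]


@dataclass
class FeaturizedGraph:
    """Numeric view of a knowledge graph: features + directed adjacency."""

    node_ids: list[str]
    X: np.ndarray             # (n, f) one-hot type + standardized properties
    edge_index: np.ndarray    # (2, m) int — (source, target) node indices
    edge_feat: np.ndarray     # (m, fe) standardized numeric edge properties
    feature_names: list[str]
    edge_feature_names: list[str]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.edge_index[0].tolist(), self.edge_index[1].tolist()))


def _standardize_columns(values: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Z-score each column over its present entries; absent and
    zero-variance entries become 0."""
    out = np.zeros_like(values)
    for j in range(values.shape[1]):
        mask = present[:, j]
        if not mask.any():
            continue
        col = values[mask, j]
        mu, sd = col.mean(), col.std()
        if sd > 0:
            out[mask, j] = (col - mu) / sd
    return out


def featurize(kg: KnowledgeGraph) -> FeaturizedGraph:
    """Build node features, directed adjacency and edge features.

    Node features are the one-hot node type concatenated with one
    standardized column plus one presence flag per numeric node property.
    Edge features are standardized numeric edge properties.  Direction is
    kept exactly as stored.
    """
    if kg.n_edges == 0:
        raise ValueError("graph has no edges; nothing to reconstruct")

    node_ids = kg.node_ids
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    prop_keys = sorted({
        k for node in kg.nodes for k, v in node.properties.items()
        if isinstance(v, (int, float)) and not isinstance(v, bool)
    })
    type_block = np.zeros((n, len(NODE_TYPE_ORDER)))
    values = np.zeros((n, len(prop_keys)))
    present = np.zeros((n, len(prop_keys)), dtype=bool)
    for i, node in enumerate(kg.nodes):
        type_block[i, NODE_TYPE_ORDER.index(node.node_type)] = 1.0
        for j, k in enumerate(prop_keys):
            v = node.properties.get(k)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                values[i, j] = float(v)
                present[i, j] = True
    X = np.concatenate([type_block, _standardize_columns(values, present), present.astype(float)], axis=1)
    feature_names = (
        [f"type:{t}" for t in NODE_TYPE_ORDER]
        + [f"prop:{k}" for k in prop_keys]
        + [f"has:{k}" for k in prop_keys]
    )

    # directed pairs, relation types merged for reconstruction purposes
    pairs = sorted(kg.directed_pairs())
    edge_index = np.array(
        [[index[s] for s, _ in pairs], [index[t] for _, t in pairs]], dtype=np.int64
    )
    eprop_keys = sorted({
        k for e in kg.edges for k, v in e.properties.items()
        if isinstance(v, (int, float)) and not isinstance(v, bool)
    })
    evalues = np.zeros((len(pairs), len(eprop_keys)))
    epresent = np.zeros((len(pairs), len(eprop_keys)), dtype=bool)
    pair_pos = {p: i for i, p in enumerate(pairs)}
    for e in kg.edges:
        row = pair_pos[(e.source_id, e.target_id)]
        for j, k in enumerate(eprop_keys):
            v = e.properties.get(k)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                evalues[row, j] = float(v)
                epresent[row, j] = True
    edge_feat = _standardize_columns(evalues, epresent)
    return FeaturizedGraph(
        node_ids=node_ids,
        X=X,
        edge_index=edge_index,
        edge_feat=edge_feat,
        feature_names=feature_names,
        edge_feature_names=[f"eprop:{k}" for k in eprop_keys],
        index=index,
    )


# -- closed-form losses ----------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode_edge_probability(z_u: np.ndarray, z_v: np.ndarray) -> float:
    """Inner-product decoder: sigmoid(z_u . z_v)."""
    z_u = np.asarray(z_u, dtype=float)
    z_v = np.asarray(z_v, dtype=float)
    if z_u.shape != z_v.shape:
        raise ValueError(f"embedding length mismatch: {z_u.shape} vs {z_v.shape}")
    return float(_sigmoid(np.atleast_1d(z_u @ z_v))[0])


def reconstruction_loss(
    z: np.ndarray, positive_edges: np.ndarray, epsilon: float = 1e-15
) -> float:
    """-(1/|E+|) sum over observed edges of log(sigmoid(z_u . z_v) + eps)."""
    positive_edges = np.asarray(positive_edges)
    if positive_edges.size == 0:
        raise ValueError("positive edge set is empty")
    src, dst = positive_edges[0], positive_edges[1]
    dots = np.einsum("ij,ij->i", z[src], z[dst])
    return float(-np.mean(np.log(_sigmoid(dots) + epsilon)))


def kl_loss(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL(q || N(0, I)) summed over nodes and latent dimensions."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(-0.5 * np.sum(1.0 + np.log(sigma**2) - mu**2 - sigma**2))


def total_loss(recon: float, kl: float, n_nodes: int) -> float:
    """Total objective: reconstruction + KL / N, N the node count."""
    if n_nodes < 1:
        raise ValueError("node count must be >= 1")
    return float(recon + kl / n_nodes)


def reparameterize(mu: np.ndarray, sigma: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I), seeded."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape != sigma.shape:
        raise ValueError("mu and sigma must have identical shapes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return mu + sigma * rng.standard_normal(mu.shape)


def edge_wise_accuracy(
    original_edges: Iterable[tuple], reconstructed_edges: Iterable[tuple]
) -> float:
    """|original ∩ reconstructed| / |original|."""
    original = set(original_edges)
    if not original:
        raise ValueError("original edge set is empty")
    return len(original & set(reconstructed_edges)) / len(original)


# -- negative sampling -----------------------------------------------------

def sample_negative_pairs(
    n_nodes: int,
    existing: set[tuple[int, int]],
    count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """`count` distinct directed non-edges (no self-loops), as a (2, count) array."""
    capacity = n_nodes * (n_nodes - 1) - len(existing)
    if count > capacity:
        raise ValueError(
            f"cannot sample {count} negative edges; only {capacity} non-edges exist"
        )
    chosen: set[tuple[int, int]] = set()
    # rejection sampling; falls back to exhaustive enumeration when the
    # non-edge pool is nearly exhausted
    attempts = 0
    while len(chosen) < count and attempts < 200:
        need = count - len(chosen)
        src = rng.integers(0, n_nodes, size=2 * need + 8)
        dst = rng.integers(0, n_nodes, size=2 * need + 8)
        for u, v in zip(src.tolist(), dst.tolist()):
            if u == v or (u, v) in existing or (u, v) in chosen:
                continue
            chosen.add((u, v))
            if len(chosen) == count:
                break
        attempts += 1
    if len(chosen) < count:
        pool = [
            (u, v)
            for u in range(n_nodes)
            for v in range(n_nodes)
            if u != v and (u, v) not in existing and (u, v) not in chosen
        ]
        idx = rng.choice(len(pool), size=count - len(chosen), replace=False)
        chosen.update(pool[i] for i in idx)
    ordered = sorted(chosen)
    rng.shuffle(ordered)
    return np.array(ordered, dtype=np.int64).T


def sample_negative_edges(
    kg: KnowledgeGraph, count: int, seed: int
) -> set[tuple[str, str]]:
    """Seeded sample of directed node-id pairs absent from the graph."""
    feats_index = {nid: i for i, nid in enumerate(kg.node_ids)}
    existing = {
        (feats_index[s], feats_index[t]) for s, t in kg.directed_pairs()
    }
    arr = sample_negative_pairs(kg.n_nodes, existing, count, np.random.default_rng(seed))
    ids = kg.node_ids
    return {(ids[u], ids[v]) for u, v in arr.T}


# -- the model -------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _ConvParams:
    """One directed graph-convolution layer: self, in-neighbor and
    out-neighbor weight matrices plus a bias."""

    def __init__(self, rng: np.random.Generator, fin: int, fout: int):
        self.Ws = _glorot(rng, fin, fout)
        self.Wi = _glorot(rng, fin, fout)
        self.Wo = _glorot(rng, fin, fout)
        self.b = np.zeros(fout)

    def params(self):
        return [self.Ws, self.Wi, self.Wo, self.b]


@dataclass
class LatentEmbeddings:
    """Per-node variational posterior (mu, sigma) and a sampled code z."""

    node_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if not (self.mu.shape == self.sigma.shape == self.z.shape):
            raise ValueError("mu, sigma, z must share one shape")
        if self.mu.shape[0] != len(self.node_ids):
            raise ValueError("row count must equal node count")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


class DVGAE:
    """Two-channel directed graph-convolutional variational auto-encoder.

    Input to the first convolution is the featurizer output concatenated
    with a learned per-node embedding (the node-identity signal an
    anonymous heterogeneous graph otherwise lacks); direction enters via
    separate in- and out-neighbor aggregation weights, and edge properties
    via a learned per-edge scalar gate.
    """

    def __init__(self, config: EncoderConfig, n_features: int,
                 n_edge_features: int = 0, n_nodes: int | None = None):
        self.config = config
        self.n_features = n_features
        self.n_edge_features = n_edge_features
        rng = np.random.default_rng(config.seed)
        k = config.node_emb if n_nodes else 0
        self.n_nodes = n_nodes or 0
        self.P = (
            rng.standard_normal((self.n_nodes, k)) / np.sqrt(max(k, 1))
            if k else np.zeros((self.n_nodes, 0))
        )
        dims = [n_features + self.P.shape[1]] + [config.hidden] * (config.layers - 1)
        self.hidden_layers = [
            _ConvParams(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)
        ]
        self.head_mu = _ConvParams(rng, dims[-1], config.latent_dim)
        self.head_lv = _ConvParams(rng, dims[-1], config.latent_dim)
        # per-edge gate: sigmoid(w . e_feat + b); with no edge features the
        # gate is a single learned global scalar
        self.gate_w = np.zeros(n_edge_features)
        self.gate_b = np.array(2.0)  # start near-open (sigmoid(2) ~ 0.88)
        self.trained = False

    # ---- parameter plumbing ------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        ps: list[np.ndarray] = []
        for layer in self.hidden_layers + [self.head_mu, self.head_lv]:
            ps.extend(layer.params())
        ps.append(self.P)
        ps.append(self.gate_w)
        ps.append(self.gate_b)
        return ps

    # ---- forward ------------------------------------------------------
    def _adjacency(self, n: int, edge_index: np.ndarray, edge_feat: np.ndarray):
        m = edge_index.shape[1]
        if self.n_edge_features:
            gate_logit = edge_feat @ self.gate_w + self.gate_b
        else:
            gate_logit = np.full(m, float(self.gate_b))
        g = _sigmoid(gate_logit)
        src, dst = edge_index
        din = np.maximum(np.bincount(dst, minlength=n), 1)
        dout = np.maximum(np.bincount(src, minlength=n), 1)
        win = g / din[dst]
        wout = g / dout[src]
        A_in = sp.csr_matrix((win, (dst, src)), shape=(n, n))
        A_out = sp.csr_matrix((wout, (src, dst)), shape=(n, n))
        return g, A_in, A_out, din, dout

    def _conv(self, layer: _ConvParams, H, A_in, A_out):
        Mi = A_in @ H
        Mo = A_out @ H
        Y = H @ layer.Ws + Mi @ layer.Wi + Mo @ layer.Wo + layer.b
        return Y, Mi, Mo

    def forward(self, X: np.ndarray, edge_index: np.ndarray, edge_feat: np.ndarray):
        """Full forward pass; returns (mu, sigma, cache for backprop)."""
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} does not match model ({self.n_features})"
            )
        n = X.shape[0]
        if self.P.shape[1]:
            if self.n_nodes != n:
                raise ValueError(
                    f"model was built for {self.n_nodes} nodes, got {n}"
                )
            H0 = np.concatenate([X, self.P], axis=1)
        else:
            H0 = X
        g, A_in, A_out, din, dout = self._adjacency(n, edge_index, edge_feat)
        cache = {"X": X, "edge_index": edge_index, "edge_feat": edge_feat,
                 "g": g, "A_in": A_in, "A_out": A_out, "din": din, "dout": dout,
                 "hidden": []}
        H = H0
        for layer in self.hidden_layers:
            Y, Mi, Mo = self._conv(layer, H, A_in, A_out)
            Hn = np.maximum(Y, 0.0)
            cache["hidden"].append({"H_in": H, "Mi": Mi, "Mo": Mo, "Y": Y, "H_out": Hn})
            H = Hn
        mu, Mi_mu, Mo_mu = self._conv(self.head_mu, H, A_in, A_out)
        lv, Mi_lv, Mo_lv = self._conv(self.head_lv, H, A_in, A_out)
        lv = np.clip(lv, -10.0, 10.0)
        cache.update({
            "H_top": H, "Mi_mu": Mi_mu, "Mo_mu": Mo_mu,
            "Mi_lv": Mi_lv, "Mo_lv": Mo_lv, "mu": mu, "lv": lv,
        })
        sigma = np.exp(0.5 * lv)
        return mu, sigma, cache

    def encode(self, feats: FeaturizedGraph,
               edge_index: np.ndarray | None = None,
               edge_feat: np.ndarray | None = None) -> LatentEmbeddings:
        """Deterministic posterior parameters plus a seeded sample z."""
        ei = feats.edge_index if edge_index is None else edge_index
        ef = feats.edge_feat if edge_feat is None else edge_feat
        mu, sigma, _ = self.forward(feats.X, ei, ef)
        z = reparameterize(mu, sigma, self.config.seed)
        return LatentEmbeddings(feats.node_ids, mu, sigma, z)

    # ---- backward -----------------------------------------------------
    def _conv_backward(self, layer: _ConvParams, dY, H_in, Mi, Mo, A_in, A_out,
                       grads: dict, gid: int, dg_accum: np.ndarray,
                       edge_index: np.ndarray, din, dout):
        grads[f"{gid}.Ws"] = grads.get(f"{gid}.Ws", 0) + H_in.T @ dY
        grads[f"{gid}.Wi"] = grads.get(f"{gid}.Wi", 0) + Mi.T @ dY
        grads[f"{gid}.Wo"] = grads.get(f"{gid}.Wo", 0) + Mo.T @ dY
        grads[f"{gid}.b"] = grads.get(f"{gid}.b", 0) + dY.sum(axis=0)
        dMi = dY @ layer.Wi.T
        dMo = dY @ layer.Wo.T
        dH = dY @ layer.Ws.T + A_in.T @ dMi + A_out.T @ dMo
        src, dst = edge_index
        # gate gradient through both aggregation channels
        dg_accum += np.einsum("ij,ij->i", dMi[dst], H_in[src]) / din[dst]
        dg_accum += np.einsum("ij,ij->i", dMo[src], H_in[dst]) / dout[src]
        return dH

    def backward(self, cache: dict, dmu: np.ndarray, dlv: np.ndarray) -> dict:
        """Gradients of the loss w.r.t. every parameter given head grads."""
        grads: dict = {}
        edge_index = cache["edge_index"]
        din, dout = cache["din"], cache["dout"]
        A_in, A_out = cache["A_in"], cache["A_out"]
        dg = np.zeros_like(cache["g"])
        dlv = dlv * ((cache["lv"] > -10.0) & (cache["lv"] < 10.0))
        dH = self._conv_backward(
            self.head_mu, dmu, cache["H_top"], cache["Mi_mu"], cache["Mo_mu"],
            A_in, A_out, grads, len(self.hidden_layers), dg, edge_index, din, dout,
        )
        dH += self._conv_backward(
            self.head_lv, dlv, cache["H_top"], cache["Mi_lv"], cache["Mo_lv"],
            A_in, A_out, grads, len(self.hidden_layers) + 1, dg, edge_index, din, dout,
        )
        for li in range(len(self.hidden_layers) - 1, -1, -1):
            hc = self.hidden_layers[li]
            c = cache["hidden"][li]
            dY = dH * (c["Y"] > 0)
            dH = self._conv_backward(
                hc, dY, c["H_in"], c["Mi"], c["Mo"], A_in, A_out,
                grads, li, dg, edge_index, din, dout,
            )
        # the tail columns of the input gradient belong to the learned
        # per-node embedding
        grads["P"] = (
            dH[:, self.n_features:] if self.P.shape[1] else np.zeros((self.n_nodes, 0))
        )
        # through the gate nonlinearity
        g = cache["g"]
        dlogit = dg * g * (1.0 - g)
        if self.n_edge_features:
            grads["gate_w"] = cache["edge_feat"].T @ dlogit
        else:
            grads["gate_w"] = np.zeros(0)
        grads["gate_b"] = np.array(dlogit.sum())
        return grads

    def _grad_list(self, grads: dict) -> list[np.ndarray]:
        out = []
        n_hidden = len(self.hidden_layers)
        for gid in list(range(n_hidden)) + [n_hidden, n_hidden + 1]:
            for name in ("Ws", "Wi", "Wo", "b"):
                out.append(np.asarray(grads[f"{gid}.{name}"], dtype=float))
        out.append(np.asarray(grads["P"], dtype=float))
        out.append(np.asarray(grads["gate_w"], dtype=float))
        out.append(np.asarray(grads["gate_b"], dtype=float))
        return out


@dataclass
class TrainSplit:
    """70/30 edge split plus sampled validation negatives (index pairs)."""

    train_edges: np.ndarray       # (2, m_train)
    validation_edges: np.ndarray  # (2, m_val)
    negative_validation_edges: np.ndarray
    seed: int


def split_edges(feats: FeaturizedGraph, seed: int, train_frac: float = 0.7) -> TrainSplit:
    m = feats.n_edges
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_train = int(round(train_frac * m))
    if n_train == 0 or n_train == m:
        raise ValueError("degenerate split: one side has no edges")
    tr, va = perm[:n_train], perm[n_train:]
    negs = sample_negative_pairs(feats.n_nodes, feats.pairs(), len(va), rng)
    return TrainSplit(feats.edge_index[:, tr], feats.edge_index[:, va], negs, seed)


@dataclass
class LossReport:
    """Validation losses of one configuration."""

    recon: float
    kl: float
    total: float
    n_nodes: int
    trace: list[float]
    config_key: str


def _bce_terms(z, pos, neg, epsilon):
    sp_ = np.einsum("ij,ij->i", z[pos[0]], z[pos[1]])
    sn = np.einsum("ij,ij->i", z[neg[0]], z[neg[1]])
    lp = float(-np.mean(np.log(_sigmoid(sp_) + epsilon)))
    ln = float(-np.mean(np.log(1.0 - _sigmoid(sn) + epsilon)))
    return lp + ln


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p, dtype=float) for p in params]
        self.v = [np.zeros_like(p, dtype=float) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _fit(model: DVGAE, feats: FeaturizedGraph, train_edges: np.ndarray,
         split: TrainSplit | None, rng: np.random.Generator) -> list[float]:
    """Mini-batch Adam training on `train_edges`; returns the per-epoch
    validation-loss trace (empty when no split is given)."""
    cfg = model.config
    n = feats.n_nodes
    all_pairs = feats.pairs()
    # message passing sees only the training edges
    train_keys = set(map(tuple, train_edges.T.tolist()))
    tr_mask = np.array([
        (u, v) in train_keys for u, v in feats.edge_index.T.tolist()
    ])
    ei = feats.edge_index[:, tr_mask]
    ef = feats.edge_feat[tr_mask]
    opt = _Adam(model.parameters(), cfg.learning_rate)
    m_train = train_edges.shape[1]
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(m_train)
        for start in range(0, m_train, cfg.batch_size):
            batch = train_edges[:, order[start:start + cfg.batch_size]]
            nb = sample_negative_pairs(n, all_pairs, batch.shape[1], rng)
            mu, sigma, cache = model.forward(feats.X, ei, ef)
            eps_draw = rng.standard_normal(mu.shape)
            z = mu + sigma * eps_draw
            # d(BCE)/dz for positive and negative batch pairs
            dz = np.zeros_like(z)
            s_pos = np.einsum("ij,ij->i", z[batch[0]], z[batch[1]])
            s_neg = np.einsum("ij,ij->i", z[nb[0]], z[nb[1]])
            cp = (_sigmoid(s_pos) - 1.0) / batch.shape[1]
            cn = _sigmoid(s_neg) / nb.shape[1]
            np.add.at(dz, batch[0], cp[:, None] * z[batch[1]])
            np.add.at(dz, batch[1], cp[:, None] * z[batch[0]])
            np.add.at(dz, nb[0], cn[:, None] * z[nb[1]])
            np.add.at(dz, nb[1], cn[:, None] * z[nb[0]])
            # KL contribution: the node-mean KL enters the total as
            # mean_KL / N (the standard VGAE normalization), so the
            # per-node gradient carries 1/N^2
            beta = cfg.kl_weight / (n * n)
            dmu = dz + beta * mu
            dlv = dz * (0.5 * sigma * eps_draw) + beta * 0.5 * (sigma**2 - 1.0)
            grads = model.backward(cache, dmu, dlv)
            opt.step(model._grad_list(grads))
        if split is not None:
            mu, sigma, _ = model.forward(feats.X, ei, ef)
            recon = _bce_terms(mu, split.validation_edges,
                               split.negative_validation_edges, cfg.epsilon)
            trace.append(total_loss(recon, kl_loss(mu, sigma) / n, n))
    model.trained = True
    return trace


@dataclass
class TrainResult:
    """Outcome of a grid-search training run.

    ``embeddings`` come from the final model; ``selection_embeddings`` from
    the split-trained winner on the training-edge adjacency (the honest
    view for held-out edge evaluation).
    """

    model: DVGAE
    config: EncoderConfig
    feats: FeaturizedGraph
    embeddings: LatentEmbeddings
    reports: list[LossReport]
    split: TrainSplit
    selection_embeddings: LatentEmbeddings | None = None


def train(
    kg: KnowledgeGraph,
    grid: Sequence[EncoderConfig] | None = None,
    seed: int = 0,
    refit_full: bool = True,
) -> TrainResult:
    """Grid-search DVGAE training.

    For each configuration the edge set is split 70/30, the model is fit on
    the training edges, and the validation loss (reconstruction on
    validation positives plus 1:1 sampled negatives, plus KL / N) is traced
    per epoch.  The configuration with the lowest final validation loss
    wins (ties broken by grid order); the winner is then refit on the full
    edge set to produce the final embeddings.
    """
    if grid is None:
        grid = [EncoderConfig(seed=seed)]
    grid = [replace(c, seed=seed) for c in grid]
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    feats = featurize(kg)
    split = split_edges(feats, seed)
    reports: list[LossReport] = []
    best_i, best_loss, best_model = 0, np.inf, None
    for i, cfg in enumerate(grid):
        model = DVGAE(cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        rng = np.random.default_rng(cfg.seed + 1)
        trace = _fit(model, feats, split.train_edges, split, rng)
        mu, sigma, _ = model.forward(
            feats.X,
            *_train_view(feats, split),
        )
        recon = _bce_terms(mu, split.validation_edges,
                           split.negative_validation_edges, cfg.epsilon)
        # node-mean KL; the total then scales it by a further 1/N
        kl = kl_loss(mu, sigma) / feats.n_nodes
        tot = total_loss(recon, kl, feats.n_nodes)
        reports.append(LossReport(recon, kl, tot, feats.n_nodes, trace, cfg.key()))
        logger.info("config %s: validation loss %.5f", cfg.key(), tot)
        if tot < best_loss - 1e-12:
            best_loss, best_i, best_model = tot, i, model
    best_cfg = grid[best_i]
    mu, sigma, _ = best_model.forward(feats.X, *_train_view(feats, split))
    selection_embeddings = LatentEmbeddings(
        feats.node_ids, mu, sigma, reparameterize(mu, sigma, best_cfg.seed)
    )
    if refit_full:
        final = DVGAE(best_cfg, feats.X.shape[1], feats.edge_feat.shape[1], feats.n_nodes)
        rng = np.random.default_rng(best_cfg.seed + 1)
        _fit(final, feats, feats.edge_index, None, rng)
        embeddings = final.encode(feats)
    else:
        # reuse the split-trained winner; message passing stays on the
        # training-edge adjacency it was fit with
        final = best_model
        embeddings = selection_embeddings
    return TrainResult(final, best_cfg, feats, embeddings, reports, split, selection_embeddings)


def _train_view(feats: FeaturizedGraph, split: TrainSplit):
    keys = {tuple(e) for e in split.train_edges.T.tolist()}
    mask = np.array([tuple(e) in keys for e in feats.edge_index.T.tolist()])
    return feats.edge_index[:, mask], feats.edge_feat[mask]


def reconstruct_pairs(
    embeddings: LatentEmbeddings,
    threshold: float = 0.5,
    candidates: Iterable[tuple[str, str]] | None = None,
    use_mu: bool = True,
    max_dense_nodes: int = 2000,
) -> set[tuple[str, str]]:
    """Decoded edge set: node-id pairs with probability >= threshold.

    Full enumeration of ordered pairs when the graph is small; otherwise the
    caller must supply a candidate pool (typically original edges plus
    sampled negatives).
    """
    z = embeddings.mu if use_mu else embeddings.z
    ids = embeddings.node_ids
    if candidates is None:
        if len(ids) > max_dense_nodes:
            raise ValueError(
                "graph too large for full pair enumeration; pass `candidates`"
            )
        scores = z @ z.T
        keep = _sigmoid(scores) >= threshold
        np.fill_diagonal(keep, False)
        src, dst = np.nonzero(keep)
        return {(ids[u], ids[v]) for u, v in zip(src.tolist(), dst.tolist())}
    index = {nid: i for i, nid in enumerate(ids)}
    out = set()
    for s, t in candidates:
        if decode_edge_probability(z[index[s]], z[index[t]]) >= threshold:
            out.add((s, t))
    return out


def export_embeddings(result: TrainResult, mode: str = "mu"):
    """Per-node embedding table (node_id index, J columns)."""
    import pandas as pd

    if not result.model.trained:
        raise ValueError("model is untrained; nothing to export")
    emb = result.embeddings
    mat = {"mu": emb.mu, "z": emb.z}[mode]
    return pd.DataFrame(
        mat,
        index=pd.Index(emb.node_ids, name="node_id"),
        columns=[f"dim_{j + 1}" for j in range(mat.shape[1])],
    )
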