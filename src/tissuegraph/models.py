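"""Model families for graph-level tissue phenotype prediction.

Implements the full ablation ladder: pseudobulk MLP / random forest /
logistic regression, permutation-invariant multi-instance networks, graph
convolution with symmetric normalization (GCN) and with sum aggregation
(GCN_SUM), graph isomorphism networks (GIN, concatenated-layer readout),
dot-product graph attention (GAT), an auxiliary self-supervision head that
predicts neighboring-cluster cell-type composition, multi-task heads, and
the loss menu (categorical cross-entropy, MSE, BCE-with-logits for
proportions, right-censored MSE for survival).

Conventions shared by all graph models: binary symmetric adjacency without
self-loops, leaky-ReLU activations with negative slope 0.1, mean pooling
over nodes, and a dense "graph embedding" stack mapping the pooled
representation to the output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import nn
from .nn import Tensor

FAMILIES = ("mlp", "rf", "logreg", "mi", "gcn", "gcn_sum", "gin", "gat",
            "gnn_ss", "gnn_multitask")
GRAPH_FAMILIES = ("gcn", "gcn_sum", "gin", "gat", "gnn_ss", "gnn_multitask")
SHALLOW_FAMILIES = ("rf", "logreg")


@dataclass
class ModelSpec:
    family: str
    n_outputs: int = 2
    depth_feature: int = 0      # per-node dense stack before message passing
    width_feature: int = 16
    depth_node: int = 2         # message-passing / per-node stack depth
    width_node: int = 16
    depth_graph: int = 1        # post-pooling dense stack (plus final linear)
    width_graph: int = 16
    pooling: str = "mean"
    leaky_slope: float = 0.1
    key_dim: int = 4            # GAT query/key embedding dimension
    epsilon: float = 0.0        # GIN self-weight, (1 - eps) convention
    lambda_aux: float = 0.0     # self-supervision loss weight
    task: str = "classification"
    add_self_loops: bool = False
    gat_value_on_raw: bool = True   # attention/value act on raw layer inputs
    base_family: str = "gin"        # message passing used by gnn_ss / multitask
    aux_tasks: tuple = ()           # (name, task_kind, n_outputs, weight) for multitask

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.pooling not in ("mean", "max", "sum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.lambda_aux < 0:
            raise ValueError("aux loss weight must be nonnegative")
        for w in (self.width_feature, self.width_node, self.width_graph):
            if w < 1:
                raise ValueError("widths must be >= 1")


# ---------------------------------------------------------------------------
# layer operations (functional; shared by the batched networks and by tests)


def _check_sym(A: sp.spmatrix):
    if (abs(A - A.T)).nnz != 0:
        raise ValueError("adjacency must be symmetric")


def sym_normalize(A: sp.spmatrix) -> sp.csr_matrix:
    """D^{-1/2} A D^{-1/2}; rows/columns of degree-0 nodes are zero."""
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    D = sp.diags(inv)
    return (D @ A @ D).tocsr()


def mlp_forward(x, layers) -> Tensor:
    """Dense stack; every layer but the last applies leaky-ReLU."""
    h = x if isinstance(x, Tensor) else Tensor(x)
    for layer in layers:
        h = layer(h)
    return h


def gcn_layer(H, A, W, mode="sym", slope=0.1, activate=True) -> Tensor:
    """H' = phi(A* H W) with A* the symmetric normalization (or raw A in sum mode)."""
    _check_sym(A)
    if mode == "sym":
        A = sym_normalize(A)
    elif mode != "sum":
        raise ValueError(f"unknown GCN mode {mode!r}")
    H = H if isinstance(H, Tensor) else Tensor(H)
    W = W if isinstance(W, Tensor) else Tensor(W)
    out = nn.spmm(sp.csr_matrix(A), nn.matmul(H, W))
    return nn.leaky_relu(out, slope) if activate else out


def gin_layer(H, A, mlp, eps=0.0) -> Tensor:
    """h_i' = MLP((1 - eps) h_i + sum_{j in N(i)} h_j)."""
    _check_sym(A)
    H = H if isinstance(H, Tensor) else Tensor(H)
    agg = nn.add(nn.scale(H, 1.0 - eps), nn.spmm(sp.csr_matrix(A), H))
    return mlp(agg)


def gin_readout(per_layer_embeddings) -> Tensor:
    """Concatenate per-layer node embeddings (layer 0..L), mean over nodes."""
    cat = nn.concat_cols(per_layer_embeddings)
    n = cat.value.shape[0]
    pool = sp.csr_matrix(np.full((1, n), 1.0 / n))
    return nn.spmm(pool, cat)


def gat_layer(X, A, W_Q, W_K, W_V, slope=0.1):
    """Dot-product attention message passing.

    alpha_ij = softmax_j(x_i^T W_Q W_K^T x_j) over the neighbors j of i
    (max-subtracted before exponentiation), then
    x_i' = sigma(W_V^T sum_j alpha_ij x_j).

    Returns ``(out, alpha, info)`` where ``alpha`` is the per-edge attention
    Tensor and ``info`` holds the edge index arrays, raw scores, and the
    isolated-node flag (their output row is sigma(0)).
    """
    _check_sym(A)
    X = X if isinstance(X, Tensor) else Tensor(X)
    W_Q = W_Q if isinstance(W_Q, Tensor) else Tensor(W_Q)
    W_K = W_K if isinstance(W_K, Tensor) else Tensor(W_K)
    W_V = W_V if isinstance(W_V, Tensor) else Tensor(W_V)
    n = A.shape[0]
    coo = sp.coo_matrix(A)
    src, dst = coo.row, coo.col  # i attends over its neighbors j
    Q = nn.matmul(X, W_Q)
    K = nn.matmul(X, W_K)
    scores = nn.row_sum(nn.mul(nn.gather(Q, src), nn.gather(K, dst)))
    alpha = nn.segment_softmax(scores, src, n)
    msg = nn.mul(nn.reshape(alpha, (-1, 1)), nn.gather(X, dst))
    agg = nn.segment_sum(msg, src, n)
    out = nn.leaky_relu(nn.matmul(agg, W_V), slope)
    isolated = np.asarray(A.sum(axis=1)).ravel() == 0
    info = {"src": src, "dst": dst, "scores": scores, "isolated": isolated,
            "preact": nn.matmul(agg, W_V)}
    return out, alpha, info


def loss(task: str, preds, targets, events=None) -> Tensor:
    """Loss menu dispatch; returns a scalar Tensor."""
    preds = preds if isinstance(preds, Tensor) else Tensor(preds)
    if task == "classification":
        return nn.softmax_cross_entropy(preds, targets)
    if task == "regression":
        return nn.mse_loss(preds, targets)
    if task == "proportion":
        return nn.bce_with_logits(preds, targets)
    if task == "survival":
        if events is None:
            raise ValueError("survival loss requires event indicators")
        return nn.censored_mse(preds, targets, events)
    raise ValueError(f"unknown task kind {task!r}")


# ---------------------------------------------------------------------------
# batched graph container


class GraphBatch:
    """A block-diagonal stack of graphs for one forward/backward pass."""

    def __init__(self, views, add_self_loops=False):
        mats, feats, sizes, self.sample_ids = [], [], [], []
        for v in views:
            g = v.payload if hasattr(v, "payload") else v
            if hasattr(g, "adjacency"):
                A, X = g.adjacency, g.node_features
            else:  # a bare feature matrix: a bag with no edges
                X = np.asarray(g, dtype=float)
                A = sp.csr_matrix((len(X), len(X)))
            if add_self_loops:
                A = (A + sp.identity(A.shape[0], format="csr")).tocsr()
                A.data[:] = 1.0
            mats.append(sp.csr_matrix(A))
            feats.append(np.asarray(X, dtype=float))
            sizes.append(X.shape[0])
            self.sample_ids.append(getattr(v, "sample_id", None))
        self.sizes = np.array(sizes)
        self.n_graphs = len(sizes)
        self.X = np.concatenate(feats) if feats else np.empty((0, 0))
        self.A = sp.block_diag(mats, format="csr") if mats else sp.csr_matrix((0, 0))
        self.graph_ids = np.repeat(np.arange(self.n_graphs), self.sizes)
        n = self.X.shape[0]
        w = np.concatenate([np.full(s, 1.0 / max(s, 1)) for s in sizes]) if n else np.array([])
        self.pool_mean = sp.csr_matrix((w, (self.graph_ids, np.arange(n))),
                                       shape=(self.n_graphs, n))
        self.pool_sum = sp.csr_matrix((np.ones(n), (self.graph_ids, np.arange(n))),
                                      shape=(self.n_graphs, n))
        self._norm = None

    @property
    def A_norm(self) -> sp.csr_matrix:
        if self._norm is None:
            self._norm = sym_normalize(self.A)
        return self._norm


# ---------------------------------------------------------------------------
# the neural network over a spec


class NeuralNet:
    """Architecture instance: parameter container plus batched forward pass."""

    def __init__(self, spec: ModelSpec, in_dim: int, seed: int = 0):
        self.spec = spec
        self.in_dim = in_dim
        rng = np.random.default_rng(seed)
        s = spec
        fam = spec.base_family if spec.family in ("gnn_ss", "gnn_multitask") else spec.family
        self.mp_family = fam
        d = in_dim
        self.feature_layers = []
        use_fe = s.depth_feature > 0 and not (fam == "gat" and s.gat_value_on_raw)
        if use_fe:
            for _ in range(s.depth_feature):
                self.feature_layers.append(nn.Dense(rng, d, s.width_feature,
                                                    slope=s.leaky_slope))
                d = s.width_feature
        self.node_layers = []
        gin_dims = [d]
        if fam in ("mi", "mlp"):
            node_depth = s.depth_node if fam == "mi" else 0
            for _ in range(node_depth):
                self.node_layers.append(nn.Dense(rng, d, s.width_node, slope=s.leaky_slope))
                d = s.width_node
        elif fam in ("gcn", "gcn_sum"):
            for _ in range(s.depth_node):
                self.node_layers.append(
                    nn.Dense(rng, d, s.width_node, bias=False, activation=False))
                d = s.width_node
        elif fam == "gin":
            for _ in range(s.depth_node):
                m1 = nn.Dense(rng, d, s.width_node, slope=s.leaky_slope)
                m2 = nn.Dense(rng, s.width_node, s.width_node, slope=s.leaky_slope)
                self.node_layers.append((m1, m2))
                d = s.width_node
                gin_dims.append(d)
        elif fam == "gat":
            for _ in range(s.depth_node):
                layer = {
                    "W_Q": Tensor(nn.uniform_init(rng, (d, s.key_dim), d), requires_grad=True),
                    "W_K": Tensor(nn.uniform_init(rng, (d, s.key_dim), d), requires_grad=True),
                    "W_V": Tensor(nn.uniform_init(rng, (d, s.width_node), d), requires_grad=True),
                }
                self.node_layers.append(layer)
                d = s.width_node
        self.gin_readout_dim = sum(gin_dims)
        pooled_dim = self.gin_readout_dim if fam == "gin" else d
        self.pooled_dim = pooled_dim
        self.node_out_dim = d
        self.graph_layers = []
        g = pooled_dim
        for _ in range(s.depth_graph):
            self.graph_layers.append(nn.Dense(rng, g, s.width_graph, slope=s.leaky_slope))
            g = s.width_graph
        self.out_layer = nn.Dense(rng, g, s.n_outputs, activation=False)
        self.aux_heads = {}
        for name, kind, n_out, _w in s.aux_tasks:
            self.aux_heads[name] = nn.Dense(rng, g, n_out, activation=False)
        self.ss_head = None  # created on demand by attach_ss_head

    def attach_ss_head(self, n_types: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.ss_head = nn.Dense(rng, self.node_out_dim, n_types, activation=False)

    @property
    def params(self):
        ps = []
        for layer in self.feature_layers + self.graph_layers + [self.out_layer]:
            ps += layer.params
        for layer in self.node_layers:
            if isinstance(layer, nn.Dense):
                ps += layer.params
            elif isinstance(layer, tuple):
                for sub in layer:
                    ps += sub.params
            else:
                ps += [layer["W_Q"], layer["W_K"], layer["W_V"]]
        for head in self.aux_heads.values():
            ps += head.params
        if self.ss_head is not None:
            ps += self.ss_head.params
        return ps

    def get_state(self):
        return [p.value.copy() for p in self.params]

    def set_state(self, state):
        for p, v in zip(self.params, state):
            p.value = v.copy()

    def forward(self, batch: GraphBatch, X: Tensor | None = None) -> dict:
        """Full forward pass; returns logits and all interpretation hooks."""
        s = self.spec
        if X is None:
            X = Tensor(batch.X)
        H = X
        for layer in self.feature_layers:
            H = layer(H)
        fam = self.mp_family
        hooks: dict = {"X": X, "alpha": [], "attention_info": [],
                       "layer_preacts": [], "layer_outputs": []}
        if fam in ("mi", "mlp"):
            for layer in self.node_layers:
                H = layer(H)
                hooks["layer_outputs"].append(H)
        elif fam in ("gcn", "gcn_sum"):
            A = batch.A_norm if fam == "gcn" else batch.A
            for layer in self.node_layers:
                pre = nn.spmm(A, nn.matmul(H, layer.W))
                hooks["layer_preacts"].append(pre)
                H = nn.leaky_relu(pre, s.leaky_slope)
                hooks["layer_outputs"].append(H)
        elif fam == "gin":
            layers_out = [H]
            for m1, m2 in self.node_layers:
                agg = nn.add(nn.scale(H, 1.0 - s.epsilon), nn.spmm(batch.A, H))
                hooks["layer_preacts"].append(agg)
                H = m2(m1(agg))
                layers_out.append(H)
                hooks["layer_outputs"].append(H)
            hooks["gin_layers"] = layers_out
        elif fam == "gat":
            for layer in self.node_layers:
                H, alpha, info = gat_layer(H, batch.A, layer["W_Q"], layer["W_K"],
                                           layer["W_V"], s.leaky_slope)
                hooks["alpha"].append(alpha)
                hooks["attention_info"].append(info)
                hooks["layer_preacts"].append(info["preact"])
                hooks["layer_outputs"].append(H)
        hooks["node_embeddings"] = H
        if fam == "gin":
            # mean pooling commutes with the per-layer concatenation
            pooled = nn.concat_cols([nn.spmm(batch.pool_mean, Hl)
                                     for Hl in hooks["gin_layers"]])
        elif fam == "mlp":
            pooled = H  # vector input: one row per graph already
        else:
            if s.pooling == "mean":
                pooled = nn.spmm(batch.pool_mean, H)
            elif s.pooling == "sum":
                pooled = nn.spmm(batch.pool_sum, H)
            else:
                pooled = nn.segment_max(H, batch.graph_ids, batch.n_graphs)
        hooks["graph_embedding"] = pooled
        G = pooled
        for layer in self.graph_layers:
            G = layer(G)
        hooks["graph_hidden"] = G
        hooks["logits"] = self.out_layer(G)
        for name, head in self.aux_heads.items():
            hooks[f"logits_{name}"] = head(G)
        return hooks

    def ss_loss(self, hooks, ss_batch) -> Tensor:
        """Auxiliary self-supervision loss for one batch.

        ``ss_batch`` is ``(pool_matrix, targets)``: a sparse mean-pooling
        matrix from nodes to valid clusters and the stacked composition
        targets. Returns MSE between the one-layer head predictions and the
        targets (0 when there are no valid clusters).
        """
        pool, targets = ss_batch
        if pool is None or pool.shape[0] == 0:
            import warnings
            warnings.warn("no valid clusters for self-supervision; aux loss is 0")
            return Tensor(0.0)
        cluster_emb = nn.spmm(pool, hooks["node_embeddings"])
        pred = self.ss_head(cluster_emb)
        return nn.mse_loss(pred, targets)


def ss_head(node_embeddings, cluster_labels, targets, head: nn.Dense,
            lambda_aux: float = 1.0, task_loss: Tensor | None = None):
    """Self-supervision loss for a single graph.

    Node embeddings are mean-pooled per cluster, passed through the
    one-layer head, and compared to the valid composition targets by MSE;
    the result is ``task_loss + lambda * aux`` when a task loss is given.
    """
    H = node_embeddings if isinstance(node_embeddings, Tensor) else Tensor(node_embeddings)
    labels = np.asarray(cluster_labels)
    valid = [t for t in targets if t.valid]
    if not valid:
        import warnings
        warnings.warn("no valid clusters for self-supervision; aux loss is 0")
        aux = Tensor(0.0)
    else:
        n = len(labels)
        rows, cols, w = [], [], []
        for r, t in enumerate(valid):
            members = np.flatnonzero(labels == t.cluster_id)
            rows += [r] * len(members)
            cols += list(members)
            w += [1.0 / len(members)] * len(members)
        pool = sp.csr_matrix((w, (rows, cols)), shape=(len(valid), n))
        pred = head(nn.spmm(pool, H))
        aux = nn.mse_loss(pred, np.stack([t.vector for t in valid]))
    if task_loss is None:
        return aux
    return nn.add(task_loss, nn.scale(aux, lambda_aux))


def mi_forward(node_features, net: NeuralNet) -> Tensor:
    """Multi-instance forward for a single bag of cells.

    The bag is an unordered (n, d) matrix; the per-node dense stack, pooling
    and graph stack come from ``net`` (family ``mi``).
    """
    X = np.asarray(node_features, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("multi-instance forward needs at least one node")
    batch = GraphBatch([X])
    return net.forward(batch)["logits"]


# ---------------------------------------------------------------------------
# shallow baselines


class ShallowModel:
    """Random forest / logistic regression over vector views."""

    def __init__(self, family: str, estimator, classes):
        self.family = family
        self.estimator = estimator
        self.classes_ = classes

    def predict_proba(self, X):
        return self.estimator.predict_proba(np.asarray(X))


def fit_shallow(X, y, family: str, seed: int = 0) -> ShallowModel:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if family == "rf":
        est = RandomForestClassifier(n_estimators=200, random_state=int(seed) % (2 ** 31))
    elif family == "logreg":
        est = LogisticRegression(max_iter=2000, random_state=int(seed) % (2 ** 31))
    else:
        raise ValueError(f"unknown shallow family {family!r}")
    est.fit(X, y)
    return ShallowModel(family, est, est.classes_)


# ---------------------------------------------------------------------------
# trained model wrapper


@dataclass
class TrainedModel:
    """A fitted neural model plus its history and interpretation hooks."""

    spec: ModelSpec
    net: NeuralNet
    history: dict = field(default_factory=dict)
    class_names: tuple | None = None
    seed: int | None = None

    def _batch(self, views):
        if self.spec.family == "mlp":
            X = np.stack([np.asarray(v.payload if hasattr(v, "payload") else v)
                          for v in views])
            return GraphBatch([X])
        return GraphBatch(views, add_self_loops=self.spec.add_self_loops)

    def forward(self, views) -> dict:
        return self.net.forward(self._batch(views))

    def predict_logits(self, views) -> np.ndarray:
        return self.forward(views)["logits"].value

    def predict_proba(self, views) -> np.ndarray:
        z = self.predict_logits(views)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def graph_embeddings(self, views) -> np.ndarray:
        """Activations after the global node pooling step, one row per graph."""
        return self.forward(views)["graph_embedding"].value

    def save(self, path):
        import json
        from dataclasses import asdict
        from pathlib import Path
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", *[p.value for p in self.net.params])
        meta = {"spec": asdict(self.spec), "in_dim": self.net.in_dim,
                "seed": self.seed,
                "class_names": list(self.class_names) if self.class_names else None}
        (path / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path):
        import json
        from pathlib import Path
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        spec_d = meta["spec"]
        spec_d["aux_tasks"] = tuple(tuple(t) for t in spec_d["aux_tasks"])
        spec = ModelSpec(**spec_d)
        net = NeuralNet(spec, meta["in_dim"], seed=0)
        data = np.load(path / "params.npz")
        net.set_state([data[k] for k in data.files])
        return cls(spec, net, class_names=(tuple(meta["class_names"])
                                           if meta["class_names"] else None),
                   seed=meta["seed"])
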