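"""Input representations for the ablation ladder.

Each arm of the ablation consumes a different deterministic reduction of a
tissue sample: pseudobulk vectors (mean markers or type fractions), the
dissociated cell bag, the degree histogram, or a node-featured spatial
graph (molecular, one-hot cell type, binary immune, permuted, skeleton, or
expression-correlation variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import graphs as _graphs
from .graphs import SpatialGraph
from .simulate import TissueSample

VIEW_KINDS = (
    "bulk_molecular", "bulk_fractions", "cell_bag", "degree_hist",
    "graph_molecular", "graph_celltype_onehot", "graph_immune_binary",
    "graph_permuted", "graph_skeleton", "correlation_graph",
)


@dataclass
class FeatureView:
    kind: str
    payload: object                # vector | matrix | SpatialGraph
    sample_id: str
    params: dict

    @property
    def is_graph(self) -> bool:
        return isinstance(self.payload, SpatialGraph)


def pseudobulk(sample: TissueSample, space: str = "molecular",
               type_order=None) -> np.ndarray:
    """Mean marker vector or normalized cell-type frequency vector."""
    if sample.n_cells == 0:
        raise ValueError("pseudobulk of an empty sample is undefined")
    if space == "molecular":
        return sample.markers.mean(axis=0)
    if space == "fractions":
        if type_order is None:
            type_order = sorted(set(sample.cell_type), key=str)
        counts = np.array([(sample.cell_type == t).sum() for t in type_order], float)
        return counts / counts.sum()
    raise ValueError(f"unknown pseudobulk space {space!r}")


def encode_nodes(sample: TissueSample, space: str = "molecular",
                 type_order=None) -> np.ndarray:
    """Node feature matrix: raw markers, one-hot cell types, or binary immune.

    ``immune_binary`` encodes each cell as a 2-column one-hot
    (immune, non-immune).
    """
    if space == "molecular":
        return sample.markers.astype(float)
    if space == "celltype_onehot":
        if type_order is None:
            type_order = sorted(set(sample.cell_type), key=str)
        idx = {t: i for i, t in enumerate(type_order)}
        unmapped = set(sample.cell_type) - set(idx)
        if unmapped:
            raise ValueError(f"unmapped cell types: {sorted(map(str, unmapped))}")
        X = np.zeros((sample.n_cells, len(type_order)))
        X[np.arange(sample.n_cells), [idx[t] for t in sample.cell_type]] = 1.0
        return X
    if space == "immune_binary":
        X = np.zeros((sample.n_cells, 2))
        imm = sample.immune_flag.astype(bool)
        X[imm, 0] = 1.0
        X[~imm, 1] = 1.0
        return X
    raise ValueError(f"unknown node feature space {space!r}")


def make_view(sample: TissueSample, kind: str, params=None) -> FeatureView:
    """Build one named representation of a sample.

    ``params`` may carry ``r`` (radius graph), ``k`` (correlation graph),
    ``type_order``, ``seed`` (permutation / bag shuffling), and
    ``immune_fraction_space`` details depending on the kind.
    """
    params = dict(params or {})
    if kind not in VIEW_KINDS:
        raise ValueError(f"unknown view kind {kind!r}")

    def _need(key):
        if key not in params:
            raise ValueError(f"view kind {kind!r} requires parameter {key!r}")
        return params[key]

    type_order = params.get("type_order")
    if kind == "bulk_molecular":
        payload = pseudobulk(sample, "molecular")
    elif kind == "bulk_fractions":
        space = params.get("space", "types")
        if space == "immune_binary":
            f = float(sample.immune_flag.mean())
            payload = np.array([f, 1.0 - f])
        else:
            payload = pseudobulk(sample, "fractions", type_order=type_order)
    elif kind == "cell_bag":
        X = encode_nodes(sample, params.get("space", "molecular"), type_order)
        seed = params.get("seed")
        if seed is not None:  # in-silico dissociation: randomize row order
            X = X[np.random.default_rng(seed).permutation(len(X))]
        payload = X
    elif kind == "degree_hist":
        A = _graphs.build_radius_graph(sample.coords, _need("r"))
        payload = _graphs.degree_histogram(A)
    elif kind in ("graph_molecular", "graph_celltype_onehot", "graph_immune_binary",
                  "graph_permuted", "graph_skeleton"):
        r = _need("r")
        A = _graphs.build_radius_graph(sample.coords, r)
        if kind == "graph_skeleton":
            # constant scalar feature: structure-only arm runnable by any GNN
            X = np.ones((sample.n_cells, 1))
        else:
            space = {"graph_molecular": "molecular",
                     "graph_celltype_onehot": "celltype_onehot",
                     "graph_immune_binary": "immune_binary",
                     "graph_permuted": params.get("space", "celltype_onehot")}[kind]
            X = encode_nodes(sample, space, type_order)
        g = SpatialGraph(A, X, cell_type=sample.cell_type,
                         immune_flag=sample.immune_flag, radius=r,
                         sample_id=sample.image_id)
        if kind == "graph_permuted":
            g = _graphs.permute_node_labels(g, seed=params.get("seed", 0))
        payload = g
    elif kind == "correlation_graph":
        k = _need("k")
        A = _graphs.build_correlation_graph(sample.markers, k)
        X = encode_nodes(sample, params.get("space", "molecular"), type_order)
        payload = SpatialGraph(A, X, cell_type=sample.cell_type,
                               immune_flag=sample.immune_flag,
                               sample_id=sample.image_id)
    return FeatureView(kind, payload, sample.image_id, params)


def make_views(cohort, kind: str, params=None) -> list:
    """Views for every sample of a cohort, with a shared cell-type order."""
    params = dict(params or {})
    if "type_order" not in params:
        params["type_order"] = sorted(cohort.type_immune_map)
    out = []
    for i, s in enumerate(cohort.samples):
        p = dict(params)
        if kind in ("graph_permuted", "cell_bag"):
            p["seed"] = int(params.get("seed", 0)) * 100003 + i
        out.append(make_view(s, kind, p))
    return out


class NodeScaler:
    """Per-marker z-scoring fitted on training samples only.

    Leakage-safe normalization for molecular node features; a no-op for
    one-hot/binary spaces.
    """

    def __init__(self):
        self.mean = None
        self.sd = None

    def fit(self, views):
        X = np.concatenate([
            v.payload.node_features if v.is_graph else np.atleast_2d(v.payload)
            for v in views
        ])
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, views):
        out = []
        for v in views:
            if v.is_graph:
                g = v.payload
                g2 = SpatialGraph((g.adjacency), (g.node_features - self.mean) / self.sd,
                                  g.cell_type, g.immune_flag, g.radius, g.sample_id)
                out.append(FeatureView(v.kind, g2, v.sample_id, v.params))
            else:
                out.append(FeatureView(v.kind, (np.asarray(v.payload) - self.mean) / self.sd,
                                       v.sample_id, v.params))
        return out
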