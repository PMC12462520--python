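"""Post-hoc analyses of trained graph models.

Covers the interpretation toolkit: graph-embedding manifolds (quantile
normalization + PCA), survival concordance of embedding coordinates,
attention-derived cell-type interaction matrices and filter-gradient
context for dot-product GATs, input-gradient cell saliency with
degree/immune-fraction stratification, and neighborhood composition
contrasts between classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.spatial.distance import cdist

from . import nn
from .nn import Tensor
from .models import GRAPH_FAMILIES, TrainedModel

# ---------------------------------------------------------------------------
# embeddings


def extract_embeddings(model: TrainedModel, views, samples=None) -> pd.DataFrame:
    """Post-pooling graph embeddings for a whole cohort (train+val+test).

    One row per sample; survival columns are attached when the samples
    carry them.
    """
    if model.spec.family not in GRAPH_FAMILIES and model.spec.family != "mi":
        raise ValueError("graph embeddings require a pooled (graph or bag) model")
    Z = model.graph_embeddings(views)
    df = pd.DataFrame(Z, columns=[f"emb_{j}" for j in range(Z.shape[1])])
    df.insert(0, "sample_id", [v.sample_id for v in views])
    if samples is not None:
        df["label"] = [s.label for s in samples]
        df["severity"] = [s.severity for s in samples]
        df["survival_time"] = [s.survival_time for s in samples]
        df["event"] = [s.event for s in samples]
    return df


def quantile_transform(X: np.ndarray) -> np.ndarray:
    """Rank-based per-feature transform to uniform values in (0, 1]."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        out[:, j] = _stats.rankdata(X[:, j], method="average") / n
    return out


def manifold(embeddings, n_components=None) -> dict:
    """Quantile-normalize embeddings feature-wise, then centered PCA.

    Principal-component signs are fixed by convention: the loading of
    largest magnitude is made positive. Constant features are excluded
    with a warning. Returns scores, loadings, explained variance and the
    kept feature indices.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("manifold needs at least two samples")
    keep = np.flatnonzero(X.std(axis=0) > 0)
    if len(keep) < X.shape[1]:
        warnings.warn(f"excluding {X.shape[1] - len(keep)} constant features from PCA")
    if len(keep) == 0:
        raise ValueError("all features constant; PCA undefined")
    U = quantile_transform(X[:, keep])
    k = min(n_components or len(keep), len(keep), X.shape[0] - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(U)
    loadings = pca.components_
    for c in range(k):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] = -loadings[c]
            scores[:, c] = -scores[:, c]
    return {"scores": scores, "loadings": loadings,
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "kept_features": keep}


def class_distance(embeddings, labels, class_a, class_b) -> float:
    """Mean Euclidean distance over all cross-class embedding pairs."""
    X = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    A = X[labels == class_a]
    B = X[labels == class_b]
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both classes must be populated")
    return float(cdist(A, B).mean())


# ---------------------------------------------------------------------------
# survival


def concordance(values, times, events) -> float:
    """Right-censored concordance index of a risk score.

    Comparable pairs are those whose earlier time is an event; a pair is
    concordant when the subject with the earlier time has the larger
    predictor value (risk convention). Predictor ties credit 0.5. Raises
    when no pair is comparable.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (len(v) == len(t) == len(e)):
        raise ValueError("values, times and events must have equal length")
    earlier = (t[:, None] < t[None, :]) & e[:, None]   # (i earlier event, j later)
    n_comp = int(earlier.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs; concordance undefined")
    conc = (v[:, None] > v[None, :]) & earlier
    ties = (v[:, None] == v[None, :]) & earlier
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


# ---------------------------------------------------------------------------
# attention interpretation


def _check_gat_onehot(model: TrainedModel, type_order):
    if model.net.mp_family != "gat":
        raise ValueError("attention interpretation requires a GAT model")
    if model.net.feature_layers:
        raise ValueError("attention-type analysis requires raw one-hot inputs "
                         "(no feature-embedding stack)")
    if model.net.in_dim != len(type_order):
        raise ValueError("model input dimension does not match the cell-type "
                         "one-hot encoding")


def attention_type_matrix(model: TrainedModel, type_order) -> pd.DataFrame:
    """Transformed attention scores for every (query, key) cell-type pair.

    With one-hot type inputs the pre-softmax score of query type q against
    key type k is (W_Q W_K^T)[q, k]. Scores are max-subtracted per key and
    exponentiated (softmax-like); each key column then has maximum 1.
    Rows are query types, columns are key types.
    """
    _check_gat_onehot(model, type_order)
    layer = model.net.node_layers[0]
    S = layer["W_Q"].value @ layer["W_K"].value.T
    E = np.exp(S - S.max(axis=0, keepdims=True))
    E = E / E.max(axis=0, keepdims=True)
    return pd.DataFrame(E, index=list(type_order), columns=list(type_order))


def filter_gradients(model: TrainedModel, views) -> np.ndarray:
    """Average gradient of each class output w.r.t. first-layer filter activations.

    Returns an (n_classes, n_filters) array averaged over all nodes of the
    given views.
    """
    batch = model._batch(views)
    out = np.zeros((model.spec.n_outputs, model.net.spec.width_node))
    for c in range(model.spec.n_outputs):
        hooks = model.net.forward(batch)
        H1 = hooks["layer_outputs"][0]
        sel = np.zeros((model.spec.n_outputs, 1))
        sel[c] = 1.0
        scalar = nn.mean_all(nn.matmul(hooks["logits"], Tensor(sel)))
        scalar.backward()
        out[c] = H1.grad.mean(axis=0)
    return out


def filter_context(model: TrainedModel, views, cell_type, type_order):
    """First-layer value filters in the attention context of one cell type.

    The value matrix W_V (rows indexed by the neighbor/key type for one-hot
    inputs) is scaled by the transformed attention row of ``cell_type``
    attending each key type; the per-class averaged filter gradients set
    the filters into global context. Returns ``(heatmap, gradients)``.
    """
    _check_gat_onehot(model, type_order)
    att = attention_type_matrix(model, type_order)
    w = att.loc[cell_type].to_numpy()          # attention of cell_type over keys
    W_V = model.net.node_layers[0]["W_V"].value
    heatmap = pd.DataFrame(W_V * w[:, None], index=list(type_order))
    grads = filter_gradients(model, views)
    return heatmap, grads


def interaction_relevance(model: TrainedModel, views, type_order,
                          class_pos=1, class_neg=0) -> pd.DataFrame:
    """Rank (query, key) type pairs by attention-weighted filter relevance.

    For each pair, the transformed attention score is weighted by how much
    the key type feeds class-discriminative filters:
    rel(q, k) = att(q, k) * sum_f |W_V[k, f]| * |g+_f - g-_f| with g the
    per-class averaged filter gradients.
    """
    att = attention_type_matrix(model, type_order)
    W_V = model.net.node_layers[0]["W_V"].value
    grads = filter_gradients(model, views)
    g = np.abs(grads[class_pos] - grads[class_neg])
    key_weight = (np.abs(W_V) * g[None, :]).sum(axis=1)
    rel = att.to_numpy() * key_weight[None, :]
    return pd.DataFrame(rel, index=list(type_order), columns=list(type_order))


# ---------------------------------------------------------------------------
# saliency


def saliency(model: TrainedModel, view) -> pd.DataFrame:
    """Per-cell input-gradient saliency for one graph of a binary task.

    The gradient of (logit_class1 - logit_class0) with respect to each
    node's input row is reduced to a scalar: the gradient on the cell's
    active indicator for one-hot/binary feature spaces, or the L2 norm
    signed by the row-gradient sum for molecular features. Positive values
    point toward class 1.
    """
    if model.spec.n_outputs != 2 or model.spec.task != "classification":
        raise ValueError("saliency is defined for binary classification models")
    batch = model._batch([view])
    X = Tensor(batch.X, requires_grad=True)
    hooks = model.net.forward(batch, X=X)
    sel = np.array([[-1.0], [1.0]])
    scalar = nn.mean_all(nn.matmul(hooks["logits"], Tensor(sel)))
    scalar.backward()
    G = X.grad
    Xv = batch.X
    onehot = np.isin(Xv, (0.0, 1.0)).all() and np.allclose(Xv.sum(axis=1), 1.0)
    if onehot:
        vals = G[np.arange(len(G)), Xv.argmax(axis=1)]
    else:
        vals = np.sign(G.sum(axis=1)) * np.linalg.norm(G, axis=1)
    g = view.payload
    deg = g.degrees().astype(float)
    if g.immune_flag is not None:
        imm = g.immune_flag.astype(float)
        neigh_imm = np.asarray(g.adjacency @ imm).ravel()
        frac = np.divide(neigh_imm, deg, out=np.zeros_like(deg), where=deg > 0)
    else:
        frac = np.full(len(deg), np.nan)
    return pd.DataFrame({
        "sample_id": view.sample_id,
        "saliency": vals,
        "degree": deg.astype(int),
        "neighbor_immune_fraction": frac,
    })


def saliency_table(model: TrainedModel, views, samples) -> pd.DataFrame:
    """Cohort-wide saliency table with labels and generator annotations."""
    frames = []
    for v, s in zip(views, samples):
        df = saliency(model, v)
        df["label"] = s.label
        if s.in_aggregate is not None:
            df["in_aggregate"] = s.in_aggregate
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def stratify(table: pd.DataFrame, degree_bins=None, fraction_bins=None,
             group="label") -> pd.DataFrame:
    """Mean saliency per (degree bin x immune-fraction bin x group) stratum.

    Default bins: degree in steps of 5 from 0 to 30 plus overflow; immune
    fraction in steps of 0.2. Empty strata are absent (marked NaN after
    pivoting). Overlapping or unordered bin edges raise.
    """
    degree_bins = degree_bins if degree_bins is not None \
        else [0, 5, 10, 15, 20, 25, 30, np.inf]
    fraction_bins = fraction_bins if fraction_bins is not None \
        else [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    for edges in (degree_bins, fraction_bins):
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing "
                             "(overlapping bins are invalid)")
    t = table.copy()
    t["degree_bin"] = pd.cut(t["degree"], degree_bins, right=False,
                             include_lowest=True)
    t["fraction_bin"] = pd.cut(t["neighbor_immune_fraction"], fraction_bins,
                               right=True, include_lowest=True)
    grid = (t.groupby(["degree_bin", "fraction_bin", group], observed=False)
            ["saliency"].mean().reset_index())
    return grid


# ---------------------------------------------------------------------------
# neighborhood composition


def neighbor_frequency_diff(samples, graphs, query_type, class_a, class_b,
                            type_order=None) -> pd.Series:
    """Per-type difference of mean neighbor frequencies around a query type.

    For every image, the cell-type frequencies among the radius-graph
    neighbors of query-type cells are normalized to sum 1; image values are
    averaged per class and reported as class_a minus class_b. Images
    lacking the query type (or any neighbor of it) are excluded with a
    warning.
    """
    if type_order is None:
        type_order = sorted({t for s in samples for t in set(s.cell_type)}, key=str)
    per_class: dict = {class_a: [], class_b: []}
    skipped = 0
    for s, g in zip(samples, graphs):
        if s.label not in per_class:
            continue
        A = g.adjacency if hasattr(g, "adjacency") else g
        qmask = s.cell_type == query_type
        if not qmask.any():
            skipped += 1
            continue
        counts = np.zeros(len(type_order))
        sub = A[qmask]
        rows, cols = sub.nonzero()
        if len(cols) == 0:
            skipped += 1
            continue
        for j, t in enumerate(type_order):
            counts[j] = np.sum(s.cell_type[cols] == t)
        per_class[s.label].append(counts / counts.sum())
    if skipped:
        warnings.warn(f"{skipped} images lacked {query_type!r} cells or neighbors; excluded")
    if not per_class[class_a] or not per_class[class_b]:
        raise ValueError("one of the contrasted classes has no usable images")
    mean_a = np.mean(per_class[class_a], axis=0)
    mean_b = np.mean(per_class[class_b], axis=0)
    return pd.Series(mean_a - mean_b, index=list(type_order))
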