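"""Patient-grouped nested cross-validation and the ablation driver.

Cohorts are split on the patient domain (all images of a patient land in
the same partition) into training / validation / test sets, with 3 random
test splits crossed with 3 validation splits (9 evaluation cells). Models
are trained with Adam plus reduce-on-plateau learning-rate scheduling,
selected per outer split by the lowest validation loss (or training loss in
the train/test-only mode), and scored by the step-wise area under the
precision-recall curve (macro-averaged for multi-class tasks). Arms of the
ablation ladder are compared by an unpaired two-sided t-test on their 9
selected AUPR values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from . import nn
from .models import (
    FAMILIES, GRAPH_FAMILIES, SHALLOW_FAMILIES, GraphBatch, ModelSpec,
    NeuralNet, TrainedModel, fit_shallow, loss as model_loss,
)

# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitPlan:
    """Patient-grouped nested split assignments."""

    mode: str
    seed: int
    outer: list          # [{"test": [...], "inner": [{"train": [...], "val": [...]}]}]
    patients: np.ndarray

    @property
    def n_cells(self) -> int:
        return sum(len(o["inner"]) for o in self.outer)


def _classes_present(patients, patient_class, classes):
    present = {patient_class[p] for p in patients}
    return present == set(classes)


def make_splits(cohort=None, mode="train_val_test", seed=0, *, labels=None,
                patients=None, n_outer=3, n_inner=3,
                fractions=(0.8, 0.1, 0.1), max_retries=100) -> SplitPlan:
    """Draw the nested split plan used by every model family.

    ``mode="train_val_test"`` uses the stated fractions; ``"train_test"``
    (for small cohorts) holds out the validation fraction as extra training
    data and realizes the inner axis as training replicates, with model
    selection on the training loss.
    """
    if cohort is not None:
        labels = cohort.labels()
        patients = cohort.patients()
    labels = np.asarray(labels)
    patients = np.asarray(patients)
    if mode not in ("train_val_test", "train_test"):
        raise ValueError(f"unknown split mode {mode!r}")
    uniq = np.unique(patients)
    patient_class = {}
    for p in uniq:
        patient_class[p] = labels[patients == p][0]
    classes = sorted(set(labels))
    rng = np.random.default_rng(seed)
    test_frac = fractions[2] if mode == "train_val_test" else 0.2
    # folds must be able to contain every class
    n_test = max(len(classes), int(round(test_frac * len(uniq))))
    outer = []
    for _o in range(n_outer):
        for attempt in range(max_retries):
            test = rng.choice(uniq, size=n_test, replace=False)
            rest = np.setdiff1d(uniq, test)
            if _classes_present(test, patient_class, classes) and \
               _classes_present(rest, patient_class, classes):
                break
        else:
            raise RuntimeError("could not draw a test split with every class present")
        inner = []
        if mode == "train_test":
            for i in range(n_inner):
                inner.append({"train": rest.tolist(), "val": None, "replicate": i})
        else:
            val_frac = fractions[1] / (fractions[0] + fractions[1])
            n_val = max(len(classes), int(round(val_frac * len(rest))))
            for _i in range(n_inner):
                for attempt in range(max_retries):
                    val = rng.choice(rest, size=n_val, replace=False)
                    tr = np.setdiff1d(rest, val)
                    if _classes_present(val, patient_class, classes) and \
                       _classes_present(tr, patient_class, classes):
                        break
                else:
                    raise RuntimeError("could not draw a validation split with "
                                       "every class present")
                inner.append({"train": tr.tolist(), "val": val.tolist()})
        outer.append({"test": test.tolist(), "inner": inner})
    return SplitPlan(mode, seed, outer, uniq)


def _sample_indices(patients, patient_subset):
    mask = np.isin(patients, list(patient_subset))
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# metrics


def _binary_aupr(scores, y) -> float:
    y = np.asarray(y).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined without positive examples")
    if n_pos == len(y):
        return 1.0  # precision is identically 1
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    ends = np.append(np.flatnonzero(np.diff(ss) != 0), len(ss) - 1)
    tp = np.cumsum(ys)[ends]
    predicted = ends + 1
    recall = tp / n_pos
    precision = tp / predicted
    r_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - r_prev) * precision))


def aupr(scores, labels) -> float:
    """Step-wise area under the precision-recall curve.

    Thresholds are the distinct score values in descending order, with
    AUPR = sum_i (R_i - R_{i-1}) P_i and R_0 = 0. A 1-D score vector is
    scored against binary labels (positive class); a 2-D (n, k) score
    matrix is macro-averaged over one-vs-rest classes 0..k-1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2 and scores.ndim > 1:
        raise ValueError("AUPR needs at least two observed classes")
    if scores.ndim == 1:
        return _binary_aupr(scores, labels)
    vals = []
    for c in range(scores.shape[1]):
        vals.append(_binary_aupr(scores[:, c], labels == c))
    return float(np.mean(vals))


def random_baseline(labels) -> np.ndarray:
    """Expected AUPR of a random predictor: positive-class prevalence.

    ``labels`` is either one label array or a list of label arrays (one per
    cross-validation cell, averaged). Returns per-class prevalences in
    sorted class order.
    """
    if isinstance(labels, (list, tuple)):
        classes = sorted(set(np.concatenate([np.asarray(l) for l in labels])))
        per_cell = [[np.mean(np.asarray(l) == c) for c in classes] for l in labels]
        return np.asarray(per_cell).mean(axis=0)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    classes = sorted(set(labels))
    return np.array([np.mean(labels == c) for c in classes])


def compare(records_a, records_b):
    """Unpaired two-sided t-test between two arms' selected AUPR values.

    Returns ``(delta_aupr, p)``; identical degenerate samples give p = 1 by
    convention.
    """
    a = np.asarray(records_a, dtype=float)
    b = np.asarray(records_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two AUPR values per side")
    delta = float(a.mean() - b.mean())
    if a.var() == 0 and b.var() == 0:
        return delta, 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    t, p = stats.ttest_ind(a, b)
    if np.isnan(p):
        p = 1.0
    return delta, float(p)


# ---------------------------------------------------------------------------
# training loop


def _is_finite(x) -> bool:
    return np.isfinite(np.asarray(x)).all()


def _build_ss_batch(ss_items, sizes):
    """Stack per-graph self-supervision data into one pooled batch.

    ``ss_items``: per graph ``(cluster_labels, [CompositionTarget...])``.
    Returns ``(pool_matrix, targets)`` over all valid clusters, with node
    indices offset per graph.
    """
    rows, cols, w, targets = [], [], [], []
    offset = 0
    r = 0
    for (labels, tgts), n in zip(ss_items, sizes):
        labels = np.asarray(labels)
        for t in tgts:
            if not t.valid:
                continue
            members = np.flatnonzero(labels == t.cluster_id) + offset
            rows += [r] * len(members)
            cols += members.tolist()
            w += [1.0 / len(members)] * len(members)
            targets.append(t.vector)
            r += 1
        offset += n
    if not targets:
        return None, None
    pool = sp.csr_matrix((w, (rows, cols)), shape=(r, offset))
    return pool, np.stack(targets)


def train(spec: ModelSpec, train_views, train_targets, *, val_views=None,
          val_targets=None, train_events=None, val_events=None,
          lr=5e-3, weight_decay=0.0, batch_size=16, stopping="early",
          max_epochs=500, patience=20, fixed_epochs=100, seed=0,
          ss_data=None, aux_targets=None, net=None) -> TrainedModel:
    """Fit a neural model; seeded and reproducible.

    ``stopping`` is ``"early"`` (patience on the validation loss, best
    epoch restored) or ``"fixed_epochs"``. ``ss_data`` provides per-graph
    spectral clusters and composition targets for the self-supervision
    head; ``aux_targets`` maps auxiliary task names to target arrays for
    multi-task models. Non-finite losses abort with a diagnostic.
    """
    if spec.family in SHALLOW_FAMILIES:
        raise ValueError("use fit_shallow for rf / logistic regression")
    if stopping == "early" and val_views is None:
        raise ValueError("early stopping requires a validation fold")
    rng = np.random.default_rng(seed)
    train_targets = np.asarray(train_targets)
    n = len(train_views)

    def make_batch(idx):
        views = [train_views[i] for i in idx]
        if spec.family == "mlp":
            X = np.stack([np.asarray(v.payload if hasattr(v, "payload") else v)
                          for v in views])
            batch = GraphBatch([X])
        else:
            batch = GraphBatch(views, add_self_loops=spec.add_self_loops)
        tgt = train_targets[idx]
        ev = None if train_events is None else np.asarray(train_events)[idx]
        ssb = None
        if ss_data is not None:
            ssb = _build_ss_batch([ss_data[i] for i in idx], batch.sizes)
        aux = None
        if aux_targets:
            aux = {k: np.asarray(v)[idx] for k, v in aux_targets.items()}
        return batch, tgt, ev, ssb, aux

    if batch_size is None or batch_size >= n:
        parts = [np.arange(n)]
    else:
        perm = rng.permutation(n)
        parts = [perm[i:i + batch_size] for i in range(0, n, batch_size)]
    batches = [make_batch(idx) for idx in parts]

    if net is None:
        first = batches[0][0]
        in_dim = first.X.shape[1]
        net = NeuralNet(spec, in_dim, seed=int(rng.integers(2 ** 31)))
        if ss_data is not None:
            n_types = ss_data[0][1][0].vector.shape[0] if ss_data[0][1] else 1
            for item in ss_data:
                if item[1]:
                    n_types = item[1][0].vector.shape[0]
                    break
            net.attach_ss_head(n_types, seed=int(rng.integers(2 ** 31)))

    val_pack = None
    if val_views is not None:
        if spec.family == "mlp":
            X = np.stack([np.asarray(v.payload if hasattr(v, "payload") else v)
                          for v in val_views])
            vb = GraphBatch([X])
        else:
            vb = GraphBatch(val_views, add_self_loops=spec.add_self_loops)
        val_pack = (vb, np.asarray(val_targets),
                    None if val_events is None else np.asarray(val_events))

    opt = nn.Adam(net.params, lr=lr, weight_decay=weight_decay)
    sched = nn.ReduceLROnPlateau(opt)
    history = {"train_loss": [], "val_loss": []}
    n_epochs = max_epochs if stopping == "early" else fixed_epochs
    best = np.inf
    best_state = net.get_state()
    bad = 0

    def total_loss(hooks, tgt, ev, ssb, aux):
        l = model_loss(spec.task, hooks["logits"], tgt, events=ev)
        if ssb is not None and spec.lambda_aux > 0:
            l = nn.add(l, nn.scale(net.ss_loss(hooks, ssb), spec.lambda_aux))
        if aux:
            for name, kind, n_out, w in spec.aux_tasks:
                if name in aux:
                    tgt_a = aux[name]
                    la = model_loss(kind, hooks[f"logits_{name}"], tgt_a)
                    l = nn.add(l, nn.scale(la, w))
        return l

    for epoch in range(n_epochs):
        order = rng.permutation(len(batches))
        running = 0.0
        weight = 0
        for bi in order:
            batch, tgt, ev, ssb, aux = batches[bi]
            hooks = net.forward(batch)
            l = total_loss(hooks, tgt, ev, ssb, aux)
            if not _is_finite(l.value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            l.backward()
            opt.step()
            running += float(l.value) * len(tgt)
            weight += len(tgt)
        train_loss = running / max(weight, 1)
        history["train_loss"].append(train_loss)
        if val_pack is not None:
            vb, vt, ve = val_pack
            vl = float(model_loss(spec.task, net.forward(vb)["logits"], vt,
                                  events=ve).value)
            history["val_loss"].append(vl)
            monitored = vl
        else:
            monitored = train_loss
        sched.step(monitored)
        if stopping == "early":
            if monitored < best - 1e-9:
                best = monitored
                best_state = net.get_state()
                bad = 0
            else:
                bad += 1
                if bad > patience:
                    break
        else:
            best_state = net.get_state()
    if not history["train_loss"]:
        # zero-epoch budget: record the untrained losses for selection
        tot, weight = 0.0, 0
        for batch, tgt, ev, ssb, aux in batches:
            hooks = net.forward(batch)
            tot += float(total_loss(hooks, tgt, ev, ssb, aux).value) * len(tgt)
            weight += len(tgt)
        history["train_loss"].append(tot / max(weight, 1))
        if val_pack is not None:
            vb, vt, ve = val_pack
            history["val_loss"].append(float(model_loss(
                spec.task, net.forward(vb)["logits"], vt, events=ve).value))
    net.set_state(best_state)
    return TrainedModel(spec, net, history=history, seed=seed)


# ---------------------------------------------------------------------------
# grid search and the ablation driver


@dataclass
class EvalRecord:
    arm: str
    family: str
    outer: int
    inner: int
    hyperparams: dict
    train_loss: float | None
    val_loss: float | None
    test_aupr: float | None
    selected: bool


_SPEC_KEYS = {f.name for f in ModelSpec.__dataclass_fields__.values()} \
    if hasattr(ModelSpec, "__dataclass_fields__") else set()
_TRAIN_KEYS = {"lr", "weight_decay", "l2", "batch_size", "max_epochs",
               "patience", "fixed_epochs"}
_VIEW_KEYS = {"r", "k", "n_clusters"}


def _split_config(cfg: dict):
    spec_kw, train_kw, view_kw = {}, {}, {}
    for key, v in cfg.items():
        if key in _VIEW_KEYS:
            view_kw[key] = v
        elif key in _TRAIN_KEYS:
            train_kw["weight_decay" if key == "l2" else key] = v
        elif key in ModelSpec.__dataclass_fields__:
            spec_kw[key] = v
        else:
            raise ValueError(f"unknown hyperparameter {key!r}")
    return spec_kw, train_kw, view_kw


def _proba_full(model, X, n_classes):
    """Class probabilities aligned to 0..n_classes-1 for shallow models."""
    p = model.predict_proba(X)
    out = np.zeros((len(X), n_classes))
    for j, c in enumerate(model.classes_):
        out[:, int(c)] = p[:, j]
    return out


def grid_search(family: str, grid, plan: SplitPlan, view_builder, y, patients,
                *, arm="arm", spec_base=None, train_kwargs=None,
                selection=None, n_classes=None, seed=0, ss_builder=None):
    """Nested-CV grid search for one arm.

    ``view_builder(view_kw)`` returns the per-sample views for one
    view-parameter point (cached by the caller); ``selection`` is
    ``"val_loss"`` or ``"train_loss"`` (defaults by plan mode). Returns
    ``(records, winners)`` where winners maps (outer, inner) to the trained
    model of the selected configuration.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    y = np.asarray(y)
    patients = np.asarray(patients)
    n_classes = n_classes or int(y.max()) + 1
    selection = selection or ("train_loss" if plan.mode == "train_test" else "val_loss")
    train_kwargs = dict(train_kwargs or {})
    spec_base = spec_base or {}
    records: list[EvalRecord] = []
    winners = {}
    for o, outer_split in enumerate(plan.outer):
        test_idx = _sample_indices(patients, outer_split["test"])
        cfg_models = []
        cfg_losses = []
        for ci, cfg in enumerate(grid):
            spec_kw, tr_kw, view_kw = _split_config(cfg)
            views = view_builder(view_kw)
            ss_data = ss_builder(view_kw) if ss_builder is not None else None
            models_i, losses_i, recs_i = [], [], []
            for i, inner in enumerate(outer_split["inner"]):
                tr_idx = _sample_indices(patients, inner["train"])
                val_idx = (_sample_indices(patients, inner["val"])
                           if inner.get("val") else None)
                cell_seed = (seed * 9973 + o * 211 + i * 17 + ci
                             + inner.get("replicate", 0)) % (2 ** 31)
                if family in SHALLOW_FAMILIES:
                    X = np.stack([np.asarray(views[j].payload) for j in range(len(views))])
                    model = fit_shallow(X[tr_idx], y[tr_idx], family, seed=cell_seed)
                    p_tr = _proba_full(model, X[tr_idx], n_classes)
                    tr_loss = _log_loss(p_tr, y[tr_idx])
                    if val_idx is not None:
                        p_val = _proba_full(model, X[val_idx], n_classes)
                        val_loss = _log_loss(p_val, y[val_idx])
                    else:
                        val_loss = None
                else:
                    kw = dict(train_kwargs)
                    kw.update(tr_kw)
                    spec = ModelSpec(family=family, n_outputs=n_classes,
                                     **{**spec_base, **spec_kw})
                    stopping = kw.pop("stopping",
                                      "early" if val_idx is not None else "fixed_epochs")
                    model = train(
                        spec, [views[j] for j in tr_idx], y[tr_idx],
                        val_views=([views[j] for j in val_idx]
                                   if val_idx is not None else None),
                        val_targets=(y[val_idx] if val_idx is not None else None),
                        stopping=stopping, seed=cell_seed,
                        ss_data=([ss_data[j] for j in tr_idx]
                                 if ss_data is not None else None),
                        **kw)
                    tr_loss = model.history["train_loss"][-1]
                    val_loss = (model.history["val_loss"][-1]
                                if model.history["val_loss"] else None)
                sel = tr_loss if selection == "train_loss" else val_loss
                models_i.append((model, views))
                losses_i.append(sel)
                recs_i.append(EvalRecord(arm, family, o, i, dict(cfg),
                                         tr_loss, val_loss, None, False))
            cfg_models.append(models_i)
            cfg_losses.append(float(np.mean(losses_i)))
            records.extend(recs_i)
        best_ci = int(np.argmin(cfg_losses))
        for i, (model, views) in enumerate(cfg_models[best_ci]):
            if family in SHALLOW_FAMILIES:
                X = np.stack([np.asarray(v.payload) for v in views])
                scores = _proba_full(model, X[test_idx], n_classes)
            else:
                scores = model.predict_proba([views[j] for j in test_idx])
            score_in = scores[:, 1] if n_classes == 2 else scores
            test = aupr(score_in, y[test_idx])
            rec = next(r for r in records
                       if r.arm == arm and r.outer == o and r.inner == i
                       and r.hyperparams == dict(grid[best_ci]))
            rec.test_aupr = test
            rec.selected = True
            winners[(o, i)] = model
    return records, winners


def _log_loss(proba, y):
    p = np.clip(proba[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.log(p).mean())


def records_to_frame(records) -> pd.DataFrame:
    import json
    rows = []
    for r in records:
        rows.append({"arm": r.arm, "family": r.family, "outer": r.outer,
                     "inner": r.inner, "train_loss": r.train_loss,
                     "val_loss": r.val_loss, "aupr": r.test_aupr,
                     "selected": r.selected,
                     "hyperparams": json.dumps(r.hyperparams, sort_keys=True)})
    return pd.DataFrame(rows)


def run_ablation(cohort, ladder, *, plan=None, mode="train_val_test", seed=0,
                 train_kwargs=None, view_cache=None) -> dict:
    """Run an ablation ladder under one shared split plan.

    ``ladder``: list of arms, each a dict with keys ``arm`` (name),
    ``view`` (view kind), ``family``, optional ``view_params``, ``grid``
    (list of hyperparameter dicts, default one empty point), ``spec``
    (ModelSpec field overrides) and ``train`` (training overrides).

    Returns a dict with the tidy per-cell results table, pairwise
    comparisons, the random-predictor baseline, and the winning models.
    """
    from . import features as feat

    labels = cohort.labels()
    class_names = list(cohort.class_names)
    observed = sorted(set(labels), key=class_names.index)
    y = np.array([observed.index(l) for l in labels])
    patients = cohort.patients()
    n_classes = len(observed)
    if plan is None:
        plan = make_splits(labels=labels, patients=patients, mode=mode, seed=seed)
    view_cache = view_cache if view_cache is not None else {}
    all_records = []
    selected = {}
    winners = {}
    for arm_cfg in ladder:
        arm = arm_cfg["arm"]
        kind = arm_cfg["view"]
        family = arm_cfg["family"]
        base_params = dict(arm_cfg.get("view_params", {}))
        grid = arm_cfg.get("grid") or [{}]
        tkw = dict(train_kwargs or {})
        tkw.update(arm_cfg.get("train", {}))

        def view_builder(view_kw, _kind=kind, _base=base_params):
            params = dict(_base)
            params.update(view_kw)
            key = (_kind, tuple(sorted(params.items())))
            if key not in view_cache:
                view_cache[key] = feat.make_views(cohort, _kind, params)
            return view_cache[key]

        ss_builder = arm_cfg.get("ss_builder")
        recs, win = grid_search(
            family, grid, plan, view_builder, y, patients, arm=arm,
            spec_base=arm_cfg.get("spec"), train_kwargs=tkw,
            n_classes=n_classes, seed=seed, ss_builder=ss_builder)
        all_records.extend(recs)
        selected[arm] = np.array([r.test_aupr for r in recs if r.selected])
        winners[arm] = win
    comparisons = []
    for a, b in itertools.combinations(selected, 2):
        delta, p = compare(selected[a], selected[b])
        comparisons.append({"arm_a": a, "arm_b": b, "delta_aupr": delta, "p": p})
    test_label_sets = [labels[_sample_indices(patients, o["test"])]
                       for o in plan.outer for _ in o["inner"]]
    baseline = random_baseline(test_label_sets)
    return {
        "results": records_to_frame(all_records),
        "selected_aupr": selected,
        "comparisons": pd.DataFrame(comparisons),
        "baseline": baseline,
        "baseline_classes": observed,
        "plan": plan,
        "winners": winners,
    }
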