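"""Interpretation toolkit: embeddings, concordance, attention, saliency."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import tissuegraph as tg
from tissuegraph.evaluate import train
from tissuegraph.models import GraphBatch, ModelSpec, NeuralNet, TrainedModel
from tissuegraph.interpret import (
    attention_type_matrix, class_distance, concordance, extract_embeddings,
    filter_context, filter_gradients, interaction_relevance, manifold,
    quantile_transform, saliency, saliency_table, stratify,
    neighbor_frequency_diff,
)


def brute_force_concordance(values, times, events):
    num = den = 0.0
    n = len(values)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i]:
                den += 1
                if values[i] > values[j]:
                    num += 1
                elif values[i] == values[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestConcordance:
    def test_perfect_no_censoring(self):
        t = np.array([3.0, 1.0, 4.0, 2.0])
        assert concordance(-t, t, np.ones(4, int)) == 1.0

    def test_constant_predictor_half(self):
        t = np.array([1.0, 2.0, 3.0])
        assert concordance(np.zeros(3), t, np.ones(3, int)) == 0.5

    def test_spec_example_matches_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1])
        values = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance(values, times, events) == \
            brute_force_concordance(values, times, events)

    def test_matches_brute_force_all_patterns(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            t = np.round(rng.exponential(5, n), 3)
            e = rng.integers(0, 2, n)
            v = np.round(rng.normal(size=n), 1)  # predictor ties likely
            try:
                ours = concordance(v, t, e)
            except ValueError:
                with pytest.raises(ValueError):
                    brute_force_concordance(v, t, e)
                continue
            assert abs(ours - brute_force_concordance(v, t, e)) <= 1e-12

    def test_matches_lifelines_convention(self):
        from lifelines.utils import concordance_index
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 60)  # continuous: no time ties
        e = rng.integers(0, 2, 60)
        v = rng.normal(size=60)
        ours = concordance(v, t, e)
        ref = concordance_index(t, -v, e)  # lifelines: higher pred = later event
        assert np.isclose(ours, ref)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                        np.array([0, 1]))  # only the later time is an event


class TestManifold:
    def test_quantile_transform_preserves_ranks(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3)) ** 3
        U = quantile_transform(X)
        for j in range(3):
            assert spearmanr(X[:, j], U[:, j]).statistic == 1.0
        assert (U > 0).all() and (U <= 1).all()

    def test_planted_one_dimensional_recovery(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(size=80)
        v = rng.normal(size=6)
        X = np.outer(s, v) + rng.normal(0, 0.1, size=(80, 6))
        man = manifold(X)
        rho = spearmanr(man["scores"][:, 0], s).statistic
        assert abs(rho) >= 0.9

    def test_two_samples_single_component(self):
        man = manifold(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert man["scores"].shape[1] == 1

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            man = manifold(X)
        assert list(man["kept_features"]) == [0, 2]

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        a = manifold(X)
        b = manifold(X.copy())
        assert np.allclose(a["scores"], b["scores"])
        for c in range(a["loadings"].shape[0]):
            j = np.argmax(np.abs(a["loadings"][c]))
            assert a["loadings"][c, j] > 0


class TestClassDistance:
    def test_two_singletons(self):
        X = np.array([[0.0, 0.0], [3.0, 0.0]])
        labels = np.array(["a", "b"])
        assert class_distance(X, labels, "a", "b") == 3.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        labels = np.repeat(["a", "b"], 10)
        assert np.isclose(class_distance(X, labels, "a", "b"),
                          class_distance(X, labels, "b", "a"))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        labels = np.array(["a"] * 7 + ["b"] * 8)
        ref = np.mean([np.linalg.norm(X[i] - X[j])
                       for i in range(7) for j in range(7, 15)])
        assert np.isclose(class_distance(X, labels, "a", "b"), ref)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            class_distance(np.ones((2, 2)), np.array(["a", "a"]), "a", "b")


def _trained_gat(seed=0):
    """A small trained GAT on one-hot cell-type inputs."""
    cfg = tg.SimConfig(n_patients=8, images_per_patient=2, cells_per_image=120,
                       signal=tg.SignalConfig(channel="composition", strength=1.0,
                                              immune_fraction={"aggregated": 0.5,
                                                               "diffuse": 0.1}))
    co = tg.simulate_cohort(cfg, seed=seed)
    views = tg.make_views(co, "graph_celltype_onehot", {"r": 50.0})
    y = (co.labels() == "diffuse").astype(int)
    spec = ModelSpec(family="gat", n_outputs=2, depth_node=1, width_node=6)
    model = train(spec, views, y, stopping="fixed_epochs", fixed_epochs=15,
                  batch_size=None, lr=1e-2, seed=seed)
    types = sorted(co.type_immune_map)
    return co, views, model, types


class TestAttention:
    def test_zero_scores_all_ones(self):
        co, views, model, types = _trained_gat()
        layer = model.net.node_layers[0]
        layer["W_Q"].value[:] = 0.0
        M = attention_type_matrix(model, types)
        assert np.allclose(M.to_numpy(), 1.0)

    def test_hand_transform_and_key_max(self):
        co, views, model, types = _trained_gat()
        layer = model.net.node_layers[0]
        S = layer["W_Q"].value @ layer["W_K"].value.T
        M = attention_type_matrix(model, types)
        assert np.allclose(M.to_numpy().max(axis=0), 1.0)  # per-key max
        k = 0
        expect = np.exp(S[:, k] - S[:, k].max())
        assert np.allclose(M.to_numpy()[:, k], expect / expect.max())

    def test_per_key_shift_invariance(self):
        co, views, model, types = _trained_gat()
        layer = model.net.node_layers[0]
        M1 = attention_type_matrix(model, types).to_numpy()
        # shift all raw scores of one key by a constant via W_K column offset:
        # S[:, k] = WQ @ WK[k]; adding c to every query's score for key k needs
        # a rank-one change; emulate by direct recomputation instead
        S = layer["W_Q"].value @ layer["W_K"].value.T
        S2 = S.copy()
        S2[:, 2] += 7.0
        E = np.exp(S2 - S2.max(axis=0, keepdims=True))
        E = E / E.max(axis=0, keepdims=True)
        assert np.allclose(E[:, 2], M1[:, 2])

    def test_requires_gat(self, small_cohort):
        views = tg.make_views(small_cohort, "graph_immune_binary", {"r": 40.0})
        spec = ModelSpec(family="gin", n_outputs=2, depth_node=1, width_node=4)
        model = TrainedModel(spec, NeuralNet(spec, 2, seed=0))
        with pytest.raises(ValueError):
            attention_type_matrix(model, ["immune", "other"])


class TestFilterContext:
    def test_all_ones_attention_returns_wv(self):
        co, views, model, types = _trained_gat()
        model.net.node_layers[0]["W_Q"].value[:] = 0.0  # attention all ones
        heat, grads = filter_context(model, views[:2], types[0], types)
        assert np.allclose(heat.to_numpy(),
                           model.net.node_layers[0]["W_V"].value)

    def test_ignored_filter_zero_gradient(self):
        co, views, model, types = _trained_gat()
        # zero the graph-stack weights feeding from filter 0 onward
        model.net.graph_layers[0].W.value[0, :] = 0.0
        grads = filter_gradients(model, views[:2])
        assert np.allclose(grads[:, 0], 0.0)

    def test_gradients_match_finite_differences(self):
        co, views, model, types = _trained_gat()
        view = views[0]
        batch = model._batch([view])
        grads = filter_gradients(model, [view])
        # numeric check: perturb the first-layer output via W_V is indirect;
        # instead compare against an explicit epsilon-bump of the activations
        from tissuegraph import nn
        from tissuegraph.nn import Tensor
        hooks = model.net.forward(batch)
        H1 = hooks["layer_outputs"][0]
        n_nodes = len(H1.value)
        for c in range(2):
            sel = np.zeros((2, 1))
            sel[c] = 1.0

            def head_from(h1):
                pooled = nn.spmm(batch.pool_mean, Tensor(h1))
                out = pooled
                for layer in model.net.graph_layers:
                    out = layer(out)
                return float(nn.mean_all(
                    nn.matmul(model.net.out_layer(out), Tensor(sel))).value)

            for f in (0, grads.shape[1] - 1):
                eps = 1e-6
                up = H1.value.copy()
                up[:, f] += eps
                dn = H1.value.copy()
                dn[:, f] -= eps
                # bumping every node's filter f: the response equals
                # n_nodes * (per-node averaged gradient)
                num = (head_from(up) - head_from(dn)) / (2 * eps) / n_nodes
                ana = grads[c, f]
                assert abs(num - ana) / max(abs(num), abs(ana), 1e-10) <= 1e-4


class TestSaliency:
    def _trained_gin(self, seed=0):
        cfg = tg.SimConfig(n_patients=8, images_per_patient=2, cells_per_image=120,
                           signal=tg.SignalConfig(channel="arrangement",
                                                  strength=1.0))
        co = tg.simulate_cohort(cfg, seed=seed)
        views = tg.make_views(co, "graph_immune_binary", {"r": 50.0})
        y = (co.labels() == "aggregated").astype(int)
        spec = ModelSpec(family="gin", n_outputs=2, depth_node=1, width_node=6)
        model = train(spec, views, y, stopping="fixed_epochs", fixed_epochs=20,
                      batch_size=None, lr=1e-2, seed=seed)
        return co, views, model

    def test_constant_model_zero_saliency(self):
        co, views, model = self._trained_gin()
        model.net.out_layer.W.value[:] = 0.0
        model.net.out_layer.b.value[:] = 0.0
        tab = saliency(model, views[0])
        assert np.allclose(tab["saliency"], 0.0)

    def test_finite_difference_agreement(self):
        co, views, model = self._trained_gin()
        view = views[0]
        tab = saliency(model, view)
        batch = model._batch([view])
        from tissuegraph import nn
        from tissuegraph.nn import Tensor
        sel = Tensor(np.array([[-1.0], [1.0]]))
        for i in (0, 5, 20):
            j = int(batch.X[i].argmax())
            eps = 1e-6
            Xp = batch.X.copy()
            Xp[i, j] += eps
            up = float(nn.mean_all(nn.matmul(
                model.net.forward(batch, X=Tensor(Xp))["logits"], sel)).value)
            Xp[i, j] -= 2 * eps
            dn = float(nn.mean_all(nn.matmul(
                model.net.forward(batch, X=Tensor(Xp))["logits"], sel)).value)
            num = (up - dn) / (2 * eps)
            ana = tab["saliency"].iloc[i]
            assert abs(num - ana) / max(abs(num), abs(ana), 1e-10) <= 1e-4

    def test_relabeling_permutes_saliencies(self):
        co, views, model = self._trained_gin()
        view = views[0]
        tab = saliency(model, view)
        rng = np.random.default_rng(0)
        g = view.payload
        perm = rng.permutation(g.n_nodes)
        import scipy.sparse as sp
        P = sp.csr_matrix((np.ones(len(perm)), (np.arange(len(perm)), perm)))
        g2 = tg.SpatialGraph((P @ g.adjacency @ P.T).tocsr(),
                             g.node_features[perm],
                             immune_flag=g.immune_flag[perm])
        tab2 = saliency(model, tg.FeatureView(view.kind, g2, view.sample_id, {}))
        assert np.allclose(tab2["saliency"].to_numpy(),
                           tab["saliency"].to_numpy()[perm], atol=1e-10)

    def test_shallow_model_rejected(self):
        spec = ModelSpec(family="mlp", n_outputs=3)
        model = TrainedModel(spec, NeuralNet(spec, 4, seed=0))
        with pytest.raises(ValueError):
            saliency(model, None)


class TestStratify:
    def test_single_stratum_global_mean(self):
        tab = pd.DataFrame({"saliency": [1.0, 2.0, 3.0], "degree": [1, 2, 3],
                            "neighbor_immune_fraction": [0.1, 0.5, 0.9],
                            "label": ["x"] * 3})
        grid = stratify(tab, degree_bins=[0, 100], fraction_bins=[0, 1.0])
        assert np.isclose(grid["saliency"].dropna().iloc[0], 2.0)

    def test_matches_groupby_oracle(self):
        tab = pd.DataFrame({
            "saliency": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "degree": [1, 1, 7, 7, 1, 7],
            "neighbor_immune_fraction": [0.1, 0.9, 0.1, 0.9, 0.1, 0.9],
            "label": ["a", "a", "a", "a", "b", "b"],
        })
        grid = stratify(tab, degree_bins=[0, 5, 10], fraction_bins=[0, 0.5, 1.0])
        lo_lo_a = grid[(grid["degree_bin"].astype(str) == "[0, 5)")
                       & (grid["fraction_bin"].astype(str) == "(0.5, 1.0]")
                       & (grid["label"] == "a")]["saliency"].iloc[0]
        assert lo_lo_a == 2.0
        hi_hi_b = grid[(grid["degree_bin"].astype(str) == "[5, 10)")
                       & (grid["fraction_bin"].astype(str) == "(0.5, 1.0]")
                       & (grid["label"] == "b")]["saliency"].iloc[0]
        assert hi_hi_b == 6.0

    def test_row_order_invariant(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({
            "saliency": rng.normal(size=40),
            "degree": rng.integers(0, 20, 40),
            "neighbor_immune_fraction": rng.uniform(0, 1, 40),
            "label": rng.choice(["a", "b"], 40),
        })
        g1 = stratify(tab)
        g2 = stratify(tab.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(g1, g2)

    def test_overlapping_bins_rejected(self):
        tab = pd.DataFrame({"saliency": [1.0], "degree": [1],
                            "neighbor_immune_fraction": [0.5], "label": ["a"]})
        with pytest.raises(ValueError):
            stratify(tab, degree_bins=[0, 10, 5])


class TestNeighborFrequency:
    def _graphs(self, cohort, r=50.0):
        return [tg.SpatialGraph(tg.build_radius_graph(s.coords, r),
                                np.zeros((s.n_cells, 1)), cell_type=s.cell_type)
                for s in cohort.samples]

    def test_identical_classes_zero_vector(self):
        rng = np.random.default_rng(0)
        from tissuegraph.simulate import TissueSample
        samples = []
        coords = rng.uniform(0, 100, size=(60, 2))
        types = rng.choice(["tumor", "stroma"], 60).astype(object)
        for i, lab in enumerate(["a", "b"]):
            samples.append(TissueSample(f"s{i}", f"p{i}", coords, types,
                                        np.zeros(60, bool), np.zeros((60, 1)),
                                        label=lab))
        graphs = [tg.SpatialGraph(tg.build_radius_graph(coords, 40.0),
                                  np.zeros((60, 1)), cell_type=types)] * 2
        diff = neighbor_frequency_diff(samples, graphs, "tumor", "a", "b")
        assert np.allclose(diff.to_numpy(), 0.0)

    def test_interaction_cohort_sign(self):
        cfg = tg.SimConfig(n_patients=12, images_per_patient=2, cells_per_image=300,
                           class_names=("class1", "class3"),
                           signal=tg.SignalConfig(channel="interaction",
                                                  strength=0.25,
                                                  interaction_pair=("fibroblast",
                                                                    "tumor")))
        co = tg.simulate_cohort(cfg, seed=4)
        diff = neighbor_frequency_diff(co.samples, self._graphs(co), "tumor",
                                       "class1", "class3")
        assert diff["fibroblast"] > 0

    def test_frequencies_normalized_per_image(self, small_cohort):
        s = small_cohort.samples[0]
        g = self._graphs(small_cohort)[0]
        A = g.adjacency
        qmask = s.cell_type == "tumor"
        rows, cols = A[qmask].nonzero()
        counts = pd.Series(s.cell_type[cols]).value_counts(normalize=True)
        assert np.isclose(counts.sum(), 1.0)

    def test_missing_query_type_excluded(self):
        from tissuegraph.simulate import TissueSample
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, size=(30, 2))
        samples = [
            TissueSample("s0", "p0", coords,
                         np.array(["stroma"] * 30, dtype=object),
                         np.zeros(30, bool), np.zeros((30, 1)), label="a"),
            TissueSample("s1", "p1", coords,
                         np.array(["tumor"] * 15 + ["stroma"] * 15, dtype=object),
                         np.zeros(30, bool), np.zeros((30, 1)), label="a"),
            TissueSample("s2", "p2", coords,
                         np.array(["tumor"] * 15 + ["stroma"] * 15, dtype=object),
                         np.zeros(30, bool), np.zeros((30, 1)), label="b"),
        ]
        graphs = [tg.SpatialGraph(tg.build_radius_graph(coords, 40.0),
                                  np.zeros((30, 1)), cell_type=s.cell_type)
                  for s in samples]
        with pytest.warns(UserWarning, match="excluded"):
            diff = neighbor_frequency_diff(samples, graphs, "tumor", "a", "b")
        assert np.allclose(diff.to_numpy(), 0.0)


class TestEmbeddings:
    def test_rows_match_cohort_and_hooks(self, small_cohort):
        views = tg.make_views(small_cohort, "graph_immune_binary", {"r": 40.0})
        spec = ModelSpec(family="gin", n_outputs=2, depth_node=1, width_node=4)
        model = TrainedModel(spec, NeuralNet(spec, 2, seed=0))
        df = extract_embeddings(model, views, small_cohort.samples)
        assert len(df) == len(small_cohort)
        hooks = model.net.forward(model._batch(views))
        emb_cols = [c for c in df.columns if c.startswith("emb_")]
        assert np.array_equal(df[emb_cols].to_numpy(),
                              hooks["graph_embedding"].value)

    def test_duplicated_sample_duplicated_row(self, small_cohort):
        views = tg.make_views(small_cohort, "graph_immune_binary", {"r": 40.0})
        spec = ModelSpec(family="gin", n_outputs=2, depth_node=1, width_node=4)
        model = TrainedModel(spec, NeuralNet(spec, 2, seed=0))
        df = extract_embeddings(model, views + [views[0]])
        emb_cols = [c for c in df.columns if c.startswith("emb_")]
        assert np.allclose(df[emb_cols].iloc[0], df[emb_cols].iloc[-1])

    def test_non_graph_model_rejected(self):
        spec = ModelSpec(family="mlp", n_outputs=2)
        model = TrainedModel(spec, NeuralNet(spec, 4, seed=0))
        with pytest.raises(ValueError):
            extract_embeddings(model, [])
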