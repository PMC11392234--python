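"""Model-level tests: forward composition, loss closed forms, training
contracts, ablation wiring, persistence."""

import numpy as np
import pytest

from ecdcdgi import (
    ECDCDGIClassifier,
    ModelConfig,
    SyntheticSpec,
    bce_loss,
    forward,
    generate,
    load_model,
    predict,
    save_model,
    train,
)
from ecdcdgi import encoder as enc
from ecdcdgi import model as mdl


def _init(graph, cfg, seed=0):
    return mdl.init_weights(graph.n_features, cfg, np.random.default_rng(seed))


# -- forward -----------------------------------------------------------------


def test_forward_matches_encoder_op_composition(make_random_graph):
    g = make_random_graph(n=30, f=6)
    cfg = ModelConfig(hidden_dim=5, n_layers=3)
    W = _init(g, cfg, seed=4)
    # make the readout non-trivial
    rng = np.random.default_rng(9)
    for t in range(cfg.n_layers + 1):
        W[f"W_Z{t}"] = rng.normal(size=(cfg.hidden_dim, 1))
    logits, probs, states = forward(g, W, cfg)

    Z = enc.project_features(g.X, W["W_I"], W["b_I"])
    zs = [Z]
    for t in range(cfg.n_layers):
        K, Q, V = enc.compute_qkv(Z, W[f"W_K{t}"], W[f"W_Q{t}"], W[f"W_V{t}"])
        P = enc.attention_propagate(enc.pairwise_similarity(Q, K), V)
        H = enc.gcn_propagate(g.A, V)
        Z = enc.fuse_residual(P, H, Z, W[f"W_d{t}"], cfg.beta,
                              W[f"ln_gain{t}"], W[f"ln_shift{t}"])
        zs.append(Z)
    M = sum(W[f"alpha{t}"] * (zs[t] @ W[f"W_Z{t}"]) for t in range(cfg.n_layers + 1))
    assert np.allclose(logits, M.ravel(), atol=1e-8)
    assert np.allclose(probs, 1 / (1 + np.exp(-logits)), atol=1e-12)
    assert len(states) == cfg.n_layers + 1


def test_layer0_only_readout_ignores_graph_structure(make_random_graph):
    g = make_random_graph(n=15, f=5)
    cfg = ModelConfig(hidden_dim=4, n_layers=2)
    W = _init(g, cfg, seed=1)
    W["W_Z0"] = np.ones((4, 1))
    for t in range(1, 3):
        W[f"alpha{t}"] = np.asarray(0.0)
    logits1, _, _ = forward(g, W, cfg)
    g2 = make_random_graph(n=15, f=5)   # different topology
    g2.X = g.X
    logits2, _, _ = forward(g2, W, cfg)
    assert np.allclose(logits1, logits2, atol=1e-12)


def test_forward_is_permutation_equivariant(make_random_graph):
    from ecdcdgi.graph import GeneGraph
    import scipy.sparse as sp
    g = make_random_graph(n=18, f=5)
    cfg = ModelConfig(hidden_dim=6, n_layers=2)
    W = _init(g, cfg, seed=2)
    rng = np.random.default_rng(0)
    for t in range(cfg.n_layers + 1):
        W[f"W_Z{t}"] = rng.normal(size=(6, 1))
    logits, _, _ = forward(g, W, cfg)
    pi = rng.permutation(g.n_nodes)
    A = g.A.toarray()[np.ix_(pi, pi)]
    gp = GeneGraph(node_ids=[g.node_ids[i] for i in pi], A=sp.csr_array(A),
                   X=g.X[pi], y=g.y[pi])
    logits_p, _, _ = forward(gp, W, cfg)
    assert np.allclose(logits_p, logits[pi], atol=1e-8)


def test_forward_feature_width_mismatch_raises(make_random_graph):
    g = make_random_graph(n=10, f=5)
    cfg = ModelConfig(hidden_dim=4, n_layers=1)
    W = mdl.init_weights(7, cfg, np.random.default_rng(0))
    with pytest.raises(ValueError):
        forward(g, W, cfg)


def test_ablation_flags_change_architecture_not_code(make_random_graph):
    g = make_random_graph(n=12, f=5)
    outs = {}
    for flags in [
        {},
        {"use_ecd_attention": False},
        {"use_gcn": False},
        {"use_residual": False},
        {"use_multilayer_attention": False},
    ]:
        cfg = ModelConfig(hidden_dim=4, n_layers=2, **flags)
        W = _init(g, cfg, seed=5)
        rng = np.random.default_rng(1)
        for t in range(cfg.n_layers + 1):
            W[f"W_Z{t}"] = rng.normal(size=(4, 1))
        logits, _, _ = forward(g, W, cfg)
        outs[tuple(sorted(flags))] = logits
        assert np.isfinite(logits).all()
    # single-branch variants use a d x d fusion matrix
    cfg1 = ModelConfig(hidden_dim=4, use_gcn=False)
    W1 = mdl.init_weights(5, cfg1, np.random.default_rng(0))
    assert W1["W_d0"].shape == (4, 4)
    with pytest.raises(ValueError):
        ModelConfig(use_ecd_attention=False, use_gcn=False)


def test_record_energy_reports_per_layer_trajectory(make_random_graph):
    g = make_random_graph(n=10, f=5)
    cfg = ModelConfig(hidden_dim=4, n_layers=3)
    _, _, states = forward(g, _init(g, cfg), cfg, record_energy=True)
    energies = [s.energy for s in states[1:]]
    assert len(energies) == 3
    assert all(e is not None and e >= 0 for e in energies)


# -- loss --------------------------------------------------------------------


def test_bce_half_probabilities_give_log_two():
    y = np.array([1.0, 0.0, 1.0, np.nan])
    p = np.full(4, 0.5)
    assert abs(bce_loss(p, y) - np.log(2.0)) < 1e-9


def test_bce_single_labeled_node_closed_form():
    y = np.array([1.0, np.nan])
    p = np.array([0.1, 0.77])
    assert abs(bce_loss(p, y) - (-np.log(0.1))) < 1e-12


def test_bce_perfect_prediction_hits_clamp_floor():
    y = np.array([1.0, 0.0])
    p = np.array([1.0, 0.0])
    assert 0.0 < bce_loss(p, y) < 2e-7


def test_bce_excludes_unlabeled_and_masked_nodes():
    y = np.array([1.0, 0.0, 1.0])
    p = np.array([0.9, 0.9, 0.2])
    mask = np.array([True, False, False])
    assert abs(bce_loss(p, y, mask) - (-np.log(0.9))) < 1e-12


def test_bce_empty_mask_rejected():
    with pytest.raises(ValueError):
        bce_loss(np.array([0.5]), np.array([np.nan]))


# -- training ----------------------------------------------------------------


def test_training_reduces_loss_on_planted_signal():
    g = generate(SyntheticSpec(n_nodes=200, attach_m=3, n_features=12,
                               n_informative=6, seed=11))
    est = train(g, config=ModelConfig(hidden_dim=16, n_layers=2, epochs=30))
    assert est.history_[-1] < est.history_[0]
    assert len(est.history_) == 30


def test_zero_learning_rate_freezes_weights(small_graph, tiny_config):
    cfg = ModelConfig(**{**tiny_config.__dict__, "learning_rate": 0.0, "epochs": 3})
    est = ECDCDGIClassifier.from_config(cfg).fit_graph(small_graph)
    W0 = mdl.init_weights(small_graph.n_features, cfg, np.random.default_rng(cfg.random_state))
    for k, v in W0.items():
        assert np.array_equal(est.weights_[k], v), k
    assert len(set(est.history_)) == 1


def test_same_seed_reproduces_loss_trace(small_graph, tiny_config):
    h1 = train(small_graph, config=tiny_config).history_
    h2 = train(small_graph, config=tiny_config).history_
    assert h1 == h2


def test_single_class_training_mask_rejected(small_graph, tiny_config):
    mask = small_graph.y == 1.0
    with pytest.raises(ValueError):
        train(small_graph, train_mask=mask, config=tiny_config)


def test_gradient_matches_finite_difference_on_weight_slice(make_random_graph):
    from ecdcdgi.autodiff import Tensor
    g = make_random_graph(n=10, f=5)
    cfg = ModelConfig(hidden_dim=4, n_layers=2)
    W0 = _init(g, cfg, seed=3)
    rng = np.random.default_rng(8)
    for t in range(cfg.n_layers + 1):
        W0[f"W_Z{t}"] = rng.normal(size=(4, 1)) * 0.3
    Ahat = enc.normalized_adjacency(g.A)
    params = {k: Tensor(v.copy(), requires_grad=True) for k, v in W0.items()}
    _, probs, _ = mdl._forward_core(g.X, Ahat, params, cfg)
    loss = bce_loss(probs, g.y)
    loss.backward()

    def loss_at(W):
        _, p, _ = mdl._forward_core(g.X, Ahat, W, cfg)
        return float(bce_loss(p, g.y))

    h = 1e-6
    for key in ["W_K1", "W_I", "W_d0", "alpha2"]:
        base = np.asarray(W0[key], dtype=float)
        flat = base.ravel()
        picks = rng.choice(flat.size, size=min(5, flat.size), replace=False)
        for lin in picks:
            ix = np.unravel_index(lin, base.shape)
            Wp = {k: np.array(v, dtype=float) for k, v in W0.items()}
            Wm = {k: np.array(v, dtype=float) for k, v in W0.items()}
            Wp[key][ix] += h
            Wm[key][ix] -= h
            num = (loss_at(Wp) - loss_at(Wm)) / (2 * h)
            ana = np.asarray(params[key].grad)[ix]
            assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-8), (key, ix)


# -- prediction --------------------------------------------------------------


def test_predictions_are_deterministic(small_graph, tiny_config):
    est = train(small_graph, config=tiny_config)
    l1, p1 = predict(est)
    l2, p2 = predict(est)
    assert np.array_equal(l1, l2) and np.array_equal(p1, p2)
    assert np.all((p1 > 0) & (p1 < 1))


def test_planted_positives_outscore_negatives_out_of_sample():
    deltas = []
    for s in range(5):
        g = generate(SyntheticSpec(n_nodes=150, attach_m=2, n_features=12,
                                   n_informative=6, effect_size=1.5, seed=40 + s))
        labeled = np.flatnonzero(g.labeled_mask)
        rng = np.random.default_rng(s)
        hold = rng.choice(labeled, size=len(labeled) // 3, replace=False)
        mask = g.labeled_mask.copy()
        mask[hold] = False
        if len({g.y[i] for i in np.flatnonzero(mask)}) < 2:
            continue
        est = train(g, train_mask=mask,
                    config=ModelConfig(hidden_dim=16, n_layers=2, epochs=40,
                                       random_state=s))
        _, probs = predict(est)
        pos = probs[[i for i in hold if g.y[i] == 1.0]]
        neg = probs[[i for i in hold if g.y[i] == 0.0]]
        deltas.append(pos.mean() - neg.mean())
    assert np.mean(deltas) > 0


def test_zero_features_zero_readout_give_half_probability(make_random_graph):
    g = make_random_graph(n=8, f=4)
    g.X = np.zeros_like(g.X)
    cfg = ModelConfig(hidden_dim=3, n_layers=1)
    W = _init(g, cfg)  # readout W_Z is zero-initialized
    _, probs, _ = forward(g, W, cfg)
    assert np.allclose(probs, 0.5)


def test_feature_width_mismatch_at_predict_raises(small_graph, tiny_config):
    est = train(small_graph, config=tiny_config)
    with pytest.raises(ValueError):
        est.decision_function(np.zeros((4, small_graph.n_features + 1)))


# -- persistence & sklearn interface ----------------------------------------


def test_save_load_round_trip(tmp_path, small_graph, tiny_config):
    est = train(small_graph, config=tiny_config)
    path = tmp_path / "model.npz"
    save_model(est, path)
    est2 = load_model(path)
    l1, p1 = predict(est, small_graph)
    l2, p2 = predict(est2, small_graph)
    assert np.allclose(l1, l2, atol=1e-12)
    assert est2.get_params()["n_layers"] == tiny_config.n_layers


def test_estimator_params_round_trip():
    est = ECDCDGIClassifier(hidden_dim=7, use_gcn=False)
    params = est.get_params()
    assert params["hidden_dim"] == 7 and params["use_gcn"] is False
    est.set_params(hidden_dim=9)
    assert est._config().hidden_dim == 9


def test_predict_proba_columns_sum_to_one(small_graph, tiny_config):
    est = train(small_graph, config=tiny_config)
    proba = est.predict_proba()
    assert proba.shape == (small_graph.n_nodes, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
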