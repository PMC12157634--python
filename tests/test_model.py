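"""Model components: posterior, sampling, shifts, decoding, loss bookkeeping."""

import numpy as np
import pytest

import shiftvae as sv
from shiftvae._autodiff import Tensor
from shiftvae.model import LossConfig, gaussian_kl, mmd_squared_loss
from shiftvae.scm import solve_scm


def test_encoder_outputs_finite_and_deterministic(micro_model):
    X = np.zeros((3, 12))
    post = micro_model.encode_expression(X)
    assert np.all(np.isfinite(post.mean.numpy()))
    assert np.all(np.isfinite(post.log_var.numpy()))
    # identical cells -> identical posteriors
    rng = np.random.default_rng(0)
    X2 = np.tile(rng.normal(size=12), (2, 1))
    post2 = micro_model.encode_expression(X2)
    np.testing.assert_array_equal(post2.mean.numpy()[0], post2.mean.numpy()[1])
    with pytest.raises(ValueError, match="genes"):
        micro_model.encode_expression(np.zeros((2, 5)))


def test_kl_matches_closed_form(micro_model):
    rng = np.random.default_rng(1)
    post = micro_model.encode_expression(rng.normal(size=(4, 12)))
    mu, lv = post.mean.numpy(), post.log_var.numpy()
    oracle = 0.5 * (np.exp(lv) + mu ** 2 - 1.0 - lv).sum(axis=1).mean()
    assert abs(float(gaussian_kl(post).data) - oracle) < 1e-12
    assert oracle >= 0.0


def test_kl_zero_iff_standard_normal(micro_model):
    from shiftvae.model import PosteriorParams
    post = PosteriorParams(mean=Tensor(np.zeros((2, 4))),
                           log_var=Tensor(np.zeros((2, 4))))
    assert float(gaussian_kl(post).data) == 0.0


def test_sample_latent_reparameterization(micro_model):
    from shiftvae.model import PosteriorParams
    mu = np.array([[1.0, -2.0, 0.5, 0.0]])
    lv = np.array([[0.2, -0.5, 0.0, 1.0]])
    post = PosteriorParams(mean=Tensor(mu), log_var=Tensor(lv))
    # zero variance collapses to the mean
    degenerate = PosteriorParams(mean=Tensor(mu), log_var=Tensor(lv - 1e3))
    np.testing.assert_allclose(
        micro_model.sample_latent(degenerate, 0).numpy(), mu, atol=1e-12)
    # seeded determinism
    a = micro_model.sample_latent(post, 42).numpy()
    b = micro_model.sample_latent(post, 42).numpy()
    np.testing.assert_array_equal(a, b)
    # Monte-Carlo moments within 3 standard errors
    wide = PosteriorParams(mean=Tensor(np.tile(mu, (100_000, 1))),
                           log_var=Tensor(np.tile(lv, (100_000, 1))))
    draws = micro_model.sample_latent(wide, 7).numpy()
    sd = np.exp(0.5 * lv[0])
    se_mean = sd / np.sqrt(1e5)
    assert np.all(np.abs(draws.mean(axis=0) - mu[0]) < 3 * se_mean)
    se_var = sd ** 2 * np.sqrt(2 / 1e5)
    assert np.all(np.abs(draws.var(axis=0) - sd ** 2) < 3 * se_var)


def test_encode_shift_determinism_and_errors(micro_model):
    label = np.array([0.3, -0.1, 0.8])
    a = micro_model.encode_shift(label).numpy()
    b = micro_model.encode_shift(label).numpy()
    np.testing.assert_array_equal(a, b)
    assert np.all(np.isfinite(a))
    with pytest.raises(ValueError, match="label length"):
        micro_model.encode_shift(np.zeros(5))


def test_control_shift_is_zero(micro_model):
    np.testing.assert_array_equal(micro_model.shift_for(None).numpy(),
                                  np.zeros((1, 4)))
    np.testing.assert_array_equal(
        micro_model.shift_for(micro_model.control_token).numpy(),
        np.zeros((1, 4)))


def test_unknown_perturbation_error_mentions_shift_selection(micro_model):
    with pytest.raises(KeyError, match="select_shift"):
        micro_model.forward(np.zeros((2, 12)), "g5", rng=0)


def test_decode_shapes_and_local_lipschitz(micro_model):
    rng = np.random.default_rng(2)
    U = rng.normal(size=(3, 4))
    X = micro_model.decode(U).numpy()
    assert X.shape == (3, 12) and np.all(np.isfinite(X))
    eps = 1e-6
    X2 = micro_model.decode(U + eps).numpy()
    assert np.max(np.abs(X2 - X)) < 1e-3  # small input change, bounded output change
    with pytest.raises(ValueError, match="latent"):
        micro_model.decode(np.zeros((2, 7)))


def test_forward_control_is_solved_exogenous(micro_model):
    rng = np.random.default_rng(3)
    X = rng.normal(size=(4, 12))
    out = micro_model.forward(X, None, use_mean=True)
    post = micro_model.encode_expression(X)
    U = solve_scm(micro_model.scm, post.mean.numpy(), np.zeros((1, 4)))
    np.testing.assert_array_equal(out, micro_model.decode(U).numpy())


def test_zero_penetrance_equals_control_forward(micro_model):
    rng = np.random.default_rng(4)
    X = rng.normal(size=(5, 12))
    a = micro_model.forward(X, None, rng=11)
    b = micro_model.forward(X, "g1", c=0.0, rng=11)
    np.testing.assert_array_equal(a, b)


def test_conditional_variant_equals_causal_when_graph_empty():
    graph = sv.GraphSpec(mode="none_conditional", n=4)
    model = sv.PerturbationVAE(n_genes=10, n_latent=4, feature_dim=2,
                               graph=graph, hidden=(8,), shift_hidden=(8,),
                               seed=1)
    rng = np.random.default_rng(5)
    feats = sv.PerturbationFeatures(feature_matrix=rng.normal(size=(10, 2)),
                                    gene_ids=[f"g{i}" for i in range(10)],
                                    k=2, n_control_cells=5)
    model.register_perturbations(feats, ["g3"])
    X = rng.normal(size=(3, 10))
    causal = model.forward(X, "g3", rng=2)
    conditional = model.forward(X, "g3", rng=2, variant="conditional")
    np.testing.assert_array_equal(causal, conditional)


def test_loss_degenerate_configs(micro_model):
    rng = np.random.default_rng(6)
    ctrl = rng.normal(size=(6, 12))
    pert = {"g1": rng.normal(size=(4, 12))}
    _, plain = micro_model.compute_loss(ctrl, pert,
                                        LossConfig(beta=0.0, gamma=0.0), rng=0)
    assert plain.total == plain.reconstruction
    _, full = micro_model.compute_loss(ctrl, pert,
                                       LossConfig(beta=0.3, gamma=2.0), rng=0)
    assert full.check()
    assert full.reconstruction == plain.reconstruction
    assert full.kl >= 0.0 and full.mmd >= -1e-12


def test_loss_warns_on_single_cell_perturbation(micro_model):
    rng = np.random.default_rng(7)
    ctrl = rng.normal(size=(4, 12))
    with pytest.warns(UserWarning, match="MMD term is skipped"):
        _, bd = micro_model.compute_loss(ctrl, {"g1": rng.normal(size=(1, 12))},
                                         LossConfig(), rng=0)
    assert bd.mmd == 0.0


def test_gradients_reach_all_components(tiny_model, tiny_ds):
    model = tiny_model
    ctrl = tiny_ds.control_cells()[:16]
    p = model.shift_table.seen[0]
    pert = {p: tiny_ds.cells_for(p)[:16]}
    total, _ = model.compute_loss(ctrl, pert, LossConfig(), rng=3)
    for param in model.parameters():
        param.grad = None
    total.backward()
    groups = {
        "encoder": model.encoder.parameters(),
        "shift_encoder": model.shift_encoder.parameters(),
        "decoder": model.decoder.parameters(),
        "graph": [model.scm.A],
        "penetrance": [model.shift_table.c[p]],
    }
    for name, params in groups.items():
        assert any(p.grad is not None and np.any(p.grad != 0) for p in params), name


def test_checkpoint_round_trip(tmp_path, tiny_model, tiny_ds):
    path = str(tmp_path / "model.npz")
    tiny_model.shift_table.set_unseen("unseen_gene", 1.7)
    tiny_model.save(path)
    loaded = sv.PerturbationVAE.load(path)
    X = tiny_ds.control_cells()[:5]
    p = tiny_model.shift_table.seen[0]
    np.testing.assert_array_equal(tiny_model.forward(X, p, rng=9),
                                  loaded.forward(X, p, rng=9))
    assert loaded.shift_table._unseen_c["unseen_gene"] == 1.7
    np.testing.assert_array_equal(tiny_model.scm.mask, loaded.scm.mask)


def test_mmd_loss_matches_metrics_estimator():
    rng = np.random.default_rng(8)
    X, Y = rng.normal(size=(10, 4)), rng.normal(size=(12, 4))
    from shiftvae.metrics import rbf_mmd_squared
    got = float(mmd_squared_loss(X, Tensor(Y), bandwidth=0.9).data)
    assert abs(got - rbf_mmd_squared(X, Y, bandwidth=0.9)) < 1e-12
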