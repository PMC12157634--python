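import numpy as np
import pytest

import shiftvae as sv


@pytest.fixture(scope="session")
def tiny_gt():
    """Desk-scale ground truth: 40 genes, 8 modules, 6 perturbations."""
    return sv.make_ground_truth(m=40, n_modules=8, n_perturbations=6,
                                n_target_modules=4, seed=11)


@pytest.fixture(scope="session")
def tiny_ds(tiny_gt):
    return sv.simulate_dataset(tiny_gt, cells_per_condition=80)


@pytest.fixture(scope="session")
def tiny_split(tiny_ds):
    spec = sv.SplitSpec(mode="out_of_distribution", split_index=0,
                        total_splits=3, seed=2)
    return sv.make_split(tiny_ds, spec)


def tiny_train_config(**overrides):
    base = dict(epochs=20, n_latent=8, feature_dim=8, hidden=(32, 32),
                shift_hidden=(32,), seed=0, batch_perturbations=4,
                cells_per_condition=24, steps_per_epoch=12,
                val_cells_per_condition=32)
    base.update(overrides)
    return sv.TrainConfig(**base)


@pytest.fixture(scope="session")
def tiny_result(tiny_split):
    """A small trained model shared by model-dependent tests."""
    train, val, _ = tiny_split
    return sv.train(train, val, tiny_train_config())


@pytest.fixture(scope="session")
def tiny_model(tiny_result):
    return tiny_result.model


@pytest.fixture()
def micro_model():
    """Untrained 12-gene model for fast shape/determinism checks."""
    graph = sv.GraphSpec(mode="learned_full_triangular", n=4, seed=3)
    model = sv.PerturbationVAE(n_genes=12, n_latent=4, feature_dim=3,
                               graph=graph, hidden=(8,), shift_hidden=(8,),
                               seed=5)
    rng = np.random.default_rng(0)
    features = sv.PerturbationFeatures(
        feature_matrix=rng.normal(size=(12, 3)),
        gene_ids=[f"g{i}" for i in range(12)], k=3, n_control_cells=10)
    model.register_perturbations(features, ["g1", "g2"])
    return model
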