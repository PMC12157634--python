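"""Data containers, loaders, perturbation labels, filtering and splits."""

import numpy as np
import pandas as pd
import pytest

import shiftvae as sv
from shiftvae.data import export_split_assignments, load_dataset, save_dataset


def small_dataset():
    """6 cells x 4 genes with 2 controls and 2 perturbations."""
    rng = np.random.default_rng(0)
    return sv.ExpressionDataset(
        matrix=rng.normal(size=(6, 4)),
        gene_ids=["gA", "gB", "gC", "gD"],
        perturbations=np.array(["control", "control", "gA", "gA", "gB", "gB"],
                               dtype=object))


def test_dataset_counts_and_registry():
    ds = small_dataset()
    assert ds.n_controls == 2 and ds.n_genes == 4
    assert ds.counts["gA"] == 2
    assert ds.perturbation_names == ["gA", "gB"]
    with pytest.raises(ValueError, match="registry"):
        sv.ExpressionDataset(matrix=np.zeros((1, 2)), gene_ids=["a", "b"],
                             perturbations=np.array(["unknown"], dtype=object))


def test_dataset_rejects_non_finite():
    with pytest.raises(ValueError, match="non-finite"):
        sv.ExpressionDataset(matrix=np.array([[np.nan, 1.0]]),
                             gene_ids=["a", "b"],
                             perturbations=np.array(["control"], dtype=object))


@pytest.mark.parametrize("fmt,suffix", [("h5ad", "data.h5ad"), ("mtx", "mtxdir")])
def test_round_trip(tmp_path, fmt, suffix):
    ds = small_dataset()
    path = str(tmp_path / suffix)
    save_dataset(ds, path, fmt=fmt)
    loaded = load_dataset(path, fmt=fmt)
    np.testing.assert_allclose(loaded.matrix, ds.matrix, atol=1e-12)
    assert list(loaded.perturbations) == list(ds.perturbations)
    assert loaded.gene_ids == ds.gene_ids
    assert loaded.n_controls == 2


def test_missing_label_column_is_named(tmp_path):
    adata = small_dataset().to_anndata()
    adata.obs = adata.obs.rename(columns={"perturbation": "guide"})
    path = str(tmp_path / "x.h5ad")
    adata.write_h5ad(path)
    with pytest.raises(ValueError, match="perturbation"):
        load_dataset(path)
    assert load_dataset(path, perturbation_column="guide").n_cells == 6


def test_unknown_labels_dropped_when_requested(tmp_path):
    adata = small_dataset().to_anndata()
    adata.obs.iloc[2, 0] = "not_a_gene"
    path = str(tmp_path / "y.h5ad")
    adata.write_h5ad(path)
    with pytest.raises(ValueError, match="registry"):
        load_dataset(path)
    with pytest.warns(UserWarning, match="dropping"):
        ds = load_dataset(path, on_unknown="drop")
    assert ds.n_cells == 5


# -- perturbation features ---------------------------------------------------

def test_features_identical_genes_share_labels():
    ds = sv.ExpressionDataset(
        matrix=np.outer(np.arange(5.0), np.ones(3)),  # identical gene profiles
        gene_ids=["a", "b", "c"],
        perturbations=np.array(["control"] * 5, dtype=object))
    feats = sv.compute_perturbation_features(ds, k=1)
    np.testing.assert_allclose(feats.feature_matrix[0],
                               feats.feature_matrix[1], atol=1e-10)
    np.testing.assert_allclose(feats.feature_matrix[0],
                               feats.feature_matrix[2], atol=1e-10)


def test_features_match_full_svd_oracle():
    rng = np.random.default_rng(1)
    ds = sv.ExpressionDataset(
        matrix=rng.normal(size=(4, 3)), gene_ids=["a", "b", "c"],
        perturbations=np.array(["control"] * 4, dtype=object))
    feats = sv.compute_perturbation_features(ds, k=1)
    M = ds.matrix.T  # genes x cells
    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Mc)
    oracle = U[:, 0] * s[0]
    got = feats.feature_matrix[:, 0]
    sign = np.sign(oracle @ got)
    np.testing.assert_allclose(got, sign * oracle, atol=1e-10)


def test_features_gene_permutation_equivariance():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(6, 5))
    genes = [f"g{i}" for i in range(5)]
    labels = np.array(["control"] * 6, dtype=object)
    ds = sv.ExpressionDataset(matrix=X, gene_ids=genes, perturbations=labels)
    perm = rng.permutation(5)
    ds_p = sv.ExpressionDataset(matrix=X[:, perm],
                                gene_ids=[genes[i] for i in perm],
                                perturbations=labels)
    f = sv.compute_perturbation_features(ds, k=2).feature_matrix
    f_p = sv.compute_perturbation_features(ds_p, k=2).feature_matrix
    np.testing.assert_allclose(f_p, f[perm], atol=1e-8)


def test_features_invariant_to_control_cell_order():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(7, 4))
    genes = ["a", "b", "c", "d"]
    labels = np.array(["control"] * 7, dtype=object)
    ds = sv.ExpressionDataset(matrix=X, gene_ids=genes, perturbations=labels)
    shuffled = sv.ExpressionDataset(matrix=X[rng.permutation(7)],
                                    gene_ids=genes, perturbations=labels)
    f = sv.compute_perturbation_features(ds, k=2).feature_matrix
    f_s = sv.compute_perturbation_features(shuffled, k=2).feature_matrix
    np.testing.assert_allclose(np.abs(f), np.abs(f_s), atol=1e-8)


def test_features_k_bounds():
    ds = small_dataset()
    with pytest.raises(ValueError, match="k must"):
        sv.compute_perturbation_features(ds, k=3)  # only 2 control cells
    with pytest.raises(KeyError, match="panel"):
        sv.compute_perturbation_features(ds, k=1).label_for("nope")


# -- filtering ----------------------------------------------------------------

def make_filter_dataset(n_per=300, shifted=True, seed=0):
    rng = np.random.default_rng(seed)
    m = 50
    controls = rng.normal(size=(n_per, m))
    pert = rng.normal(size=(n_per, m))
    if shifted:
        pert[:, :10] += 2.0  # large mean shift on 10 of 50 genes
    genes = [f"g{i}" for i in range(m)]
    labels = np.array(["control"] * n_per + ["g0"] * n_per, dtype=object)
    return sv.ExpressionDataset(matrix=np.vstack([controls, pert]),
                                gene_ids=genes, perturbations=labels)


def independent_cv_score(X, y, folds=5, seed=0):
    """Hand-rolled stratified CV accuracy with the same linear classifier."""
    from sklearn.linear_model import LogisticRegression
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold_of[idx] = np.arange(len(idx)) % folds
    scores = []
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        clf = LogisticRegression(max_iter=1000).fit(X[tr], y[tr])
        scores.append(np.mean(clf.predict(X[te]) == y[te]))
    return float(np.mean(scores))


def test_filter_removes_small_perturbations():
    ds = make_filter_dataset(n_per=150)
    with pytest.raises(ValueError, match="no perturbation"):
        sv.filter_perturbations(ds, min_cells=200)
    kept, log = sv.filter_perturbations(ds, min_cells=100)
    assert log.loc[0, "kept"]


def test_filter_removes_indistinguishable_perturbation():
    ds = make_filter_dataset(shifted=False)
    with pytest.raises(ValueError):
        sv.filter_perturbations(ds, min_cells=200, cv_threshold=0.6)
    # the logged score sits near chance for identically distributed cells
    try:
        sv.filter_perturbations(ds, min_cells=200, cv_threshold=0.6)
    except ValueError:
        pass
    _, log = sv.filter_perturbations(ds, min_cells=200, cv_threshold=0.0)
    assert abs(log.loc[0, "cv_score"] - 0.5) < 0.1


def test_filter_score_matches_independent_cv_oracle():
    ds = make_filter_dataset()
    kept, log = sv.filter_perturbations(ds, min_cells=200, cv_threshold=0.6,
                                        seed=1)
    assert "g0" in kept.perturbation_names
    X = np.vstack([ds.cells_for("g0"), ds.control_cells()])
    y = np.concatenate([np.ones(300), np.zeros(300)])
    oracle = independent_cv_score(X, y, seed=123)
    assert abs(log.loc[0, "cv_score"] - oracle) < 0.02


def test_filter_monotone_in_min_cells(tiny_ds):
    survivors = []
    for mc in (10, 40, 81):
        try:
            kept, _ = sv.filter_perturbations(tiny_ds, min_cells=mc,
                                              cv_threshold=0.0)
            survivors.append(set(kept.perturbation_names))
        except ValueError:
            survivors.append(set())
    assert survivors[2] <= survivors[1] <= survivors[0]


# -- splits --------------------------------------------------------------------

def make_split_dataset(n_pert=10, cells=100, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_pert)]
    labels = ["control"] * cells
    for g in genes:
        labels += [g] * cells
    X = rng.normal(size=(len(labels), n_pert))
    return sv.ExpressionDataset(matrix=X, gene_ids=genes,
                                perturbations=np.array(labels, dtype=object))


def test_in_distribution_split_fractions():
    ds = make_split_dataset()
    spec = sv.SplitSpec(mode="in_distribution", seed=1)
    tr, va, te = sv.make_split(ds, spec)
    for sub, expected in ((tr, 70), (va, 10), (te, 20)):
        assert sub.counts["g0"] == expected
        assert sub.counts["control"] == expected


def test_ood_splits_partition_perturbations():
    ds = make_split_dataset()
    tested = []
    for i in range(5):
        spec = sv.SplitSpec(mode="out_of_distribution", split_index=i,
                            total_splits=5, seed=3)
        tr, va, te = sv.make_split(ds, spec)
        assert len(te.perturbation_names) == 2
        assert not set(te.perturbation_names) & set(tr.perturbation_names)
        # train/val cells of retained perturbations split 85/15
        assert tr.counts["control"] == 85 and va.counts["control"] == 15
        tested.extend(te.perturbation_names)
    assert sorted(tested) == ds.perturbation_names


def test_split_deterministic_under_seed():
    ds = make_split_dataset()
    spec = sv.SplitSpec(mode="out_of_distribution", split_index=1, seed=7)
    a = sv.make_split(ds, spec)
    b = sv.make_split(ds, spec)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.matrix, y.matrix)
        assert list(x.perturbations) == list(y.perturbations)


def test_export_split_assignments(tmp_path):
    ds = make_split_dataset(n_pert=3, cells=10)
    tr, va, te = sv.make_split(ds, sv.SplitSpec(mode="in_distribution", seed=0))
    path = str(tmp_path / "splits.tsv")
    df = export_split_assignments(ds, {"train": tr, "val": va, "test": te}, path)
    back = pd.read_csv(path, sep="\t")
    assert len(back) == ds.n_cells
    assert set(back["split"]) == {"train", "val", "test"}
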