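"""Expression-data containers, perturbation labels, filtering and splits.

Datasets are cells x genes matrices of normalised expression with a per-cell
perturbation assignment; one reserved token marks non-targeting controls.
Reading and writing goes through :mod:`anndata` (``.h5ad``) or MatrixMarket
MTX plus cell/gene metadata tables.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTROL = "control"
PERTURBATION_COLUMN = "perturbation"

__all__ = ["ExpressionDataset", "PerturbationFeatures", "SplitSpec", "CONTROL",
           "load_dataset", "save_dataset", "compute_perturbation_features",
           "filter_perturbations", "make_split", "export_split_assignments"]


@dataclass
class ExpressionDataset:
    """Cells x genes normalised expression with per-cell perturbation labels."""

    matrix: np.ndarray
    gene_ids: list[str]
    perturbations: np.ndarray
    cell_ids: list[str] | None = None
    control_token: str = CONTROL

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != self.matrix.shape[1]:
            raise ValueError("gene_ids length does not match matrix columns")
        self.perturbations = np.asarray(self.perturbations, dtype=object)
        if self.perturbations.shape[0] != self.matrix.shape[0]:
            raise ValueError("one perturbation label per cell is required")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.matrix.shape[0])]
        registry = set(self.gene_ids)
        unknown = {p for p in self.perturbations
                   if p != self.control_token and p not in registry}
        if unknown:
            raise ValueError(
                f"perturbation labels not in the gene registry: {sorted(unknown)[:5]}"
                " — pass on_unknown='drop' to the loader to discard such cells")

    # -- basic queries --------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def counts(self) -> dict[str, int]:
        """Cell count per condition (D_p; the control entry is D_control)."""
        vals, cnts = np.unique(self.perturbations.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.perturbations == self.control_token))

    @property
    def perturbation_names(self) -> list[str]:
        """Non-control condition names, sorted for determinism."""
        return sorted({str(p) for p in self.perturbations
                       if p != self.control_token})

    def cells_for(self, perturbation: str) -> np.ndarray:
        return self.matrix[self.perturbations == perturbation]

    def control_cells(self) -> np.ndarray:
        return self.cells_for(self.control_token)

    def subset(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return ExpressionDataset(
            matrix=self.matrix[index],
            gene_ids=self.gene_ids,
            perturbations=self.perturbations[index],
            cell_ids=[self.cell_ids[i] for i in index],
            control_token=self.control_token)

    def pseudobulk(self, perturbation: str) -> np.ndarray:
        cells = self.cells_for(perturbation)
        if cells.shape[0] == 0:
            raise ValueError(f"no cells with label {perturbation!r}")
        return cells.mean(axis=0)

    # -- conversion -----------------------------------------------------------
    def to_anndata(self):
        import anndata
        return anndata.AnnData(
            X=self.matrix.copy(),
            obs=pd.DataFrame({PERTURBATION_COLUMN: self.perturbations.astype(str)},
                             index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")))


def _from_anndata(adata, perturbation_column: str, control_token: str,
                  on_unknown: str) -> ExpressionDataset:
    if perturbation_column not in adata.obs.columns:
        raise ValueError(
            f"cell metadata has no column {perturbation_column!r}; available: "
            f"{list(adata.obs.columns)}")
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    perts = adata.obs[perturbation_column].astype(str).to_numpy(dtype=object)
    gene_ids = [str(g) for g in adata.var_names]
    cell_ids = [str(c) for c in adata.obs_names]
    if on_unknown == "drop":
        registry = set(gene_ids) | {control_token}
        keep = np.array([p in registry for p in perts])
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} cells with "
                          "unrecognised perturbation labels")
        X, perts = X[keep], perts[keep]
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
    ds = ExpressionDataset(matrix=X, gene_ids=gene_ids, perturbations=perts,
                           cell_ids=cell_ids, control_token=control_token)
    if ds.n_controls == 0:
        raise ValueError(f"no control cells (token {control_token!r}) in input")
    return ds


def load_dataset(path: str, fmt: str | None = None,
                 perturbation_column: str = PERTURBATION_COLUMN,
                 control_token: str = CONTROL,
                 on_unknown: str = "error") -> ExpressionDataset:
    """Load an annotated ``.h5ad`` file or an MTX directory.

    The MTX layout is ``matrix.mtx`` (cells x genes), ``cells.tsv`` (with the
    perturbation column) and ``genes.tsv``, as written by :func:`save_dataset`.
    """
    import anndata
    if fmt is None:
        fmt = "h5ad" if str(path).endswith(".h5ad") else "mtx"
    if fmt == "h5ad":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        adata = anndata.read_h5ad(path)
    elif fmt == "mtx":
        from scipy.io import mmread
        mtx_path = os.path.join(path, "matrix.mtx")
        if not os.path.exists(mtx_path):
            raise FileNotFoundError(mtx_path)
        mat = mmread(mtx_path)
        X = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", index_col=0)
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", index_col=0)
        adata = anndata.AnnData(X=X, obs=cells, var=genes)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _from_anndata(adata, perturbation_column, control_token, on_unknown)


def save_dataset(ds: ExpressionDataset, path: str, fmt: str | None = None) -> None:
    """Write a dataset as ``.h5ad`` or as an MTX directory (see load_dataset)."""
    if fmt is None:
        fmt = "h5ad" if str(path).endswith(".h5ad") else "mtx"
    if fmt == "h5ad":
        ds.to_anndata().write_h5ad(path)
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix
        os.makedirs(path, exist_ok=True)
        mmwrite(os.path.join(path, "matrix.mtx"), coo_matrix(ds.matrix))
        adata = ds.to_anndata()
        adata.obs.to_csv(os.path.join(path, "cells.tsv"), sep="\t")
        pd.DataFrame(index=adata.var_names).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# perturbation labels: gene-wise principal-component scores of the controls
# ---------------------------------------------------------------------------

@dataclass
class PerturbationFeatures:
    """k-dimensional label per measured gene, used to encode perturbations.

    Labels are the projections of each gene's control-cell profile onto the
    top-k principal axes of the transposed (genes x cells) control matrix, so
    a label exists for any gene on the panel — including unseen targets.
    """

    feature_matrix: np.ndarray  # m x k
    gene_ids: list[str]
    k: int
    n_control_cells: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def label_for(self, gene: str) -> np.ndarray:
        try:
            return self.feature_matrix[self._index[gene]]
        except KeyError as err:
            raise KeyError(f"gene {gene!r} is not on the measured panel; no "
                           "perturbation label can be formed") from err


def compute_perturbation_features(ds: ExpressionDataset, k: int = 64
                                  ) -> PerturbationFeatures:
    """PCA scores of genes over control cells, with a fixed sign convention.

    Each principal axis is oriented so that its largest-magnitude loading is
    positive, making the labels deterministic and invariant to the order of
    the control cells.
    """
    controls = ds.control_cells()  # l x m
    l, m = controls.shape
    if l == 0:
        raise ValueError("dataset has no control cells")
    if not (1 <= k <= min(m, l)):
        raise ValueError(f"k must be in [1, min(m, l)] = [1, {min(m, l)}]")
    M = controls.T  # m x l: one row (profile over control cells) per gene
    M = M - M.mean(axis=0, keepdims=True)
    # principal axes of the gene cloud in R^l
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    scores = U[:, :k] * s[:k]
    # sign convention: largest-|loading| entry of each axis positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    return PerturbationFeatures(feature_matrix=scores, gene_ids=list(ds.gene_ids),
                                k=k, n_control_cells=l)


# ---------------------------------------------------------------------------
# perturbation filtering
# ---------------------------------------------------------------------------

def filter_perturbations(ds: ExpressionDataset, min_cells: int = 200,
                         cv_threshold: float = 0.6, folds: int = 5,
                         seed: int = 0) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Keep perturbations that are abundant and distinguishable from control.

    A perturbation survives if it has at least ``min_cells`` cells and an
    L2-regularised logistic regression separates its cells from an equal-size
    control sample with mean stratified ``folds``-fold CV accuracy strictly
    above ``cv_threshold``. Controls are always retained. Returns the filtered
    dataset and a per-perturbation decision log.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    if min_cells < 1 or folds < 2 or not (0.0 <= cv_threshold <= 1.0):
        raise ValueError("invalid filter parameters")
    controls = ds.control_cells()
    rng = np.random.default_rng(seed)
    rows = []
    kept: list[str] = []
    for p in ds.perturbation_names:
        Xp = ds.cells_for(p)
        n_p = Xp.shape[0]
        score = np.nan
        if n_p < min_cells:
            keep, reason = False, f"fewer than {min_cells} cells"
        else:
            n_ctrl = min(n_p, controls.shape[0])
            ctrl_sample = controls[rng.choice(controls.shape[0], size=n_ctrl,
                                              replace=False)]
            X = np.vstack([Xp, ctrl_sample])
            y = np.concatenate([np.ones(n_p), np.zeros(n_ctrl)])
            clf = LogisticRegression(max_iter=1000)
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            score = float(np.mean(cross_val_score(clf, X, y, cv=cv,
                                                  scoring="accuracy")))
            keep = score > cv_threshold
            reason = "kept" if keep else f"CV score {score:.3f} <= {cv_threshold}"
        rows.append({"perturbation": p, "n_cells": n_p, "cv_score": score,
                     "kept": keep, "reason": reason})
        if keep:
            kept.append(p)
    log = pd.DataFrame(rows)
    if not kept:
        raise ValueError("no perturbation passed the filters; consider relaxing "
                         "min_cells or cv_threshold")
    keep_mask = np.array([p == ds.control_token or p in set(kept)
                          for p in ds.perturbations])
    return ds.subset(np.flatnonzero(keep_mask)), log


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """In-distribution (per-condition 70/10/20 cell split) or out-of-
    distribution (held-out perturbations; remaining cells split 85/15)."""

    mode: str = "in_distribution"  # or "out_of_distribution"
    train_fraction: float = 0.70
    val_fraction: float = 0.10
    test_fraction: float = 0.20          # ID: cells; ignored for OOD
    ood_train_fraction: float = 0.85     # OOD train/val cell split
    split_index: int = 0
    total_splits: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("in_distribution", "out_of_distribution"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "in_distribution":
            total = self.train_fraction + self.val_fraction + self.test_fraction
            if not np.isclose(total, 1.0):
                raise ValueError("in-distribution fractions must sum to 1")
        else:
            if not (0 <= self.split_index < self.total_splits):
                raise ValueError("split_index must lie in [0, total_splits)")
            if not (0.0 < self.ood_train_fraction < 1.0):
                raise ValueError("ood_train_fraction must be in (0, 1)")


def _three_way(idx: np.ndarray, fracs: tuple[float, float],
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = rng.permutation(idx)
    n = len(idx)
    n_train = int(round(fracs[0] * n))
    n_val = int(round(fracs[1] * n))
    n_val = min(n_val, n - n_train)
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def make_split(ds: ExpressionDataset, spec: SplitSpec
               ) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Deterministic (seeded) train/validation/test split.

    In-distribution: every condition (controls included) is split 70/10/20 at
    the cell level. Out-of-distribution: the perturbation set is shuffled once
    with the seed and partitioned into ``total_splits`` consecutive groups;
    group ``split_index`` forms the test set (all its cells), every other
    perturbation's cells — and the controls — are split 85/15 into train/val.
    Across the ``total_splits`` values of ``split_index`` each perturbation is
    tested exactly once.
    """
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    conditions = [ds.control_token] + ds.perturbation_names

    if spec.mode == "in_distribution":
        for p in conditions:
            idx = np.flatnonzero(ds.perturbations == p)
            if len(idx) < 3:
                warnings.warn(f"condition {p!r} has {len(idx)} cells (<3); "
                              "assigning all to train")
                train_idx.append(idx)
                continue
            tr, va, te = _three_way(idx, (spec.train_fraction, spec.val_fraction),
                                    rng)
            train_idx.append(tr); val_idx.append(va); test_idx.append(te)
    else:
        perts = np.array(ds.perturbation_names, dtype=object)
        order = np.random.default_rng(spec.seed).permutation(len(perts))
        bounds = np.linspace(0, len(perts), spec.total_splits + 1).astype(int)
        lo, hi = bounds[spec.split_index], bounds[spec.split_index + 1]
        test_perts = set(perts[order[lo:hi]].tolist())
        for p in conditions:
            idx = np.flatnonzero(ds.perturbations == p)
            if p in test_perts:
                test_idx.append(idx)
                continue
            if len(idx) < 2:
                warnings.warn(f"condition {p!r} has {len(idx)} cells (<2); "
                              "assigning all to train")
                train_idx.append(idx)
                continue
            idx = rng.permutation(idx)
            n_train = int(round(spec.ood_train_fraction * len(idx)))
            train_idx.append(idx[:n_train]); val_idx.append(idx[n_train:])

    def build(parts: list[np.ndarray]) -> ExpressionDataset:
        idx = np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
        return ds.subset(idx)

    return build(train_idx), build(val_idx), build(test_idx)


def export_split_assignments(ds: ExpressionDataset, splits: dict[str, ExpressionDataset],
                             path: str) -> pd.DataFrame:
    """Write a cell-level TSV (cell_id, perturbation, split)."""
    rows = []
    for name, sub in splits.items():
        for cid, p in zip(sub.cell_ids, sub.perturbations):
            rows.append({"cell_id": cid, "perturbation": p, "split": name})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
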