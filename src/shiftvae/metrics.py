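"""Per-perturbation evaluation metrics for predicted single-cell responses.

Six metrics per perturbation: pseudo-bulk mean squared error and Pearson
correlation (bulk level), maximum mean discrepancy and energy distance
(distribution level), and the fractions of genes moved from control in the
same / opposite direction as the ground truth. Each metric is reported on the
full gene panel and on the top-50 highly variable genes, aggregated as
mean +/- SD across perturbations.

Estimator conventions: MMD uses the biased two-sample V-statistic with an RBF
kernel (bandwidth = median pooled pairwise distance) and is reported on the
metric scale (square root of the V-statistic); energy distance is the
V-statistic 2 E|a-b| - E|a-a'| - E|b-b'| with Euclidean norms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

METRIC_NAMES = ("mse", "pearson", "mmd", "energy_distance",
                "fraction_same", "fraction_changed")

__all__ = ["MetricsReport", "bulk_mse_pearson", "mmd", "rbf_mmd_squared",
           "energy_distance", "direction_fractions", "top_hvg", "evaluate",
           "median_bandwidth", "METRIC_NAMES"]


def median_bandwidth(pooled: np.ndarray) -> float:
    """Median pairwise Euclidean distance; falls back to 1.0 when degenerate."""
    d = pdist(np.asarray(pooled, dtype=float))
    if d.size == 0 or np.median(d) <= 0:
        warnings.warn("degenerate sample for the median heuristic; "
                      "falling back to bandwidth 1.0")
        return 1.0
    return float(np.median(d))


def rbf_mmd_squared(sample_a: np.ndarray, sample_b: np.ndarray,
                    bandwidth: float | None = None) -> float:
    """Biased (V-statistic) estimate of squared MMD with an RBF kernel."""
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if bandwidth is None:
        bandwidth = median_bandwidth(np.vstack([a, b]))
    gamma = 1.0 / (2.0 * bandwidth ** 2)
    k_aa = np.exp(-gamma * cdist(a, a, "sqeuclidean")).mean()
    k_bb = np.exp(-gamma * cdist(b, b, "sqeuclidean")).mean()
    k_ab = np.exp(-gamma * cdist(a, b, "sqeuclidean")).mean()
    return float(k_aa + k_bb - 2.0 * k_ab)


def mmd(sample_a: np.ndarray, sample_b: np.ndarray,
        bandwidth: float | None = None) -> float:
    """Maximum mean discrepancy on the metric scale (root of the V-statistic)."""
    return float(np.sqrt(max(rbf_mmd_squared(sample_a, sample_b, bandwidth), 0.0)))


def energy_distance(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Energy distance E-statistic (V-statistic convention, Euclidean norm)."""
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    ab = cdist(a, b).mean()
    aa = cdist(a, a).mean()
    bb = cdist(b, b).mean()
    return float(2.0 * ab - aa - bb)


def bulk_mse_pearson(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Pseudo-bulk MSE and Pearson r between per-gene mean vectors."""
    pm = np.atleast_2d(pred).mean(axis=0)
    tm = np.atleast_2d(truth).mean(axis=0)
    mse = float(np.mean((pm - tm) ** 2))
    if np.std(pm) == 0 or np.std(tm) == 0:
        return mse, float("nan")
    return mse, float(np.corrcoef(pm, tm)[0, 1])


def direction_fractions(pred: np.ndarray, truth: np.ndarray,
                        control: np.ndarray, tolerance: float = 1e-6
                        ) -> tuple[float, float]:
    """Fractions of genes moved from control in the same / opposite direction.

    Genes whose predicted or true displacement from the control mean is within
    ``tolerance`` are counted in neither fraction, so the two fractions sum to
    at most 1 (relative to the full gene panel).
    """
    d_pred = np.atleast_2d(pred).mean(axis=0) - np.atleast_2d(control).mean(axis=0)
    d_true = np.atleast_2d(truth).mean(axis=0) - np.atleast_2d(control).mean(axis=0)
    moved = (np.abs(d_pred) > tolerance) & (np.abs(d_true) > tolerance)
    g = d_pred.size
    same = np.sum(moved & (np.sign(d_pred) == np.sign(d_true)))
    changed = np.sum(moved & (np.sign(d_pred) != np.sign(d_true)))
    return float(same / g), float(changed / g)


def top_hvg(cells: np.ndarray, n_top: int = 50) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes (ties: lower index first)."""
    X = np.atleast_2d(np.asarray(cells, dtype=float))
    if n_top > X.shape[1]:
        raise ValueError("n_top exceeds the number of genes")
    var = X.var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_top]
    return np.sort(order)


@dataclass
class MetricsReport:
    """Per-perturbation metric table plus mean +/- SD aggregation."""

    per_perturbation: pd.DataFrame  # index: perturbation, columns: METRIC_NAMES
    gene_subset: str                # "all" | "top50_hvg"

    @property
    def aggregate(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.per_perturbation.mean(),
                             "sd": self.per_perturbation.std(ddof=0)})

    def to_frame(self) -> pd.DataFrame:
        df = self.per_perturbation.copy()
        df.insert(0, "gene_subset", self.gene_subset)
        return df


def _metrics_row(pred: np.ndarray, truth: np.ndarray, control: np.ndarray,
                 tolerance: float, bandwidth: float | None) -> dict[str, float]:
    mse, pearson = bulk_mse_pearson(pred, truth)
    same, changed = direction_fractions(pred, truth, control, tolerance)
    return {"mse": mse, "pearson": pearson,
            "mmd": mmd(pred, truth, bandwidth),
            "energy_distance": energy_distance(pred, truth),
            "fraction_same": same, "fraction_changed": changed}


def evaluate(pred_by_perturbation: dict[str, np.ndarray],
             truth_by_perturbation: dict[str, np.ndarray],
             control: np.ndarray, n_top: int = 50, tolerance: float = 1e-6,
             bandwidth: float | None = None
             ) -> tuple[MetricsReport, MetricsReport]:
    """All six metrics per perturbation, on all genes and on top-HVG subsets.

    The highly variable subset is selected per perturbation from its ground-
    truth cells. Perturbations present in the predictions but missing from the
    truth (or vice versa) are skipped with a warning.
    """
    rows_all, rows_hvg = {}, {}
    pred_keys, truth_keys = set(pred_by_perturbation), set(truth_by_perturbation)
    for missing in sorted(pred_keys ^ truth_keys):
        warnings.warn(f"perturbation {missing!r} present on one side only; skipped")
    for p in sorted(pred_keys & truth_keys):
        pred = np.atleast_2d(pred_by_perturbation[p])
        truth = np.atleast_2d(truth_by_perturbation[p])
        rows_all[p] = _metrics_row(pred, truth, control, tolerance, bandwidth)
        hvg = top_hvg(truth, n_top=min(n_top, truth.shape[1]))
        rows_hvg[p] = _metrics_row(pred[:, hvg], truth[:, hvg],
                                   np.atleast_2d(control)[:, hvg],
                                   tolerance, bandwidth)
    cols = list(METRIC_NAMES)
    return (MetricsReport(pd.DataFrame(rows_all).T[cols], "all"),
            MetricsReport(pd.DataFrame(rows_hvg).T[cols], "top50_hvg"))
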