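"""Latent perturbation embeddings and penetrance sweeps.

A perturbation's latent embedding is the mean endogenous state over a sample
of encoded control cells, computed without reparameterisation (the posterior
mean stands in for the average over infinite latent samples). Because the SCM
is linear, the embedding decomposes exactly as

    Ubar^p = Ubar^control + c_p * (I - A)^-1 S^p,

so displacements from control are exactly linear in the penetrance; this
module exploits that superposition instead of differencing two solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import ExpressionDataset
from .metrics import mmd
from .model import PerturbationVAE
from .scm import solve_scm

__all__ = ["EmbeddingSet", "embed_perturbations",
           "latent_expression_distance_scan", "penetrance_sweep"]


@dataclass
class EmbeddingSet:
    """Mean latent state per perturbation plus the control mean."""

    embeddings: dict[str, np.ndarray]  # perturbation -> Ubar^p (n,)
    control_mean: np.ndarray           # Ubar^control (n,)
    n_control_cells: int
    seed: int
    reparameterized: bool = False      # embeddings always use the posterior mean

    def displacement(self, perturbation: str) -> np.ndarray:
        return self.embeddings[perturbation] - self.control_mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({p: e for p, e in self.embeddings.items()}).T


def _control_latent_mean(model: PerturbationVAE, controls: np.ndarray,
                         n_cells: int, seed: int) -> tuple[np.ndarray, int]:
    controls = np.atleast_2d(controls)
    rng = np.random.default_rng(seed)
    take = min(n_cells, controls.shape[0])
    idx = rng.choice(controls.shape[0], size=take, replace=False)
    post = model.encode_expression(controls[idx])
    Z = post.mean.numpy()  # no reparameterisation
    U0 = solve_scm(model.scm, Z, np.zeros((1, model.n)))
    return U0.mean(axis=0), take


def _latent_shift(model: PerturbationVAE, perturbation: str,
                  c: float | None = None) -> np.ndarray:
    """c_p * (I - A)^-1 S^p, the exact latent displacement from control.

    Perturbations without a penetrance entry (unseen, before shift selection)
    are embedded at unit penetrance: the embedding then reflects the encoded
    shift direction only.
    """
    if perturbation == model.control_token:
        return np.zeros(model.n)
    if c is None:
        c_t = model.shift_table.penetrance_or_default(perturbation)
        label = model.shift_table.label(perturbation)
        shift = (c_t * model.encode_shift(label)).numpy()
    else:
        shift = model.shift_for(perturbation, c=c).numpy()
    return solve_scm(model.scm, shift, np.zeros((1, model.n)))[0]


def embed_perturbations(model: PerturbationVAE, ds: ExpressionDataset,
                        perturbations: list[str] | None = None,
                        n_cells: int = 256, seed: int = 0) -> EmbeddingSet:
    """Mean latent embedding Ubar^p for each perturbation (and control).

    All perturbations share the same encoded control sample, so differences
    between embeddings reflect only the propagated shifts.
    """
    controls = ds.control_cells()
    if controls.shape[0] == 0:
        raise ValueError("dataset has no control cells to encode")
    if perturbations is None:
        perturbations = ds.perturbation_names
    u_control, used = _control_latent_mean(model, controls, n_cells, seed)
    embeddings = {model.control_token: u_control}
    for p in perturbations:
        if p == model.control_token:
            continue
        embeddings[p] = u_control + _latent_shift(model, p)
    return EmbeddingSet(embeddings=embeddings, control_mean=u_control,
                        n_control_cells=used, seed=seed)


def latent_expression_distance_scan(model: PerturbationVAE,
                                    ds: ExpressionDataset,
                                    n_cells: int = 256, seed: int = 0,
                                    bandwidth: float | None = None
                                    ) -> tuple[pd.DataFrame, float]:
    """Expression-space MMD from control vs latent L2 displacement, per perturbation.

    Returns the per-perturbation table and the Spearman correlation between
    the two distance columns. Perturbations with fewer than 2 observed cells
    are skipped.
    """
    controls = ds.control_cells()
    emb = embed_perturbations(model, ds, n_cells=n_cells, seed=seed)
    rows = []
    for p in ds.perturbation_names:
        cells = ds.cells_for(p)
        if cells.shape[0] < 2:
            continue
        rows.append({
            "perturbation": p,
            "expression_mmd": mmd(cells, controls, bandwidth),
            "latent_l2": float(np.linalg.norm(emb.displacement(p))),
        })
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        rho = float(spearmanr(table["expression_mmd"], table["latent_l2"]).statistic)
    else:
        rho = float("nan")
    return table, rho


def penetrance_sweep(model: PerturbationVAE, perturbation: str,
                     c_values: np.ndarray, ds: ExpressionDataset,
                     n_cells: int = 128, seed: int = 0,
                     target: np.ndarray | None = None
                     ) -> tuple[dict[float, np.ndarray], pd.DataFrame]:
    """Predicted cell populations at each penetrance value.

    Reuses one encoded control sample across all c, so the latent displacement
    at each c is exactly c times the unit displacement. When a pseudo-bulk
    ``target`` is given, the trace records the mean-prediction MSE per c.
    """
    controls = ds.control_cells()
    rng = np.random.default_rng(seed)
    idx = rng.choice(controls.shape[0], size=min(n_cells, controls.shape[0]),
                     replace=False)
    post = model.encode_expression(controls[idx])
    Z = model.sample_latent(post, rng).numpy()
    U0 = solve_scm(model.scm, Z, np.zeros((1, model.n)))
    dU = _latent_shift(model, perturbation, c=1.0)
    predictions: dict[float, np.ndarray] = {}
    rows = []
    for c in np.asarray(c_values, dtype=float):
        pred = model.decode(U0 + c * dU).numpy()
        predictions[float(c)] = pred
        row = {"c": float(c),
               "latent_displacement": float(np.linalg.norm(c * dU))}
        if target is not None:
            row["mse"] = float(np.mean((pred.mean(axis=0)
                                        - np.asarray(target)) ** 2))
        rows.append(row)
    return predictions, pd.DataFrame(rows)
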