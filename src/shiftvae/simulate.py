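"""Synthetic Perturb-seq-like data from a known linear SCM with shift interventions.

The generator states a small, fully identified world: n_true latent gene
modules wired by a strictly upper-triangular weight matrix, a linear gene
read-out with one dominant module per gene, and single-gene perturbations that
shift the target gene's dominant module(s) negatively (knock-down semantics)
with a known scalar penetrance. Control and perturbed cells share the same
exogenous noise law Z ~ N(0, I).

Defaults: m=200 genes, 16 modules, 20 perturbations (two target genes per
perturbed module, so a held-out perturbation always has an in-training
functional neighbour), 300 cells per condition, edge probability 0.3 with
weights in [-0.8, 0.8], observation noise sd 0.1, penetrance in {0.5, 1, 2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import CONTROL, ExpressionDataset

__all__ = ["GroundTruthModel", "make_ground_truth", "simulate_dataset",
           "simulate_pseudobulk", "save_ground_truth", "load_ground_truth"]


@dataclass
class GroundTruthModel:
    """Known data-generating process for recovery experiments."""

    A: np.ndarray                      # strictly upper-triangular n x n
    readout_weights: np.ndarray        # m x n linear read-out
    readout_bias: np.ndarray           # m
    noise_sd: float
    gene_ids: list[str]
    shifts: dict[str, tuple[np.ndarray, float]]  # target gene -> (direction, penetrance)
    seed: int = 0
    control_token: str = CONTROL

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if not np.allclose(self.A, np.triu(self.A, k=1)):
            raise ValueError("A must be strictly upper-triangular (acyclic)")
        for p, (direction, c) in self.shifts.items():
            if not np.any(np.asarray(direction) != 0):
                raise ValueError(f"perturbation {p!r} has a zero shift direction")

    @property
    def n_modules(self) -> int:
        return self.A.shape[0]

    @property
    def n_genes(self) -> int:
        return self.readout_weights.shape[0]

    @property
    def perturbations(self) -> list[str]:
        return list(self.shifts)

    def solve_matrix(self) -> np.ndarray:
        return np.linalg.inv(np.eye(self.n_modules) - self.A)

    def population_mean(self, perturbation: str | None = None) -> np.ndarray:
        """Exact per-gene mean of a condition (infinite-cell pseudo-bulk)."""
        if perturbation is None or perturbation == self.control_token:
            shift = np.zeros(self.n_modules)
        else:
            direction, c = self.shifts[perturbation]
            shift = c * np.asarray(direction, dtype=float)
        u_mean = self.solve_matrix() @ shift
        return self.readout_weights @ u_mean + self.readout_bias


def make_ground_truth(m: int = 200, n_modules: int = 16,
                      n_perturbations: int = 20, edge_prob: float = 0.3,
                      weight_scale: float = 0.8, noise_sd: float = 0.1,
                      n_target_modules: int = 10,
                      penetrance_choices: tuple[float, ...] = (0.5, 1.0, 2.0),
                      seed: int = 0) -> GroundTruthModel:
    """Draw a random ground-truth model under the stated defaults.

    Every gene loads ~1 on one dominant module plus small dense background
    loadings; perturbations are 1- or 2-sparse negative shifts on the target
    gene's dominant module (2-sparse ones add a half-weight secondary module).
    """
    rng = np.random.default_rng(seed)
    A = np.triu(rng.uniform(-weight_scale, weight_scale, (n_modules, n_modules)),
                k=1) * np.triu(rng.random((n_modules, n_modules)) < edge_prob, k=1)
    primary = rng.integers(0, n_modules, size=m)
    W = rng.normal(0.0, 0.1, size=(m, n_modules))
    W[np.arange(m), primary] = 1.0 + rng.normal(0.0, 0.2, size=m)
    bias = rng.normal(0.0, 0.3, size=m)
    gene_ids = [f"g{i:04d}" for i in range(m)]

    n_target_modules = min(n_target_modules, n_modules)
    target_modules = rng.choice(n_modules, size=n_target_modules, replace=False)
    shifts: dict[str, tuple[np.ndarray, float]] = {}
    i_pert = 0
    while len(shifts) < n_perturbations:
        module = int(target_modules[i_pert % n_target_modules])
        candidates = np.flatnonzero(primary == module)
        candidates = [int(g) for g in candidates if gene_ids[g] not in shifts]
        if not candidates:
            i_pert += 1
            continue
        gene = int(rng.choice(candidates))
        direction = np.zeros(n_modules)
        direction[module] = -1.0
        if i_pert % 2 == 1:  # every other perturbation is 2-sparse
            secondary = int(target_modules[(i_pert + 1) % n_target_modules])
            if secondary != module:
                direction[secondary] = -0.5
        c = float(penetrance_choices[i_pert % len(penetrance_choices)])
        shifts[gene_ids[gene]] = (direction, c)
        i_pert += 1
    return GroundTruthModel(A=A, readout_weights=W, readout_bias=bias,
                            noise_sd=noise_sd, gene_ids=gene_ids, shifts=shifts,
                            seed=seed)


def _simulate_condition(gt: GroundTruthModel, shift: np.ndarray, n_cells: int,
                        rng: np.random.Generator) -> np.ndarray:
    Z = rng.standard_normal((n_cells, gt.n_modules))
    B = gt.solve_matrix()
    U = (Z + shift) @ B.T
    X = U @ gt.readout_weights.T + gt.readout_bias
    if gt.noise_sd > 0:
        X = X + gt.noise_sd * rng.standard_normal(X.shape)
    return X


def _condition_rng(gt: GroundTruthModel, condition: str, seed: int | None
                   ) -> np.random.Generator:
    import zlib
    base = gt.seed if seed is None else seed
    # independent stream per condition, stable across processes
    key = zlib.crc32(str(condition).encode()) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence((base, key)))


def simulate_dataset(gt: GroundTruthModel, cells_per_condition: int = 300,
                     seed: int | None = None) -> ExpressionDataset:
    """Simulate control cells plus every perturbation's cells.

    Each condition draws its own exogenous noise; perturbed cells solve
    U = (I - A)^-1 (Z + c*s) and controls use a zero shift, then the linear
    read-out plus Gaussian observation noise produces expression.
    """
    if cells_per_condition < 1:
        raise ValueError("cells_per_condition must be >= 1")
    blocks, labels = [], []
    for condition in [gt.control_token, *gt.perturbations]:
        if condition == gt.control_token:
            shift = np.zeros(gt.n_modules)
        else:
            direction, c = gt.shifts[condition]
            shift = c * np.asarray(direction, dtype=float)
        rng = _condition_rng(gt, condition, seed)
        blocks.append(_simulate_condition(gt, shift, cells_per_condition, rng))
        labels.extend([condition] * cells_per_condition)
    return ExpressionDataset(matrix=np.vstack(blocks), gene_ids=list(gt.gene_ids),
                             perturbations=np.array(labels, dtype=object),
                             control_token=gt.control_token)


def simulate_pseudobulk(gt: GroundTruthModel, perturbation: str,
                        n_cells: int = 300, seed: int | None = None) -> np.ndarray:
    """Per-gene mean expression over ``n_cells`` simulated cells of a condition.

    Uses the same per-condition random stream as :func:`simulate_dataset`, so
    with matching seeds the control pseudo-bulk equals the mean of the control
    cells of the simulated dataset.
    """
    if perturbation != gt.control_token and perturbation not in gt.shifts:
        raise KeyError(f"unknown perturbation {perturbation!r}")
    if perturbation == gt.control_token:
        shift = np.zeros(gt.n_modules)
    else:
        direction, c = gt.shifts[perturbation]
        shift = c * np.asarray(direction, dtype=float)
    rng = _condition_rng(gt, perturbation, seed)
    return _simulate_condition(gt, shift, n_cells, rng).mean(axis=0)


def save_ground_truth(gt: GroundTruthModel, path: str) -> None:
    """JSON sidecar recording the true graph, read-out, shifts and penetrances."""
    payload = {
        "A": gt.A.tolist(),
        "readout_weights": gt.readout_weights.tolist(),
        "readout_bias": gt.readout_bias.tolist(),
        "noise_sd": gt.noise_sd,
        "gene_ids": gt.gene_ids,
        "shifts": {p: {"direction": np.asarray(d).tolist(), "penetrance": c}
                   for p, (d, c) in gt.shifts.items()},
        "seed": gt.seed,
        "control_token": gt.control_token,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ground_truth(path: str) -> GroundTruthModel:
    with open(path) as fh:
        payload = json.load(fh)
    shifts = {p: (np.asarray(v["direction"], dtype=float), float(v["penetrance"]))
              for p, v in payload["shifts"].items()}
    return GroundTruthModel(
        A=np.asarray(payload["A"], dtype=float),
        readout_weights=np.asarray(payload["readout_weights"], dtype=float),
        readout_bias=np.asarray(payload["readout_bias"], dtype=float),
        noise_sd=float(payload["noise_sd"]), gene_ids=list(payload["gene_ids"]),
        shifts=shifts, seed=int(payload["seed"]),
        control_token=payload.get("control_token", CONTROL))
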