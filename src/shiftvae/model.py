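"""Hybrid causal variational autoencoder for perturbation response prediction.

Four components: an expression encoder mapping a control cell X in R^m to a
diagonal-Gaussian posterior over exogenous module noise Z in R^n (n < m); a
shift encoder mapping a perturbation's gene label (PCA scores of the target
gene over control cells) to a latent shift vector S in R^n; the linear SCM
solving U = (I - A)^-1 (Z + c*S); and an expression decoder mapping U back to
expression space. A perturbation's effect is the shift c_p * S^p propagated
through the learned regulatory graph; controls use a zero shift.

Training minimises

    L = E_p E_cells ||X^p - Xhat^p||^2  +  beta * KL(q(Z|X) || N(0, I))
        + gamma * E_{p != control} MMD(X^p, Xhat^p)

where the reconstruction term is the per-gene mean squared error averaged over
all conditions (control included), the KL term runs over control cells only,
and the MMD term over non-control conditions only. Since Perturb-seq offers no natural pairing between a perturbed cell and
a control cell, each perturbed cell is paired with a uniformly resampled
control cell per batch; the MMD term supplies the distribution-level match.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import MLP, Linear, Parameter, Tensor
from .data import CONTROL, PerturbationFeatures
from .metrics import median_bandwidth
from .scm import GraphSpec, ScmParameters, build_graph, solve_scm

__all__ = ["PosteriorParams", "ShiftTable", "LossConfig", "LossBreakdown",
           "PerturbationVAE", "gaussian_kl", "pairwise_sq_dists", "mmd_squared_loss"]


@dataclass
class PosteriorParams:
    """Diagonal Gaussian q(Z | X); the prior is fixed at N(0, I_n)."""

    mean: Tensor
    log_var: Tensor

    @property
    def n(self) -> int:
        return self.mean.shape[1]


def gaussian_kl(post: PosteriorParams) -> Tensor:
    """Mean over cells of KL(q(Z|X) || N(0, I)) in closed form."""
    lv, mu = post.log_var, post.mean
    per_cell = 0.5 * (lv.exp() + mu ** 2 - 1.0 - lv).sum(axis=1)
    return per_cell.mean()


class ShiftTable:
    """Per-perturbation gene label and learnable scalar penetrance c_p.

    The control condition's shift is identically zero (the observational model
    is the shift model with S = 0). Entries for unseen perturbations can be
    added after shift selection via :meth:`set_unseen`.
    """

    def __init__(self, features: PerturbationFeatures, perturbations: list[str],
                 control_token: str = CONTROL):
        self.features = features
        self.control_token = control_token
        self.c: dict[str, Parameter] = {
            p: Parameter(np.array(1.0)) for p in sorted(perturbations)}
        self._unseen_c: dict[str, float] = {}

    @property
    def seen(self) -> list[str]:
        return list(self.c)

    def label(self, perturbation: str) -> np.ndarray:
        return self.features.label_for(perturbation)

    def penetrance(self, perturbation: str):
        if perturbation in self.c:
            return self.c[perturbation]
        if perturbation in self._unseen_c:
            return Tensor(np.array(self._unseen_c[perturbation]))
        raise KeyError(
            f"perturbation {perturbation!r} has no penetrance entry; for unseen "
            "targets select c with shiftvae.shift_selection.select_shift")

    def set_unseen(self, perturbation: str, c: float) -> None:
        self._unseen_c[perturbation] = float(c)

    def penetrance_or_default(self, perturbation: str, default: float = 1.0):
        """Penetrance if known, else unit penetrance (direction-only views)."""
        try:
            return self.penetrance(perturbation)
        except KeyError:
            return Tensor(np.array(float(default)))

    def learned_penetrances(self) -> dict[str, float]:
        return {p: float(t.data) for p, t in self.c.items()}

    def parameters(self) -> list[Parameter]:
        return [self.c[p] for p in sorted(self.c)]


@dataclass
class LossConfig:
    beta: float = 0.01
    gamma: float = 50.0
    kernel: str = "rbf"
    bandwidth: float | None = None  # None: median heuristic per batch


@dataclass
class LossBreakdown:
    reconstruction: float
    kl: float
    mmd: float
    beta: float
    gamma: float
    total: float

    def check(self) -> bool:
        return self.total == self.reconstruction + self.beta * self.kl \
            + self.gamma * self.mmd


def pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable pairwise squared Euclidean distances."""
    a2 = (a * a).sum(axis=1, keepdims=True)       # (Na, 1)
    b2 = (b * b).sum(axis=1, keepdims=True)       # (Nb, 1)
    return a2 + b2.T - 2.0 * (a @ b.T)


def mmd_squared_loss(target: np.ndarray, pred: Tensor,
                     bandwidth: float | None = None) -> Tensor:
    """Differentiable biased V-statistic of squared MMD (RBF kernel).

    ``target`` is observed data (constant); ``pred`` carries gradients. The
    bandwidth defaults to the median pooled pairwise distance of the current
    values (treated as a constant, the standard practice for MMD penalties).
    """
    t = Tensor(np.asarray(target, dtype=float))
    if bandwidth is None:
        bandwidth = median_bandwidth(np.vstack([t.data, pred.data]))
    gamma = 1.0 / (2.0 * bandwidth ** 2)
    k_tt = (-gamma * pairwise_sq_dists(t, t)).exp().mean()
    k_pp = (-gamma * pairwise_sq_dists(pred, pred)).exp().mean()
    k_tp = (-gamma * pairwise_sq_dists(t, pred)).exp().mean()
    return k_tt + k_pp - 2.0 * k_tp


class _Encoder:
    """MLP trunk with separate linear heads for posterior mean and log-variance."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        dims = [n_in, *hidden]
        self.trunk = [Linear(dims[i], dims[i + 1], rng)
                      for i in range(len(dims) - 1)]
        self.head_mean = Linear(dims[-1], n_out, rng)
        self.head_log_var = Linear(dims[-1], n_out, rng)

    def __call__(self, x: Tensor) -> PosteriorParams:
        for layer in self.trunk:
            x = layer(x).relu()
        return PosteriorParams(mean=self.head_mean(x),
                               log_var=self.head_log_var(x))

    def parameters(self) -> list[Parameter]:
        params = [p for layer in self.trunk for p in layer.parameters()]
        return params + self.head_mean.parameters() + self.head_log_var.parameters()


class PerturbationVAE:
    """Expression encoder + shift encoder + linear SCM + expression decoder."""

    def __init__(self, n_genes: int, n_latent: int, feature_dim: int,
                 graph: GraphSpec | ScmParameters,
                 hidden: tuple[int, ...] = (1024, 1024),
                 shift_hidden: tuple[int, ...] = (256, 256),
                 seed: int = 0, control_token: str = CONTROL):
        if not n_latent < n_genes:
            raise ValueError("the latent module dimension n must satisfy n < m")
        self.m = n_genes
        self.n = n_latent
        self.k = feature_dim
        self.hidden = tuple(hidden)
        self.shift_hidden = tuple(shift_hidden)
        self.seed = seed
        self.control_token = control_token
        ss = np.random.SeedSequence(seed).spawn(3)
        self.encoder = _Encoder(n_genes, self.hidden, n_latent,
                                np.random.default_rng(ss[0]))
        self.shift_encoder = MLP(feature_dim, list(self.shift_hidden), n_latent,
                                 np.random.default_rng(ss[1]))
        self.decoder = MLP(n_latent, list(self.hidden), n_genes,
                           np.random.default_rng(ss[2]))
        self.graph_spec = graph if isinstance(graph, GraphSpec) else None
        self.scm = build_graph(graph) if isinstance(graph, GraphSpec) else graph
        if self.scm.n != n_latent:
            raise ValueError("graph dimension must equal n_latent")
        self.shift_table: ShiftTable | None = None

    # -- wiring ----------------------------------------------------------------
    def register_perturbations(self, features: PerturbationFeatures,
                               perturbations: list[str]) -> None:
        if features.k != self.k:
            raise ValueError(f"feature dimension {features.k} != model k={self.k}")
        self.shift_table = ShiftTable(features, perturbations, self.control_token)

    def parameters(self) -> list[Parameter]:
        params = (self.encoder.parameters() + self.shift_encoder.parameters()
                  + self.decoder.parameters() + self.scm.parameters())
        if self.shift_table is not None:
            params += self.shift_table.parameters()
        return params

    def project_masks(self) -> None:
        self.scm.project()

    # -- components ------------------------------------------------------------
    def encode_expression(self, X) -> PosteriorParams:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.m:
            raise ValueError(f"expected {self.m} genes, got {X.shape[1]}")
        return self.encoder(Tensor(X))

    def sample_latent(self, post: PosteriorParams,
                      rng: np.random.Generator | int | None = None) -> Tensor:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        eps = rng.standard_normal(post.mean.shape)
        return post.mean + (0.5 * post.log_var).exp() * Tensor(eps)

    def encode_shift(self, label: np.ndarray) -> Tensor:
        label = np.asarray(label, dtype=float).reshape(1, -1)
        if label.shape[1] != self.k:
            raise ValueError(f"label length {label.shape[1]} != k={self.k}")
        return self.shift_encoder(Tensor(label))

    def decode(self, U) -> Tensor:
        U = U if isinstance(U, Tensor) else Tensor(np.atleast_2d(U))
        if U.shape[1] != self.n:
            raise ValueError(f"expected latent dimension {self.n}")
        return self.decoder(U)

    def shift_for(self, perturbation: str | None, c: float | None = None,
                  label: np.ndarray | None = None) -> Tensor:
        """Scaled latent shift c * S for a condition (zero for control)."""
        if perturbation in (None, self.control_token) and label is None:
            return Tensor(np.zeros((1, self.n)))
        if label is None:
            if self.shift_table is None:
                raise RuntimeError("no perturbations registered on this model")
            label = self.shift_table.label(perturbation)
            c_t = self.shift_table.penetrance(perturbation) if c is None \
                else Tensor(np.array(float(c)))
        else:
            c_t = Tensor(np.array(1.0 if c is None else float(c)))
        return c_t * self.encode_shift(label)

    # -- prediction ------------------------------------------------------------
    def forward(self, X_control, perturbation: str | None = None,
                c: float | None = None, label: np.ndarray | None = None,
                variant: str | None = None, use_mean: bool = False,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Predicted expression for cells under a perturbation (or control).

        Encodes control cells, samples Z (or uses the posterior mean when
        ``use_mean``), applies the scaled latent shift through the SCM
        (``variant='conditional'`` bypasses the graph: U = Z + c*S) and
        decodes. Returns a cells x genes array.
        """
        post = self.encode_expression(X_control)
        Z = post.mean if use_mean else self.sample_latent(post, rng)
        shift = self.shift_for(perturbation, c=c, label=label)
        if variant == "conditional":
            U = Z + shift
        else:
            U = solve_scm(self.scm, Z, shift)
        return self.decode(U).numpy()

    # -- loss --------------------------------------------------------------
    def compute_loss(self, control_X: np.ndarray,
                     perturbed_X: dict[str, np.ndarray], cfg: LossConfig,
                     rng: np.random.Generator | int | None = None,
                     label_noise: float = 0.0,
                     ) -> tuple[Tensor, LossBreakdown]:
        """Training loss on one batch; returns (differentiable total, breakdown).

        KL uses only the control cells; MMD only the non-control conditions;
        the reconstruction term averages over all conditions including control.
        """
        control_X = np.atleast_2d(np.asarray(control_X, dtype=float))
        if control_X.shape[0] < 1:
            raise ValueError("at least one control cell is required")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

        post = self.encode_expression(control_X)
        kl = gaussian_kl(post)
        Z = self.sample_latent(post, rng)
        U = solve_scm(self.scm, Z, Tensor(np.zeros((1, self.n))))
        Xhat = self.decode(U)
        diff = Xhat - Tensor(control_X)
        recon_terms = [(diff * diff).mean()]

        mmd_terms = []
        for p in sorted(perturbed_X):
            Xp = np.atleast_2d(np.asarray(perturbed_X[p], dtype=float))
            idx = rng.integers(0, control_X.shape[0], size=Xp.shape[0])
            post_p = self.encode_expression(control_X[idx])
            Zp = self.sample_latent(post_p, rng)
            if label_noise > 0:
                # jitter the gene label (scaled per feature dimension) so the
                # shift encoder learns a smooth map that generalises to the
                # labels of unseen target genes
                label = self.shift_table.label(p)
                scale = self.shift_table.features.feature_matrix.std(axis=0)
                label = label + label_noise * scale * rng.standard_normal(self.k)
                shift = self.shift_table.penetrance(p) * self.encode_shift(label)
            else:
                shift = self.shift_for(p)
            Up = solve_scm(self.scm, Zp, shift)
            Xhat_p = self.decode(Up)
            diff_p = Xhat_p - Tensor(Xp)
            recon_terms.append((diff_p * diff_p).mean())
            if Xp.shape[0] >= 2:
                mmd_terms.append(mmd_squared_loss(Xp, Xhat_p, cfg.bandwidth))
            else:
                warnings.warn(f"perturbation {p!r} has < 2 cells in the batch; "
                              "its MMD term is skipped")

        recon = recon_terms[0]
        for term in recon_terms[1:]:
            recon = recon + term
        recon = recon * (1.0 / len(recon_terms))
        if mmd_terms:
            mmd_t = mmd_terms[0]
            for term in mmd_terms[1:]:
                mmd_t = mmd_t + term
            mmd_t = mmd_t * (1.0 / len(mmd_terms))
        else:
            mmd_t = Tensor(np.array(0.0))
        total = recon + cfg.beta * kl + cfg.gamma * mmd_t
        breakdown = LossBreakdown(
            reconstruction=float(recon.data), kl=float(kl.data),
            mmd=float(mmd_t.data), beta=cfg.beta, gamma=cfg.gamma,
            total=float(recon.data) + cfg.beta * float(kl.data)
                  + cfg.gamma * float(mmd_t.data))
        return total, breakdown

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["scm_A"] = self.scm.A.data
        arrays["scm_mask"] = self.scm.mask
        if self.shift_table is not None:
            arrays["features"] = self.shift_table.features.feature_matrix
        return arrays

    def save(self, path: str) -> None:
        meta = {
            "schema": 1, "m": self.m, "n": self.n, "k": self.k,
            "hidden": list(self.hidden), "shift_hidden": list(self.shift_hidden),
            "seed": self.seed, "control_token": self.control_token,
            "graph_mode": self.graph_spec.mode if self.graph_spec else "fixed_adjacency",
            "scm_trainable": self.scm.trainable,
            "perturbations": self.shift_table.seen if self.shift_table else [],
            "unseen_c": self.shift_table._unseen_c if self.shift_table else {},
            "feature_gene_ids": (self.shift_table.features.gene_ids
                                 if self.shift_table else []),
            "n_control_cells": (self.shift_table.features.n_control_cells
                                if self.shift_table else 0),
        }
        np.savez(path, meta=np.array(json.dumps(meta)), **self.state_arrays())

    @classmethod
    def load(cls, path: str) -> "PerturbationVAE":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            arrays = {key: archive[key] for key in archive.files if key != "meta"}
        scm = ScmParameters(mask=arrays["scm_mask"], A=Parameter(arrays["scm_A"]),
                            trainable=bool(meta["scm_trainable"]))
        model = cls(n_genes=meta["m"], n_latent=meta["n"], feature_dim=meta["k"],
                    graph=scm, hidden=tuple(meta["hidden"]),
                    shift_hidden=tuple(meta["shift_hidden"]), seed=meta["seed"],
                    control_token=meta["control_token"])
        if meta["perturbations"]:
            features = PerturbationFeatures(
                feature_matrix=arrays["features"],
                gene_ids=list(meta["feature_gene_ids"]), k=meta["k"],
                n_control_cells=int(meta["n_control_cells"]))
            model.register_perturbations(features, meta["perturbations"])
            for p, c in meta["unseen_c"].items():
                model.shift_table.set_unseen(p, c)
        for i, p in enumerate(model.parameters()):
            p.data[...] = arrays[f"param_{i}"]
        return model
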