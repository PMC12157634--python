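"""Linear structural causal model over latent gene modules.

The latent state of a cell is a vector of n gene-module activities U driven by
exogenous noise Z and, under a perturbation, an additive shift c*S propagated
through a directed acyclic regulatory graph:

    U = A U + Z + c*S          =>          U = (I - A)^-1 (Z + c*S)

with unit exogenous noise scale (the module scale is arbitrary, so sigma_i = 1
by convention). ``A[i, j]`` is the regulatory weight of module j on module i
and is nonzero only where the graph mask allows an edge j -> i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Parameter, Tensor

GRAPH_MODES = ("learned_full_triangular", "fixed_adjacency", "random_dag",
               "none_conditional")

__all__ = ["GraphSpec", "ScmParameters", "build_graph", "solve_scm",
           "topological_order", "GRAPH_MODES"]


@dataclass
class GraphSpec:
    """Choice of regulatory-graph structure for the latent SCM.

    mode
        ``learned_full_triangular``: all strictly-upper-triangular weights are
        trainable (a learned DAG without sparsity restriction).
        ``fixed_adjacency``: trainable weights only on a user-supplied acyclic
        mask.
        ``random_dag``: a seeded random acyclic mask, then as ``fixed_adjacency``.
        ``none_conditional``: no regulation; A is frozen at zero and the decoder
        effectively receives Z + c*S directly (conditional-VAE ablation).
    """

    mode: str
    n: int
    mask: np.ndarray | None = None
    density: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in GRAPH_MODES:
            raise ValueError(f"unknown graph mode {self.mode!r}; "
                             f"choose from {GRAPH_MODES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mode == "fixed_adjacency":
            if self.mask is None:
                raise ValueError("fixed_adjacency requires a mask")
            self.mask = np.asarray(self.mask, dtype=float)
            if self.mask.shape != (self.n, self.n):
                raise ValueError("mask must be n x n")


def topological_order(mask: np.ndarray) -> np.ndarray:
    """Topological order of the graph encoded by ``mask`` (mask[i,j]=1 iff j->i).

    Raises ``ValueError`` if the graph has a cycle or a self-loop.
    """
    mask = np.asarray(mask)
    n = mask.shape[0]
    if np.any(np.diag(mask) != 0):
        raise ValueError("graph mask has a nonzero diagonal (self-loop)")
    indeg = (mask != 0).sum(axis=1)  # number of parents of each node
    order: list[int] = []
    ready = sorted(np.flatnonzero(indeg == 0).tolist())
    remaining = mask != 0
    while ready:
        v = ready.pop(0)
        order.append(v)
        children = np.flatnonzero(remaining[:, v])
        remaining[:, v] = False
        for c in children:
            if not remaining[c].any():
                ready.append(int(c))
        ready.sort()
    if len(order) != n:
        raise ValueError("graph mask contains a cycle; the SCM solve would be "
                         "singular — supply an acyclic adjacency")
    return np.asarray(order)


@dataclass
class ScmParameters:
    """Masked weight matrix A of the linear SCM plus the (unit) noise scale."""

    mask: np.ndarray
    A: Parameter
    sigma: np.ndarray = field(default=None)  # type: ignore[assignment]
    trainable: bool = True

    def __post_init__(self):
        if self.sigma is None:
            self.sigma = np.ones(self.mask.shape[0])
        self.project()

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    def project(self) -> None:
        """Zero out off-pattern entries of A (run after every optimizer step)."""
        self.A.data *= self.mask

    def parameters(self) -> list[Parameter]:
        return [self.A] if self.trainable and self.mask.any() else []


def build_graph(spec: GraphSpec, init_scale: float = 0.01) -> ScmParameters:
    """Initialise SCM parameters for a graph specification.

    Weights on free entries start at N(0, init_scale^2): near the conditional
    (no-regulation) model, letting regulation emerge during training.
    """
    n = spec.n
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "learned_full_triangular":
        mask = np.triu(np.ones((n, n)), k=1)
    elif spec.mode == "fixed_adjacency":
        mask = (np.asarray(spec.mask) != 0).astype(float)
        topological_order(mask)  # raises on cycles / self-loops
    elif spec.mode == "random_dag":
        upper = np.triu(rng.random((n, n)) < spec.density, k=1).astype(float)
        perm = rng.permutation(n)
        mask = upper[np.ix_(perm, perm)]  # permutation-triangular, still a DAG
    else:  # none_conditional
        mask = np.zeros((n, n))
    A = Parameter(rng.normal(0.0, init_scale, size=(n, n)) * mask)
    trainable = spec.mode != "none_conditional"
    return ScmParameters(mask=mask, A=A, trainable=trainable)


def _solve_matrix(A: np.ndarray) -> np.ndarray:
    """(I - A)^-1 with a guard against (near-)singular systems."""
    n = A.shape[0]
    ImA = np.eye(n) - A
    try:
        B = np.linalg.inv(ImA)
    except np.linalg.LinAlgError as err:
        raise ValueError("(I - A) is singular; the adjacency is likely cyclic "
                         "— shift-intervention SCMs here require a DAG") from err
    if not np.all(np.isfinite(B)):
        raise ValueError("(I - A) is numerically singular (cyclic adjacency?)")
    return B


def solve_scm(params: ScmParameters, Z, shift):
    """Solve U = A U + Z + shift for a batch of cells (rows).

    Accepts numpy arrays or autodiff Tensors; with Tensor inputs (or a
    trainable A) the result is differentiable with respect to A, Z and shift.
    Row-vector convention: U = (Z + shift) @ (I - A)^-T.
    """
    is_tensor = isinstance(Z, Tensor) or isinstance(shift, Tensor)
    A = params.A
    B = _solve_matrix(A.data)
    if not is_tensor:
        Z = np.asarray(Z, dtype=float)
        shift = np.asarray(shift, dtype=float)
        return (Z + shift) @ B.T

    rhs = (Z if isinstance(Z, Tensor) else Tensor(Z)) + \
          (shift if isinstance(shift, Tensor) else Tensor(shift))

    out_data = rhs.data @ B.T

    def bwd(g):
        # U = RHS B^T with B = (I-A)^-1:
        #   dL/dRHS = g B ;   dL/dA = B^T g^T U  (adjoint of d(I-A)^-1)
        gA = (B.T @ g.T @ out_data) * params.mask
        return ((rhs, g @ B), (A, gA))

    return Tensor(out_data, parents=(rhs, A), backward=bwd)
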