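"""Semi-supervised non-negative matrix tri-factorization (SSNMTF).

The model approximates a symmetric PPI adjacency matrix ``A`` (n x n) by a
tri-factorization ``A ~ F G F'`` with ``F >= 0`` an n x k node-to-module
membership matrix and ``G >= 0`` a k x k module-relationship matrix.  Prior
knowledge that certain node pairs co-occur in a complex enters through the
must-link Laplacian ``L = D - M`` (see :mod:`ssnmtf.constraints`), giving
the objective

    J(F, G) = ||A - F G F'||_F^2  +  Tr((F G)' L (F G))  +  Tr(F' L F)

The first penalty pulls the *reconstructed* propensities ``R = F G`` of
constrained pairs together — this is what yields a diagonally dominant G
and hence a clear module structure; the second pulls the raw membership
rows together.  J is minimized by alternating multiplicative updates

    F <- F * [2 A F G + M F (G G + I)] / [2 F G F' F G + D F (G G + I)]
    G <- G * [F' A F + G F' M F]       / [F' F G F' F + G F' D F]

which preserve non-negativity and decrease J to a local minimum.  The
update numerators/denominators and the gradients used for KKT diagnostics
are implemented exactly in this printed form.  (Differentiating the
penalty terms directly gives gradients 2 L F G G and 2 L F; the printed
form drops that factor of 2.  Both share the same fixed points, and the
updates here follow the printed form.)

Usage follows the statsmodels convention::

    model = SSNMTF(network, constraints, k=45, alpha=10.0)
    res = model.fit(seed=0)
    print(res.summary())
    cover = res.complexes(overlap=True)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .constraints import ConstraintMatrices, MustLinkConstraints, build_matrices
from .io import ComplexCover, Network

logger = logging.getLogger(__name__)

__all__ = [
    "SSNMTF",
    "SSNMTFResults",
    "FactorPair",
    "objective",
    "update_f",
    "update_g",
    "initialize_factors",
    "select_seeds",
]


class NumericalError(RuntimeError):
    """Raised when the optimizer produces non-finite values."""


@dataclass
class FactorPair:
    """The two factor matrices: membership ``F`` (n x k) and module
    relationship ``G`` (k x k), both non-negative."""

    F: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.F.ndim != 2 or self.G.ndim != 2:
            raise ValueError("F and G must be 2-D")
        k = self.F.shape[1]
        if self.G.shape != (k, k):
            raise ValueError(f"G shape {self.G.shape} incompatible with F {self.F.shape}")
        if (self.F < 0).any() or (self.G < 0).any():
            raise ValueError("factors must be non-negative")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def k(self) -> int:
        return self.F.shape[1]


def _as_csr(a) -> sp.csr_matrix:
    if sp.issparse(a):
        return a.tocsr()
    return sp.csr_matrix(np.asarray(a, dtype=float))


def objective(A, factors: FactorPair, cm: ConstraintMatrices | None = None) -> float:
    """Evaluate J(F, G) = ||A - FGF'||^2_F + Tr((FG)'L(FG)) + Tr(F'LF).

    ``A`` may be dense or sparse; the reconstruction term is evaluated via
    its trace expansion so the dense n x n residual is never formed.
    """
    A = _as_csr(A)
    F, G = factors.F, factors.G
    if A.shape[0] != F.shape[0]:
        raise ValueError("A and F have incompatible shapes")
    normA2 = float((A.data**2).sum())
    AF = A @ F
    S = F.T @ AF                       # F' A F, k x k
    X = F.T @ F
    cross = float(np.trace(S @ G))     # <A, FGF'>
    recon2 = float(np.trace(G.T @ X @ G @ X))  # ||FGF'||^2_F
    j = normA2 - 2.0 * cross + recon2
    if cm is not None and cm.L.nnz:
        R = F @ G
        j += float(np.sum(R * (cm.L @ R)))
        j += float(np.sum(F * (cm.L @ F)))
    # tiny negative values can arise from cancellation at near-exact fits
    return max(j, 0.0)


def update_f(
    A,
    factors: FactorPair,
    cm: ConstraintMatrices | None = None,
    denom_floor: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of F with G held fixed."""
    A = _as_csr(A)
    F, G = factors.F, factors.G
    GGI = G @ G + np.eye(factors.k)
    num = 2.0 * (A @ (F @ G))
    den = 2.0 * (F @ (G @ (F.T @ F) @ G))
    if cm is not None and cm.M.nnz:
        FG2 = F @ GGI
        num = num + cm.M @ FG2
        den = den + cm.D @ FG2
    return _mult_step(F, num, den, denom_floor)


def update_g(
    A,
    factors: FactorPair,
    cm: ConstraintMatrices | None = None,
    denom_floor: float = 1e-12,
    symmetrize: bool = False,
) -> np.ndarray:
    """One multiplicative update of G with F held fixed.

    With ``symmetrize`` the result is replaced by ``(G + G') / 2``; the raw
    update does not structurally preserve the symmetry that G is meant to
    have, and the F-update assumes a symmetric G.
    """
    A = _as_csr(A)
    F, G = factors.F, factors.G
    X = F.T @ F
    num = F.T @ (A @ F)
    den = X @ G @ X
    if cm is not None and cm.M.nnz:
        num = num + G @ (F.T @ (cm.M @ F))
        den = den + G @ (F.T @ (cm.D @ F))
    G_new = _mult_step(G, num, den, denom_floor)
    if symmetrize:
        G_new = 0.5 * (G_new + G_new.T)
    return G_new


def _mult_step(W: np.ndarray, num: np.ndarray, den: np.ndarray, floor: float) -> np.ndarray:
    """W * num / den with a floored denominator; 0/0 entries keep W."""
    num = np.asarray(num)
    den = np.asarray(den)
    if not (np.isfinite(num).all() and np.isfinite(den).all()):
        raise NumericalError("non-finite values in multiplicative update")
    ratio = num / np.maximum(den, floor)
    out = W * ratio
    both_zero = (num == 0) & (den == 0)
    if both_zero.any():
        out[both_zero] = W[both_zero]
    return out


def gradients(
    A, factors: FactorPair, cm: ConstraintMatrices | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of J wrt F and G in the same form the updates are derived
    from (Lagrange multipliers dropped):

        dJ/dF = 2 F G F' F G - 2 A F G + L F G G + L F
        dJ/dG = F' F G F' F - F' A F + G F' L F
    """
    A = _as_csr(A)
    F, G = factors.F, factors.G
    X = F.T @ F
    gF = 2.0 * (F @ (G @ X @ G)) - 2.0 * (A @ (F @ G))
    gG = X @ G @ X - F.T @ (A @ F)
    if cm is not None and cm.L.nnz:
        LF = cm.L @ F
        gF = gF + LF @ (G @ G) + LF
        gG = gG + G @ (F.T @ LF)
    return gF, gG


def select_seeds(net: Network, k: int) -> list[int]:
    """Pick k well-separated, high-degree seed nodes.

    Greedy heuristic: take the highest-degree node first, then repeatedly
    take the highest-degree node at shortest-path distance >= 2 from every
    chosen seed (i.e. not adjacent to any); when no such node remains, fall
    back to the highest-degree unchosen node.
    """
    n = net.n_nodes
    if k > n:
        raise ValueError(f"k={k} exceeds the number of nodes n={n}")
    deg = net.degrees()
    order = np.lexsort((np.arange(n), -deg))  # by degree desc, index asc
    chosen: list[int] = []
    blocked = np.zeros(n, dtype=bool)
    taken = np.zeros(n, dtype=bool)
    for _ in range(k):
        pick = -1
        for i in order:
            if not taken[i] and not blocked[i]:
                pick = int(i)
                break
        if pick < 0:  # everything unchosen is adjacent to a seed
            for i in order:
                if not taken[i]:
                    pick = int(i)
                    break
        chosen.append(pick)
        taken[pick] = True
        blocked[pick] = True
        blocked[net.adjacency[pick] > 0] = True
    return chosen


def initialize_factors(
    net: Network,
    k: int,
    mode: Literal["seeded", "random"] = "seeded",
    rng_seed: int = 0,
    g_noise: float | None = None,
    f_floor: float = 1e-6,
) -> FactorPair:
    """Initial F and G.

    F: in ``seeded`` mode, soft assignment of every node to k seed nodes —
    ``f_ic`` proportional to 1 + (cosine similarity of adjacency rows of
    node i and seed c) + (1 if i is wired to seed c), row-normalized, then
    floored at ``f_floor`` so no entry is exactly zero (multiplicative
    updates cannot revive zeros).  In ``random`` mode, iid uniform(0, 1).

    G: every row sums to exactly one with all entries strictly positive and
    close to 1/k — entries are 1/k plus uniform(0, g_noise) jitter before
    exact row renormalization.  The jitter (default 0.1/k) must be large
    enough to break the symmetry between modules.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > net.n_nodes:
        raise ValueError(f"k={k} exceeds the number of nodes n={net.n_nodes}")
    rng = np.random.default_rng(rng_seed)
    n = net.n_nodes
    if mode == "random":
        F = rng.uniform(size=(n, k))
    elif mode == "seeded":
        seeds = select_seeds(net, k)
        A = net.adjacency
        norms = np.sqrt((A**2).sum(axis=1))
        C = A @ A[:, seeds]                      # weighted common neighbours
        denom = np.outer(norms, norms[seeds])
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, C / denom, 0.0)
        direct = (A[:, seeds] > 0).astype(float)
        F = 1.0 + cos + direct
        F /= F.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    F = np.maximum(F, f_floor)

    if g_noise is None:
        g_noise = 0.1 / k
    G = 1.0 / k + rng.uniform(0.0, g_noise, size=(k, k))
    G /= G.sum(axis=1, keepdims=True)
    return FactorPair(F=F, G=G)


class SSNMTF:
    """Semi-supervised NMTF model bound to a network and its constraints.

    Parameters
    ----------
    network : Network
        The interaction network; its adjacency provides the data matrix A.
    constraints : MustLinkConstraints or ConstraintMatrices, optional
        Must-link prior.  ``None`` gives the unconstrained NMTF model.
    k : int
        Module budget — number of columns of F.  Set generously; modules
        that attract no node are pruned at detection time, so k acts as an
        upper bound that is adapted downward automatically.
    symmetrize_g : bool
        Re-symmetrize G after every update (default True).
    denom_floor : float
        Lower floor applied to update denominators before division.
    """

    def __init__(
        self,
        network: Network,
        constraints: MustLinkConstraints | ConstraintMatrices | None = None,
        k: int = 1000,
        symmetrize_g: bool = True,
        denom_floor: float = 1e-12,
    ) -> None:
        self.network = network
        self.k = int(k)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k > network.n_nodes:
            raise ValueError(
                f"k={self.k} exceeds the number of nodes n={network.n_nodes}"
            )
        self.symmetrize_g = symmetrize_g
        self.denom_floor = denom_floor
        if constraints is None:
            cm = ConstraintMatrices.empty(network.n_nodes)
            self.alpha = 0.0
        elif isinstance(constraints, MustLinkConstraints):
            cm = build_matrices(constraints, network, strict=False)
            self.alpha = constraints.alpha
        else:
            cm = constraints
            self.alpha = float(cm.M.max()) if cm.M.nnz else 0.0
        self.constraint_matrices = cm
        self._A = _as_csr(network.adjacency)

    # -- paper-facing primitives, bound to this model's data ---------------

    def objective(self, factors: FactorPair) -> float:
        return objective(self._A, factors, self.constraint_matrices)

    def gradients(self, factors: FactorPair) -> tuple[np.ndarray, np.ndarray]:
        return gradients(self._A, factors, self.constraint_matrices)

    def initialize(
        self, mode: Literal["seeded", "random"] = "seeded", rng_seed: int = 0
    ) -> FactorPair:
        return initialize_factors(self.network, self.k, mode=mode, rng_seed=rng_seed)

    # ----------------------------------------------------------------------

    def fit(
        self,
        max_iter: int = 1000,
        rel_tol: float = 1e-9,
        init: Literal["seeded", "random"] = "seeded",
        seed: int = 0,
        start: FactorPair | None = None,
        paper_strict: bool = False,
    ) -> "SSNMTFResults":
        """Run the alternating multiplicative-update loop.

        Each iteration updates F (G fixed) then G (F fixed) and evaluates
        J; the loop stops when the relative change |J_t - J_{t-1}| / J_{t-1}
        drops below ``rel_tol`` or after ``max_iter`` iterations.
        ``paper_strict`` sets rel_tol to 1e-15, which is below float64
        relative resolution for a changing objective, so the iteration cap
        then effectively governs.
        """
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if paper_strict:
            rel_tol = 1e-15
        factors = start if start is not None else self.initialize(mode=init, rng_seed=seed)
        cm = self.constraint_matrices
        A = self._A
        trace = [self.objective(factors)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            F = update_f(A, factors, cm, self.denom_floor)
            factors = FactorPair(F=F, G=factors.G)
            G = update_g(A, factors, cm, self.denom_floor, symmetrize=self.symmetrize_g)
            factors = FactorPair(F=F, G=G)
            j = self.objective(factors)
            if not np.isfinite(j):
                raise NumericalError(f"objective became non-finite at iteration {it}")
            j_prev = trace[-1]
            trace.append(j)
            if j_prev == 0.0:
                if j == 0.0:
                    converged = True
                    break
                continue
            if abs(j - j_prev) / j_prev < rel_tol:
                converged = True
                break
        logger.info(
            "fit finished: %d iterations, converged=%s, J=%.6g", it, converged, trace[-1]
        )
        return SSNMTFResults(
            model=self,
            factors=factors,
            objective_trace=trace,
            iterations=it,
            converged=converged,
        )


@dataclass
class SSNMTFResults:
    """Result of :meth:`SSNMTF.fit`.

    Carries the fitted factors, the per-iteration objective trace and
    convergence diagnostics; complex extraction and the summary table hang
    off this object.
    """

    model: SSNMTF
    factors: FactorPair
    objective_trace: list[float]
    iterations: int
    converged: bool

    @property
    def F(self) -> np.ndarray:
        return self.factors.F

    @property
    def G(self) -> np.ndarray:
        return self.factors.G

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def kkt_residuals(self) -> tuple[float, float]:
        """Max-norm of min(W, |grad_W J|) for W in {F, G}.

        Near a local minimum every entry either vanishes or has vanishing
        gradient, so both residuals should be small at convergence.
        """
        gF, gG = self.model.gradients(self.factors)
        rF = float(np.abs(np.minimum(self.factors.F, np.abs(gF))).max())
        rG = float(np.abs(np.minimum(self.factors.G, np.abs(gG))).max())
        return rF, rG

    def complexes(
        self,
        overlap: bool = False,
        min_size: int = 3,
        dedupe: bool = True,
    ) -> ComplexCover:
        """Extract predicted complexes from F.

        ``overlap=False`` gives the non-overlapping NSSNMTF assignment
        (row argmax), ``overlap=True`` the OSSNMTF column-prefix rule.
        Complexes smaller than ``min_size`` are dropped; in overlapping
        mode exact-duplicate complexes are removed when ``dedupe``.
        """
        from . import detection

        nodes = self.model.network.nodes
        if overlap:
            cover = detection.detect_overlapping(self.factors, nodes)
            if dedupe:
                cover = detection.dedupe_cover(cover)
        else:
            cover = detection.assign_nonoverlapping(self.factors, nodes)
        if min_size > 1:
            cover = detection.filter_cover(cover, min_size=min_size)
        return cover

    def partition_labels(self) -> np.ndarray:
        """Row-argmax module label per node, in network node order."""
        return np.argmax(self.factors.F, axis=1)

    def summary(self) -> str:
        net = self.model.network
        non = self.complexes(overlap=False)
        over = self.complexes(overlap=True)
        rF, rG = self.kkt_residuals()
        lines = [
            "SSNMTF fit results",
            "==================",
            f"nodes                 {net.n_nodes}",
            f"edges                 {net.n_edges}",
            f"weighted              {net.weighted}",
            f"module budget k       {self.model.k}",
            f"must-link pairs       {self.model.constraint_matrices.M.nnz // 2}",
            f"alpha                 {self.model.alpha:g}",
            f"iterations            {self.iterations}",
            f"converged             {self.converged}",
            f"initial objective     {self.objective_trace[0]:.6g}",
            f"final objective       {self.objective_trace[-1]:.6g}",
            f"KKT residual (F, G)   {rF:.3g}, {rG:.3g}",
            f"complexes (>=3, non-overlapping)  {len(non)}",
            f"complexes (>=3, overlapping)      {len(over)}",
        ]
        return "\n".join(lines)
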