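"""Must-link pairwise constraints and their graph-Laplacian encoding.

A must-link constraint states that two proteins belong to the same complex.
The set of constraints is encoded as a symmetric matrix ``M`` with
``m_ij = alpha`` for constrained pairs and 0 elsewhere.  With the diagonal
degree matrix ``D`` (``d_ii = sum_j m_ij``) the Laplacian ``L = D - M`` is
positive semi-definite and its quadratic form

    x' L x = 1/2 * sum_ij m_ij (x_i - x_j)^2

penalises assigning constrained pairs different membership profiles.

Constraints are sampled from a reference catalog following the rule that a
candidate pair must consist of proteins belonging to exactly **one**
reference complex (proteins shared by several complexes would give
ambiguous prior information).  A complex of ``N_c`` single-membership
proteins thus contributes ``N_c (N_c - 1) / 2`` candidate pairs, and a
fixed fraction of the pooled candidates is drawn uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ComplexCover, Network

logger = logging.getLogger(__name__)

__all__ = [
    "MustLinkConstraints",
    "ConstraintMatrices",
    "sample_mustlinks",
    "build_matrices",
    "read_mustlinks",
    "write_mustlinks",
]

DEFAULT_ALPHA = 10.0  # constraint weight used throughout unless overridden


@dataclass
class MustLinkConstraints:
    """A set of unordered must-link pairs with a common weight ``alpha``."""

    pairs: set[frozenset[str]]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"must-link pair must have two distinct labels: {set(p)}")

    def __len__(self) -> int:
        return len(self.pairs)

    def labels(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p
        return out


@dataclass
class ConstraintMatrices:
    """Materialized constraint matrices in a network's node order.

    ``M`` symmetric with entries in {0, alpha}, ``D`` diagonal degree
    matrix, ``L = D - M`` the (PSD) constraint Laplacian.  Stored sparse;
    the factorization updates touch them only through mat-vec products.
    """

    M: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @classmethod
    def empty(cls, n: int) -> "ConstraintMatrices":
        z = sp.csr_matrix((n, n))
        return cls(M=z, D=z.copy(), L=z.copy())


def sample_mustlinks(
    reference: ComplexCover,
    fraction: float,
    alpha: float = DEFAULT_ALPHA,
    rng_seed: int = 0,
) -> MustLinkConstraints:
    """Sample must-link pairs from a reference complex catalog.

    Candidate pairs are formed within each complex, but only among members
    that appear in exactly one complex of the reference.  A uniform sample
    of ``round(fraction * pool_size)`` pairs (round-half-up, without
    replacement) is drawn from the pooled candidate list.

    Parameters
    ----------
    reference : ComplexCover
        The catalog supplying prior knowledge.
    fraction : float in (0, 1]
        Fraction of the candidate pool to draw.  ``fraction=0`` is allowed
        as an explicit "no prior information" edge case.
    alpha : float
        Weight attached to every sampled pair.
    rng_seed : int
        Seed for the sampling RNG; same seed, same sample.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    membership_count: dict[str, int] = {}
    for c in reference.complexes:
        for p in c:
            membership_count[p] = membership_count.get(p, 0) + 1

    pool: list[tuple[str, str]] = []
    for c in reference.complexes:
        singles = sorted(p for p in c if membership_count[p] == 1)
        for i in range(len(singles)):
            for j in range(i + 1, len(singles)):
                pool.append((singles[i], singles[j]))

    if not pool:
        logger.warning("must-link candidate pool is empty; returning no constraints")
        return MustLinkConstraints(pairs=set(), alpha=alpha)

    n_draw = int(np.floor(fraction * len(pool) + 0.5))  # round half up
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(pool), size=n_draw, replace=False)
    pairs = {frozenset(pool[i]) for i in idx}
    return MustLinkConstraints(pairs=pairs, alpha=alpha)


def build_matrices(
    constraints: MustLinkConstraints,
    net: Network,
    strict: bool = True,
) -> ConstraintMatrices:
    """Materialize ``M``, ``D`` and ``L = D - M`` in the network's node order.

    With ``strict=True`` a constrained label missing from the network raises
    a validation error naming it; with ``strict=False`` (the pipeline path)
    such pairs are dropped with a warning, for robustness to
    catalog/network mismatch.
    """
    n = net.n_nodes
    rows: list[int] = []
    cols: list[int] = []
    dropped = 0
    for pair in constraints.pairs:
        u, v = tuple(pair)
        try:
            i, j = net.index_of(u), net.index_of(v)
        except KeyError as exc:
            if strict:
                raise ValueError(f"constrained label {exc.args[0]!r} not in network") from exc
            dropped += 1
            continue
        rows += [i, j]
        cols += [j, i]
    if dropped:
        logger.warning("dropped %d must-link pairs with labels absent from the network", dropped)

    data = np.full(len(rows), constraints.alpha)
    M = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    M.sum_duplicates()
    D = sp.diags(np.asarray(M.sum(axis=1)).ravel(), format="csr")
    L = (D - M).tocsr()
    return ConstraintMatrices(M=M, D=D, L=L)


def read_mustlinks(path, alpha: float = DEFAULT_ALPHA) -> MustLinkConstraints:
    """Read must-link pairs from a two-column whitespace/tab file."""
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected two labels")
            if cols[0] == cols[1]:
                logger.warning("%s:%d: ignoring self-pair %r", path, lineno, cols[0])
                continue
            pairs.add(frozenset((cols[0], cols[1])))
    return MustLinkConstraints(pairs=pairs, alpha=alpha)


def write_mustlinks(constraints: MustLinkConstraints, path) -> None:
    with open(path, "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in constraints.pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
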