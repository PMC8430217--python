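"""Evaluation statistics for predicted complex covers.

The matching score between a predicted complex ``p`` and a reference
complex ``g`` is the neighborhood affinity

    NA(p, g) = |p & g|^2 / (|p| * |g|)

which is 1 exactly when the sets coincide.  Predicted and reference
complexes are "matched" at NA >= 0.25 by convention; the looser 0.2
threshold is used for the precision/recall/F1 family.  The cluster-wise
sensitivity Sn, positive predictive value PPV and their geometric mean
Acc, the maximum matching ratio MMR, normalized mutual information for
partitions and for overlapping covers, and the hypergeometric enrichment
p-value complete the suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .io import ComplexCover

__all__ = [
    "neighborhood_affinity",
    "na_matrix",
    "count_matched",
    "precision_recall_f1",
    "sn_ppv_acc",
    "mmr",
    "nmi_partition",
    "nmi_cover",
    "hypergeom_pvalue",
    "enrichment_proportions",
    "EnrichmentQuery",
    "EvaluationReport",
    "evaluate",
]


def _sets(cover) -> list[set]:
    if isinstance(cover, ComplexCover):
        return [set(c) for c in cover.complexes]
    return [set(c) for c in cover]


def neighborhood_affinity(p: set, g: set) -> float:
    if not p or not g:
        raise ValueError("neighborhood affinity requires non-empty sets")
    inter = len(p & g)
    return inter * inter / (len(p) * len(g))


def na_matrix(pred, ref) -> np.ndarray:
    """NA scores for every (predicted, reference) pair, shape (|pred|, |ref|)."""
    P, R = _sets(pred), _sets(ref)
    out = np.zeros((len(P), len(R)))
    for i, p in enumerate(P):
        for j, g in enumerate(R):
            out[i, j] = neighborhood_affinity(p, g)
    return out


def count_matched(pred, ref, threshold: float = 0.25) -> int:
    """Number of predicted complexes whose best NA against the reference
    reaches ``threshold`` (the "#mm" column of benchmark tables)."""
    P, R = _sets(pred), _sets(ref)
    if not P or not R:
        return 0
    na = na_matrix(P, R)
    return int((na.max(axis=1) >= threshold).sum())


def precision_recall_f1(
    pred, ref, threshold: float = 0.2
) -> tuple[float, float, float]:
    """Complex-level precision, recall and F1 at overlap threshold.

    A reference complex counts as recovered if some prediction overlaps it
    with NA >= threshold; a prediction counts as correct if it overlaps
    some reference likewise.  F1 is 0 when both rates are 0.
    """
    P, R = _sets(pred), _sets(ref)
    if not P or not R:
        raise ValueError("precision_recall_f1 requires non-empty covers")
    na = na_matrix(P, R)
    n_cp = int((na.max(axis=1) >= threshold).sum())  # matched predictions
    n_cb = int((na.max(axis=0) >= threshold).sum())  # recovered references
    precision = n_cp / len(P)
    recall = n_cb / len(R)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def sn_ppv_acc(pred, ref) -> tuple[float, float, float]:
    """Cluster-wise sensitivity, positive predictive value and accuracy.

    With ``t_ij = |pred_i & ref_j|`` and ``N_j = |ref_j|``:
    Sn = sum_j max_i t_ij / sum_j N_j,
    PPV = sum_i max_j t_ij / sum_ij t_ij (0 when no overlap at all),
    Acc = sqrt(Sn * PPV).
    """
    P, R = _sets(pred), _sets(ref)
    if not P or not R:
        raise ValueError("sn_ppv_acc requires non-empty covers")
    t = np.array([[len(p & g) for g in R] for p in P], dtype=float)
    sn = float(t.max(axis=0).sum() / sum(len(g) for g in R))
    denom = t.sum()
    ppv = float(t.max(axis=1).sum() / denom) if denom > 0 else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def mmr(pred, ref, strict_matching: bool = False) -> float:
    """Maximum matching ratio.

    Default: the mean over reference complexes of their best NA against
    any prediction.  ``strict_matching`` instead solves the maximum-weight
    one-to-one assignment between predictions and references and divides
    the total matched NA by |ref|; it is never larger than the default.
    """
    P, R = _sets(pred), _sets(ref)
    if not P or not R:
        raise ValueError("mmr requires non-empty covers")
    na = na_matrix(P, R)
    if not strict_matching:
        return float(na.max(axis=0).mean())
    rows, cols = linear_sum_assignment(-na)
    return float(na[rows, cols].sum() / len(R))


# ---------------------------------------------------------------------------
# Normalized mutual information


def _partition_label_arrays(a, b, universe: Sequence | None = None):
    """Covers -> aligned integer label arrays; uncovered nodes become
    singletons.  Raises if either cover assigns a node to several sets."""
    A, B = _sets(a), _sets(b)
    if universe is None:
        uni = sorted(set().union(*A, *B) if A or B else set())
    else:
        uni = list(universe)
    if not uni:
        raise ValueError("empty node universe")
    index = {node: i for i, node in enumerate(uni)}
    out = []
    for cover in (A, B):
        lab = np.full(len(uni), -1, dtype=int)
        for c_idx, c in enumerate(cover):
            for node in c:
                i = index.get(node)
                if i is None:
                    continue
                if lab[i] != -1:
                    raise ValueError("cover is not a partition: node in several sets")
                lab[i] = c_idx
        nxt = len(cover)
        for i in range(len(uni)):
            if lab[i] == -1:
                lab[i] = nxt
                nxt += 1
        out.append(lab)
    return out[0], out[1]


def nmi_partition(a, b, universe: Sequence | None = None) -> float:
    """NMI between two partitions: 2 I(A;B) / (H(A) + H(B)).

    ``a`` and ``b`` may be aligned label sequences or disjoint covers over
    the same universe (uncovered nodes become singletons).  Returns 0 when
    either partition has zero entropy and the two differ.
    """
    if isinstance(a, (ComplexCover, list)) and isinstance(b, (ComplexCover, list)) and (
        isinstance(a, ComplexCover)
        or (a and isinstance(a[0], (set, frozenset)))
        or isinstance(b, ComplexCover)
        or (b and isinstance(b[0], (set, frozenset)))
    ):
        la, lb = _partition_label_arrays(a, b, universe)
    else:
        la = np.asarray(a)
        lb = np.asarray(b)
        if la.shape != lb.shape:
            raise ValueError("label arrays must align")
    if la.size == 0:
        raise ValueError("empty node universe")
    n = la.size
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    ct = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(ct, (ia, ib), 1.0)
    pa = ct.sum(axis=1) / n
    pb = ct.sum(axis=0) / n
    pab = ct / n

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    ha, hb = entropy(pa), entropy(pb)
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both trivial and identical
    if ha == 0.0 or hb == 0.0:
        return 0.0
    nz = pab > 0
    mi = float((pab[nz] * np.log(pab[nz] / np.outer(pa, pb)[nz])).sum())
    return 2.0 * mi / (ha + hb)


def _h(p: float) -> float:
    return -p * math.log(p, 2) if p > 0 else 0.0


def nmi_cover(a, b, universe: Sequence) -> float:
    """Overlapping-cover NMI of Lancichinetti, Fortunato & Kertesz.

    Each complex is a binary membership variable over the universe; the
    score is 1 - [H(A|B)_norm + H(B|A)_norm] / 2, where the conditional
    entropy of one complex given a whole cover minimizes over the other
    cover's complexes, subject to the admissibility condition
    h(11) + h(00) >= h(01) + h(10) (otherwise the unconditional entropy is
    used).  Equals 1 exactly for identical covers.
    """
    A, B = _sets(a), _sets(b)
    uni = list(universe)
    n = len(uni)
    if n == 0:
        raise ValueError("empty node universe")
    if not A or not B:
        raise ValueError("nmi_cover requires non-empty covers")
    uniset = set(uni)
    A = [c & uniset for c in A]
    B = [c & uniset for c in B]

    def cond_norm(X: list[set], Y: list[set]) -> float:
        # mean over X's complexes of H(Xk | Y) / H(Xk)
        total = 0.0
        for xk in X:
            px = len(xk) / n
            hx = _h(px) + _h(1 - px)
            if hx == 0.0:
                continue  # degenerate variable carries no information
            best = hx
            for yl in Y:
                py = len(yl) / n
                p11 = len(xk & yl) / n
                p10 = px - p11
                p01 = py - p11
                p00 = 1 - p11 - p10 - p01
                if _h(p11) + _h(p00) < _h(p01) + _h(p10):
                    continue  # inadmissible: complement-like match
                hy = _h(py) + _h(1 - py)
                hxy = _h(p11) + _h(p10) + _h(p01) + _h(p00)
                best = min(best, hxy - hy)
            total += best / hx
        return total / len(X)

    return 1.0 - 0.5 * (cond_norm(A, B) + cond_norm(B, A))


# ---------------------------------------------------------------------------
# Functional enrichment


@dataclass
class EnrichmentQuery:
    """Inputs of the hypergeometric enrichment test.

    t: total proteins in the network; k_c: size of the predicted complex;
    f: proteins carrying the annotation in the whole network; q: annotated
    proteins inside the complex.
    """

    t: int
    k_c: int
    f: int
    q: int

    def __post_init__(self) -> None:
        if not (0 <= self.q <= min(self.k_c, self.f) <= self.t):
            raise ValueError(
                f"invalid enrichment query: need 0 <= q <= min(k_c, f) <= t, "
                f"got t={self.t}, k_c={self.k_c}, f={self.f}, q={self.q}"
            )
        if self.k_c > self.t:
            raise ValueError("complex larger than the network")


def hypergeom_pvalue(query: EnrichmentQuery) -> float:
    """Upper-tail hypergeometric probability of observing >= q annotated
    proteins in a complex of size k_c, drawn from t proteins of which f
    are annotated.  q = 0 gives 1 by construction."""
    if query.q == 0:
        return 1.0
    return float(hypergeom.sf(query.q - 1, query.t, query.f, query.k_c))


def enrichment_proportions(
    pvalues: Iterable[float], thresholds: Iterable[float]
) -> dict:
    """Fractions of complexes significant at each threshold.

    Returns sorted thresholds with the cumulative fraction of p-values at
    or below each, plus the per-interval fractions between consecutive
    thresholds (first interval is [0, thr_1]).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    thr = np.sort(np.asarray(list(thresholds), dtype=float))
    if p.size == 0:
        cum = np.zeros(thr.size)
    else:
        cum = np.array([(p <= t).mean() for t in thr])
    interval = np.diff(np.concatenate(([0.0], cum)))
    return {
        "thresholds": thr.tolist(),
        "cumulative": cum.tolist(),
        "interval": interval.tolist(),
    }


# ---------------------------------------------------------------------------
# Aggregate report


@dataclass
class EvaluationReport:
    """All cover-vs-reference statistics in one record."""

    precision: float
    recall: float
    f1: float
    sn: float
    ppv: float
    acc: float
    mmr: float
    n_predicted: int
    n_matched: int

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        rows = self.to_dict()
        width = max(len(k) for k in rows)
        return "\n".join(
            f"{k:<{width}}  {v:.4f}" if isinstance(v, float) else f"{k:<{width}}  {v}"
            for k, v in rows.items()
        )


def evaluate(
    pred,
    ref,
    na_threshold: float = 0.25,
    ol_threshold: float = 0.2,
) -> EvaluationReport:
    """Score a predicted cover against a reference catalog."""
    precision, recall, f1 = precision_recall_f1(pred, ref, threshold=ol_threshold)
    sn, ppv, acc = sn_ppv_acc(pred, ref)
    return EvaluationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        sn=sn,
        ppv=ppv,
        acc=acc,
        mmr=mmr(pred, ref),
        n_predicted=len(_sets(pred)),
        n_matched=count_matched(pred, ref, threshold=na_threshold),
    )
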