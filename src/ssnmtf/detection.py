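"""Turn a fitted membership matrix F into complex predictions.

Two extraction rules are provided:

* **Non-overlapping (NSSNMTF)** — each node joins the module whose column
  holds the maximum of its F row; columns that are nobody's argmax yield
  no complex, which is how a generous module budget k adapts downward.
* **Overlapping (OSSNMTF)** — for each column c the entries are ranked in
  descending order and accumulated until their running sum reaches the
  module's size estimate ``s_c = (F'F)_cc`` (for a binary membership
  matrix this diagonal is exactly the module size); the nodes in that
  shortest sufficient prefix form complex c.  A node may appear in many
  complexes.

Predicted complexes with fewer than three members are conventionally
filtered out before evaluation.
"""

from __future__ import annotations

import logging

import numpy as np

from .factorization import FactorPair
from .io import ComplexCover

logger = logging.getLogger(__name__)

__all__ = [
    "assign_nonoverlapping",
    "detect_overlapping",
    "filter_cover",
    "dedupe_cover",
]


def assign_nonoverlapping(factors: FactorPair, nodes: list[str]) -> ComplexCover:
    """Assign every node to its row-argmax module; ties break toward the
    lowest column index.  All-zero rows go to column 0 with a warning.
    Returns one complex per non-empty module, in column order."""
    F = factors.F
    if F.shape[0] != len(nodes):
        raise ValueError("node list length does not match F")
    zero_rows = ~F.any(axis=1)
    if zero_rows.any():
        logger.warning(
            "%d all-zero F rows assigned to module 0", int(zero_rows.sum())
        )
    labels = np.argmax(F, axis=1)
    complexes = []
    for c in range(F.shape[1]):
        members = {nodes[i] for i in np.flatnonzero(labels == c)}
        if members:
            complexes.append(members)
    return ComplexCover(complexes=complexes, name="nssnmtf")


def overlapping_prefix_length(column: np.ndarray, target: float) -> int:
    """Length of the shortest descending-order prefix of ``column`` whose
    sum reaches ``target``; the whole column if the total falls short."""
    order = np.argsort(-column, kind="stable")
    csum = np.cumsum(column[order])
    hit = np.flatnonzero(csum >= target)
    return int(hit[0]) + 1 if hit.size else len(column)


def detect_overlapping(factors: FactorPair, nodes: list[str]) -> ComplexCover:
    """Extract one (possibly overlapping) complex per F column by the
    sorted-prefix accumulation rule.

    Ties in F values are broken by ascending node index, making the output
    deterministic.  An all-zero column yields an empty prefix and is
    dropped here (size filtering removes small survivors later).
    """
    F = factors.F
    if F.shape[0] != len(nodes):
        raise ValueError("node list length does not match F")
    sizes = np.einsum("ic,ic->c", F, F)  # diagonal of F'F
    complexes = []
    for c in range(F.shape[1]):
        col = F[:, c]
        if sizes[c] == 0.0:
            continue
        order = np.argsort(-col, kind="stable")
        m = overlapping_prefix_length(col, sizes[c])
        complexes.append({nodes[i] for i in order[:m]})
    return ComplexCover(complexes=complexes, name="ossnmtf")


def filter_cover(cover: ComplexCover, min_size: int = 3) -> ComplexCover:
    """Drop complexes with fewer than ``min_size`` members, keeping order."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [c for c in cover.complexes if len(c) >= min_size]
    return ComplexCover(complexes=kept, name=cover.name)


def dedupe_cover(cover: ComplexCover) -> ComplexCover:
    """Remove exact-duplicate complexes, keeping the first occurrence.

    Distinct F columns can select identical member sets; reported complex
    counts presume distinct complexes."""
    seen: set[frozenset[str]] = set()
    kept = []
    for c in cover.complexes:
        key = frozenset(c)
        if key not in seen:
            seen.add(key)
            kept.append(c)
    removed = len(cover.complexes) - len(kept)
    if removed:
        logger.info("dedupe_cover removed %d duplicate complexes", removed)
    return ComplexCover(complexes=kept, name=cover.name)
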