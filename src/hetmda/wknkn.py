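"""Weighted K-nearest-known-neighbors (WKNKN) completion.

The binary association matrix is extremely sparse and its zeros conflate
"tested negative" with "never observed".  WKNKN replaces each zero with an
interaction likelihood estimated from the K most similar *known* neighbors
(entities with at least one known association) in each space:

* disease side: ``Yd(i, .) = sum_t r^(t-1) * sim(i, nn_t) * A(nn_t, .)``
  normalized by ``sum_t sim(i, nn_t)``, neighbors sorted by similarity
  descending with a decay ``r`` per neighbor rank;
* miRNA side analogously on columns;
* the completed entry is the average of the two one-sided estimates, clipped
  to [0, 1]; known 1s are never modified.
"""

from __future__ import annotations

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix
from .errors import AlignmentError, ParameterError

__all__ = ["knn_known", "wknkn_complete"]


def knn_known(
    sim: SimilarityMatrix, A: AssociationMatrix, space: str, K: int
) -> dict[str, list[tuple[str, float]]]:
    """The K most similar *known* neighbors of every entity in one space.

    Known means at least one association in the (training) matrix: positive
    row sum for diseases, positive column sum for miRNAs.  The entity itself
    is excluded.  Ties break by label ascending; fewer than K neighbors are
    returned when fewer known entities exist.
    """
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K!r}")
    if space == "disease":
        ids, degrees = A.disease_ids, A.disease_degrees()
    elif space == "mirna":
        ids, degrees = A.mirna_ids, A.mirna_degrees()
    else:
        raise ParameterError(f"space must be 'disease' or 'mirna', got {space!r}")
    if sim.ids != ids:
        raise AlignmentError(f"similarity labels do not match the {space} labels")

    known = degrees > 0
    out: dict[str, list[tuple[str, float]]] = {}
    for i, entity in enumerate(ids):
        candidates = [
            (ids[j], float(sim.values[i, j]))
            for j in range(len(ids))
            if j != i and known[j]
        ]
        candidates.sort(key=lambda t: (-t[1], t[0]))
        out[entity] = candidates[:K]
    return out


def wknkn_complete(
    A: AssociationMatrix,
    ISD: SimilarityMatrix,
    ISM: SimilarityMatrix,
    K: int = 5,
    r: float = 0.7,
) -> AssociationMatrix:
    """Complete a binary association matrix from its K nearest known neighbors.

    Returns a new matrix with every known 1 preserved and every 0 replaced by
    ``min(1, (Yd + Ym) / 2)``.  An entity whose K neighbor similarities sum to
    zero (or which has no known neighbor at all) contributes a zero estimate
    on its side.
    """
    if not 0 < r <= 1:
        raise ParameterError(f"r must lie in (0, 1], got {r!r}")
    if not A.is_binary():
        raise ParameterError("WKNKN expects a binary association matrix")

    values = A.values
    didx = A.disease_index()
    midx = A.mirna_index()
    decay = np.array([r**t for t in range(K)])

    dn = knn_known(ISD, A, "disease", K)
    mn = knn_known(ISM, A, "mirna", K)

    Yd = np.zeros_like(values)
    for i, d in enumerate(A.disease_ids):
        nbrs = dn[d]
        if not nbrs:
            continue
        sims = np.array([s for _, s in nbrs])
        denom = sims.sum()
        if denom <= 0:
            continue
        rows = np.array([didx[n] for n, _ in nbrs])
        w = decay[: len(nbrs)] * sims
        Yd[i] = w @ values[rows] / denom

    Ym = np.zeros_like(values)
    for j, m in enumerate(A.mirna_ids):
        nbrs = mn[m]
        if not nbrs:
            continue
        sims = np.array([s for _, s in nbrs])
        denom = sims.sum()
        if denom <= 0:
            continue
        cols = np.array([midx[n] for n, _ in nbrs])
        w = decay[: len(nbrs)] * sims
        Ym[:, j] = values[:, cols] @ w / denom

    estimate = np.minimum(1.0, (Yd + Ym) / 2.0)
    completed = np.where(values == 1, 1.0, estimate)
    return AssociationMatrix(completed, list(A.disease_ids), list(A.mirna_ids))
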