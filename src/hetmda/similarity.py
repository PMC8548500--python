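"""Disease, miRNA and interaction-profile similarity measures.

Four similarity layers feed the heterogeneous networks:

* **disease semantic similarity (DSS)** from the disease ontology DAGs, in the
  Wang style: each ancestor t contributes ``D_d(t)``, decaying by a factor
  ``delta_sem`` per generation below the disease itself, and two diseases are
  similar in proportion to the shared part of their ancestor closures;
* **miRNA functional similarity (MFS)** from each miRNA's set of associated
  disease terms, averaging best-match semantic similarities between the two
  term sets;
* **Gaussian interaction-profile (GIP) kernel similarity** in either space,
  a Gaussian kernel on the rows (diseases) or columns (miRNAs) of the binary
  association matrix with a data-driven bandwidth (``gamma_prime`` divided by
  the mean squared profile norm);
* **integrated similarity (ISD/ISM)**, which keeps the semantic/functional
  value wherever one exists and falls back to the GIP kernel elsewhere —
  diseases without a DAG (or miRNAs whose functional similarity is undefined)
  still receive a complete similarity row.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .errors import AlignmentError, InputError, ParameterError, StructureError

__all__ = [
    "semantic_contributions",
    "disease_semantic_similarity",
    "mirna_functional_similarity",
    "gip_similarity",
    "integrate_similarity",
]


def semantic_contributions(dag: DiseaseDAG, delta_sem: float = 0.5) -> dict[str, float]:
    """Per-ancestor semantic contribution values D_d(t).

    D_d(d) = 1; for any other ancestor t the contribution decays through its
    best (max) child inside the closure: D_d(t) = delta_sem * max_{t'} D_d(t').
    """
    if not 0 < delta_sem < 1:
        raise ParameterError(f"delta_sem must lie in (0, 1), got {delta_sem!r}")
    children: dict[str, set[str]] = {t: set() for t in dag.ancestors}
    for c, p in dag.edges:
        children[p].add(c)

    contrib: dict[str, float] = {dag.term_id: 1.0}
    # resolve bottom-up; the closure is acyclic so repeated sweeps terminate
    pending = set(dag.ancestors) - {dag.term_id}
    while pending:
        progressed = False
        for t in list(pending):
            kids = children[t]
            if not kids:
                raise StructureError(
                    f"ancestor {t!r} of {dag.term_id!r} has no child inside "
                    "the closure (no path back to the term)"
                )
            if kids <= contrib.keys():
                contrib[t] = delta_sem * max(contrib[c] for c in kids)
                pending.discard(t)
                progressed = True
        if not progressed:
            raise StructureError(
                f"closure of {dag.term_id!r} contains ancestors unreachable "
                f"from the term: {sorted(pending)}"
            )
    return contrib


def disease_semantic_similarity(
    dags: dict[str, DiseaseDAG],
    delta_sem: float = 0.5,
    ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over the shared ancestor closures.

    DSS(i, j) sums D_i(t) + D_j(t) over the shared ancestors t and divides by
    the two total semantic values.  When ``ids`` extends beyond the DAG map,
    diseases without a DAG get zero off-diagonal similarity (the integration
    step later backfills those entries from the GIP kernel).
    """
    if not dags:
        raise InputError("empty DAG map")
    if ids is None:
        ids = list(dags)
    contrib = {d: semantic_contributions(dag, delta_sem) for d, dag in dags.items()}
    totals = {d: sum(c.values()) for d, c in contrib.items()}

    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        da = ids[a]
        if da not in contrib:
            continue
        for b in range(a + 1, n):
            db = ids[b]
            if db not in contrib:
                continue
            shared = contrib[da].keys() & contrib[db].keys()
            if not shared:
                continue
            num = sum(contrib[da][t] + contrib[db][t] for t in shared)
            values[a, b] = values[b, a] = num / (totals[da] + totals[db])
    return SimilarityMatrix(values, ids, kind="semantic")


def mirna_functional_similarity(
    dtt: dict[str, set[str]],
    dss: SimilarityMatrix,
    ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Best-match average functional similarity between miRNA disease sets.

    With DTT_i of size k and DTT_j of size l,
    MFS(i, j) = (sum_m SS(d_im, DTT_j) + sum_n SS(d_jn, DTT_i)) / (k + l)
    where SS(d, DTT) = max_{d' in DTT} DSS(d, d').
    """
    if not dtt:
        raise InputError("empty miRNA -> disease-term map")
    if ids is None:
        ids = list(dtt)
    didx = dss.index()
    cols: dict[str, np.ndarray] = {}
    for m in ids:
        terms = dtt.get(m)
        if not terms:
            raise InputError(f"miRNA {m!r} has an empty disease-term set")
        missing = [t for t in terms if t not in didx]
        if missing:
            raise InputError(
                f"miRNA {m!r} references disease terms absent from the "
                f"semantic similarity matrix: {sorted(missing)}"
            )
        cols[m] = np.array(sorted(didx[t] for t in terms), dtype=int)

    # best_match[m] holds SS(d, DTT_m) for every disease d in the vocabulary
    best_match = {m: dss.values[:, cols[m]].max(axis=1) for m in ids}

    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        ma = ids[a]
        for b in range(a + 1, n):
            mb = ids[b]
            k, l = len(cols[ma]), len(cols[mb])
            total = best_match[mb][cols[ma]].sum() + best_match[ma][cols[mb]].sum()
            values[a, b] = values[b, a] = total / (k + l)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(np.clip(values, 0.0, 1.0), ids, kind="functional")


def gip_similarity(
    A: AssociationMatrix, space: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity.

    Profiles are the rows (``space='disease'``) or columns (``space='mirna'``)
    of the association matrix; the bandwidth is gamma_prime divided by the
    mean squared profile norm.
    """
    if gamma_prime <= 0:
        raise ParameterError(f"gamma_prime must be > 0, got {gamma_prime!r}")
    if space == "disease":
        profiles, ids = A.values, A.disease_ids
    elif space == "mirna":
        profiles, ids = A.values.T, A.mirna_ids
    else:
        raise ParameterError(f"space must be 'disease' or 'mirna', got {space!r}")
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0:
        raise InputError(
            "all interaction profiles are zero; the GIP bandwidth is undefined"
        )
    gamma = gamma_prime / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq_dists)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ids), kind="gip")


def integrate_similarity(
    primary_sim: SimilarityMatrix,
    gip_sim: SimilarityMatrix,
    mask: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Fuse a semantic/functional similarity with the GIP kernel.

    Keeps the primary value where one exists, else the GIP value.  By default
    "exists" means primary_sim(i, j) > 0 elementwise; an explicit boolean
    ``mask`` (True = use the primary value) overrides that test.  The diagonal
    is forced to 1.
    """
    if primary_sim.ids != gip_sim.ids:
        raise AlignmentError("primary and GIP similarity labels differ")
    if mask is None:
        mask = primary_sim.values > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != primary_sim.values.shape:
            raise AlignmentError("availability mask shape mismatch")
    values = np.where(mask, primary_sim.values, gip_sim.values)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(primary_sim.ids), kind="integrated")
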