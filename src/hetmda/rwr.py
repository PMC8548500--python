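"""Random walk with restart over the heterogeneous networks.

The walk iterates the matrix recurrence ``P_{t+1} = (1 - gamma) W P_t +
gamma P0`` (the assembled network left-multiplies the state) from a
block-diagonal seed ``P0`` that splits unit mass between the disease block
(weight ``1 - delta``, spread as 1/n_d per seed) and the miRNA block
(weight ``delta``, spread as 1/n_m).  One walk runs on the disease-based
network, one on the miRNA-based network; the final prediction matrix is
their delta-weighted combination, and the disease x miRNA scores are read
from the two off-diagonal blocks (averaged by default).
"""

from __future__ import annotations

import numpy as np

from .containers import AssociationMatrix, PipelineParams, ScoreTable, SimilarityMatrix
from .errors import AlignmentError, NumericalError, ParameterError
from .hetnet import HetNetwork, build_networks
from .wknkn import wknkn_complete

__all__ = [
    "initial_probability",
    "rwr_propagate",
    "combine_and_extract",
    "predict_associations",
]


def initial_probability(n_d: int, n_m: int, delta: float) -> np.ndarray:
    """Block-diagonal seed matrix with trace 1.

    Disease diagonal entries are ``(1 - delta) / n_d``, miRNA diagonal
    entries ``delta / n_m``; all off-block entries are zero.
    """
    if n_d < 1 or n_m < 1:
        raise ParameterError("n_d and n_m must be >= 1")
    if not 0 < delta < 1:
        raise ParameterError(f"delta must lie in (0, 1), got {delta!r}")
    diag = np.concatenate(
        [np.full(n_d, (1.0 - delta) / n_d), np.full(n_m, delta / n_m)]
    )
    return np.diag(diag)


def rwr_propagate(
    W: HetNetwork | np.ndarray,
    P0: np.ndarray,
    gamma: float,
    t_max: int = 10,
    tol: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Iterate the restart recurrence; returns (final state, steps taken).

    Stops after ``t_max`` steps, or earlier once the max-abs change between
    consecutive states drops below ``tol`` (``tol=0`` disables the early
    stop, matching the fixed-iteration convention).
    """
    if not 0 < gamma <= 1:
        raise ParameterError(f"gamma must lie in (0, 1], got {gamma!r}")
    if t_max < 1:
        raise ParameterError(f"t_max must be >= 1, got {t_max!r}")
    M = W.assembled if isinstance(W, HetNetwork) else np.asarray(W, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    if M.shape != P0.shape:
        raise AlignmentError(
            f"network shape {M.shape} does not match seed shape {P0.shape}"
        )
    P = P0
    for t in range(1, t_max + 1):
        P_next = (1.0 - gamma) * (M @ P) + gamma * P0
        if not np.all(np.isfinite(P_next)):
            raise NumericalError(f"non-finite walk state at iteration {t}")
        delta_max = float(np.max(np.abs(P_next - P)))
        P = P_next
        if tol > 0 and delta_max < tol:
            return P, t
    return P, t_max


def combine_and_extract(
    P1: np.ndarray,
    P2: np.ndarray,
    delta: float,
    n_d: int,
    n_m: int,
    disease_ids: list[str],
    mirna_ids: list[str],
    known_mask: np.ndarray,
    symmetrize: bool = True,
) -> ScoreTable:
    """Fuse the two walk results and read out the disease x miRNA scores.

    ``P = (1 - delta) P1 + delta P2``; scores come from the top-right
    n_d x n_m block, averaged with the transpose of the bottom-left block
    unless ``symmetrize`` is False (then top-right only).
    """
    P1 = np.asarray(P1, dtype=float)
    P2 = np.asarray(P2, dtype=float)
    if P1.shape != P2.shape or P1.shape != (n_d + n_m, n_d + n_m):
        raise AlignmentError("walk states do not conform to (n_d + n_m) square")
    if not 0 < delta < 1:
        raise ParameterError(f"delta must lie in (0, 1), got {delta!r}")
    P = (1.0 - delta) * P1 + delta * P2
    top_right = P[:n_d, n_d:]
    if symmetrize:
        scores = (top_right + P[n_d:, :n_d].T) / 2.0
    else:
        scores = top_right
    return ScoreTable(scores, list(disease_ids), list(mirna_ids), np.asarray(known_mask))


def predict_associations(
    A: AssociationMatrix,
    ISD: SimilarityMatrix,
    ISM: SimilarityMatrix,
    params: PipelineParams | None = None,
    use_wknkn: bool = True,
    symmetrize: bool = True,
) -> ScoreTable:
    """Score every disease-miRNA pair from integrated similarities.

    Runs WKNKN completion (unless disabled), builds both degree-weighted
    heterogeneous networks, propagates the restart walk on each, and fuses
    the results.  Fully deterministic.
    """
    params = params or PipelineParams()
    if not A.is_binary():
        raise ParameterError("prediction expects the binary association matrix")
    A_new = wknkn_complete(A, ISD, ISM, K=params.K, r=params.r) if use_wknkn else A
    net_d, net_m = build_networks(A_new, ISD, ISM, params.phi)
    P0 = initial_probability(A.n_diseases, A.n_mirnas, params.delta)
    P1, _ = rwr_propagate(net_d, P0, params.gamma, params.t_max, params.tol)
    P2, _ = rwr_propagate(net_m, P0, params.gamma, params.t_max, params.tol)
    return combine_and_extract(
        P1,
        P2,
        params.delta,
        A.n_diseases,
        A.n_mirnas,
        A.disease_ids,
        A.mirna_ids,
        known_mask=A.values.copy(),
        symmetrize=symmetrize,
    )
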