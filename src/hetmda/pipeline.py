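"""End-to-end scoring from primary similarities and a binary matrix.

This is the composition the evaluation protocols re-run on every masked
training matrix: GIP kernels are recomputed from the (possibly masked)
associations, integrated with the association-independent semantic and
functional similarities, WKNKN completes the matrix, and the two restart
walks produce the score table.
"""

from __future__ import annotations

from .containers import AssociationMatrix, PipelineParams, ScoreTable, SimilarityMatrix
from .rwr import predict_associations
from .similarity import gip_similarity, integrate_similarity

__all__ = ["integrated_similarities", "score_pairs"]


def integrated_similarities(
    A: AssociationMatrix,
    DSS: SimilarityMatrix,
    MFS: SimilarityMatrix,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """ISD and ISM: semantic/functional values backed by GIP kernels.

    GIP profiles come from the binary matrix passed in (in cross-validation
    that is the masked training matrix, so no held-out association leaks
    into the kernels).
    """
    gip_d = gip_similarity(A, "disease", gamma_prime)
    gip_m = gip_similarity(A, "mirna", gamma_prime)
    ISD = integrate_similarity(DSS, gip_d)
    ISM = integrate_similarity(MFS, gip_m)
    return ISD, ISM


def score_pairs(
    A: AssociationMatrix,
    DSS: SimilarityMatrix,
    MFS: SimilarityMatrix,
    params: PipelineParams | None = None,
    use_wknkn: bool = True,
    use_integration: bool = True,
) -> ScoreTable:
    """Run the full pipeline on one training matrix.

    ``use_wknkn=False`` skips the completion step (sparsity ablation);
    ``use_integration=False`` drops the semantic/functional layers and runs
    on the GIP kernels alone (similarity ablation).
    """
    params = params or PipelineParams()
    if use_integration:
        ISD, ISM = integrated_similarities(A, DSS, MFS, params.gamma_prime)
    else:
        ISD = gip_similarity(A, "disease", params.gamma_prime)
        ISM = gip_similarity(A, "mirna", params.gamma_prime)
    return predict_associations(A, ISD, ISM, params, use_wknkn=use_wknkn)
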