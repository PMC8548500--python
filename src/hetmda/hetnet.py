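"""Degree-weighted heterogeneous network construction.

Two heterogeneous networks are assembled, one per space.  Their blocks:

* ``disease_base = ISD @ A_new`` and ``mirna_base = A_new @ ISM`` re-weight
  each association edge by how similar the remaining entities of one space
  are to its endpoint — the "degree tendency" of the edge;
* the inter-space transition ``T_DM`` distributes the jump probability
  ``phi`` over each disease's candidate miRNAs proportionally to
  ``A_new * mirna_base`` (rows sum to phi); ``T_MD`` does the same per miRNA
  column with ``A_new * disease_base`` (columns sum to phi);
* the intra-space transitions ``Wd``/``Wm`` are similarity rows normalized by
  their row sum (self-similarity included), scaled by ``1 - phi`` for
  entities that have at least one association and left unscaled for isolated
  ones, which cannot jump across;
* each network stacks the blocks as ``[[Wd, T], [T^T, Wm]]`` with T = T_DM
  (disease-based) or T = T_MD (miRNA-based).

Rows of the opposite space are deliberately not renormalized; the restart
term of the walk keeps the propagation well defined regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix
from .errors import AlignmentError, ParameterError

__all__ = [
    "BaseAdjacency",
    "HetNetwork",
    "base_adjacencies",
    "inter_transition",
    "intra_transition",
    "assemble_network",
    "build_networks",
]


@dataclass
class BaseAdjacency:
    """The two similarity-weighted association matrices (both n_d x n_m)."""

    disease_base: np.ndarray
    mirna_base: np.ndarray


@dataclass
class HetNetwork:
    """One assembled heterogeneous transition matrix and its blocks."""

    Wd: np.ndarray
    Wm: np.ndarray
    T: np.ndarray
    orientation: str
    isolated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("disease_based", "mirna_based"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")
        n_d, n_m = self.T.shape
        if self.Wd.shape != (n_d, n_d) or self.Wm.shape != (n_m, n_m):
            raise AlignmentError(
                f"blocks do not conform: Wd {self.Wd.shape}, Wm {self.Wm.shape}, "
                f"T {self.T.shape}"
            )

    @property
    def n_diseases(self) -> int:
        return self.T.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.T.shape[1]

    @property
    def assembled(self) -> np.ndarray:
        return np.block([[self.Wd, self.T], [self.T.T, self.Wm]])


def _check_alignment(ISD: SimilarityMatrix, A: AssociationMatrix, ISM: SimilarityMatrix):
    if ISD.ids != A.disease_ids:
        raise AlignmentError("disease similarity labels do not match the matrix rows")
    if ISM.ids != A.mirna_ids:
        raise AlignmentError("miRNA similarity labels do not match the matrix columns")


def base_adjacencies(
    ISD: SimilarityMatrix, A_new: AssociationMatrix, ISM: SimilarityMatrix
) -> BaseAdjacency:
    """Similarity-weighted association matrices for both orientations."""
    _check_alignment(ISD, A_new, ISM)
    return BaseAdjacency(
        disease_base=ISD.values @ A_new.values,
        mirna_base=A_new.values @ ISM.values,
    )


def inter_transition(
    A_new: AssociationMatrix, base: np.ndarray, phi: float, direction: str
) -> np.ndarray:
    """Inter-space jump probabilities.

    ``direction='dm'`` normalizes each disease row of ``A_new * mirna_base``
    to sum to phi; ``direction='md'`` normalizes each miRNA column of
    ``A_new * disease_base`` to sum to phi.  Rows/columns whose denominator
    is zero stay all-zero.
    """
    if not 0 < phi < 1:
        raise ParameterError(f"phi must lie in (0, 1), got {phi!r}")
    base = np.asarray(base, dtype=float)
    if base.shape != A_new.values.shape:
        raise AlignmentError("base adjacency shape does not match the association matrix")
    weighted = A_new.values * base
    out = np.zeros_like(weighted)
    if direction == "dm":
        denom = weighted.sum(axis=1)
        rows = denom > 0
        out[rows] = phi * weighted[rows] / denom[rows, None]
    elif direction == "md":
        denom = weighted.sum(axis=0)
        cols = denom > 0
        out[:, cols] = phi * weighted[:, cols] / denom[None, cols]
    else:
        raise ParameterError(f"direction must be 'dm' or 'md', got {direction!r}")
    return out


def intra_transition(
    sim: SimilarityMatrix, A_new: AssociationMatrix, phi: float, space: str
) -> tuple[np.ndarray, list[str]]:
    """Within-space transition matrix; returns (W, isolated-entity labels).

    Each row is the similarity row divided by its row sum (diagonal
    included).  Entities with at least one association get the ``1 - phi``
    factor (the rest of their mass jumps across via the inter block);
    entities with none keep the full row.  All-zero similarity rows stay
    zero and are reported as isolated.
    """
    if not 0 < phi < 1:
        raise ParameterError(f"phi must lie in (0, 1), got {phi!r}")
    if space == "disease":
        if sim.ids != A_new.disease_ids:
            raise AlignmentError("similarity labels do not match disease labels")
        degrees = A_new.disease_degrees()
    elif space == "mirna":
        if sim.ids != A_new.mirna_ids:
            raise AlignmentError("similarity labels do not match miRNA labels")
        degrees = A_new.mirna_degrees()
    else:
        raise ParameterError(f"space must be 'disease' or 'mirna', got {space!r}")

    rowsum = sim.values.sum(axis=1)
    W = np.zeros_like(sim.values)
    nz = rowsum > 0
    W[nz] = sim.values[nz] / rowsum[nz, None]
    connected = degrees > 0
    W[connected & nz] *= 1.0 - phi
    isolated = [sim.ids[i] for i in np.flatnonzero(~nz)]
    return W, isolated


def assemble_network(
    Wd: np.ndarray, Wm: np.ndarray, T: np.ndarray, orientation: str
) -> HetNetwork:
    """Stack the three blocks into one (n_d + n_m)-square transition matrix."""
    return HetNetwork(np.asarray(Wd, float), np.asarray(Wm, float), np.asarray(T, float), orientation)


def build_networks(
    A_new: AssociationMatrix,
    ISD: SimilarityMatrix,
    ISM: SimilarityMatrix,
    phi: float,
) -> tuple[HetNetwork, HetNetwork]:
    """Both heterogeneous networks (disease-based, miRNA-based)."""
    bases = base_adjacencies(ISD, A_new, ISM)
    T_dm = inter_transition(A_new, bases.mirna_base, phi, "dm")
    T_md = inter_transition(A_new, bases.disease_base, phi, "md")
    Wd, iso_d = intra_transition(ISD, A_new, phi, "disease")
    Wm, iso_m = intra_transition(ISM, A_new, phi, "mirna")
    net_d = assemble_network(Wd, Wm, T_dm, "disease_based")
    net_m = assemble_network(Wd, Wm, T_md, "mirna_based")
    net_d.isolated = net_m.isolated = iso_d + iso_m
    return net_d, net_m
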