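"""Core labelled-matrix and DAG data types.

All pipeline stages exchange these containers.  Matrices are stored dense:
at the scale this method targets (a few hundred diseases by a few hundred
miRNAs) dense arithmetic is simplest and fast, and every operation is
label-driven rather than positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import CycleError, ParameterError, StructureError

__all__ = [
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "ScoreTable",
    "PipelineParams",
]

SIMILARITY_KINDS = ("semantic", "functional", "gip", "integrated")


def _check_labels(ids, name: str) -> list[str]:
    ids = [str(x) for x in ids]
    if not ids:
        raise ValueError(f"{name}: label list is empty")
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValueError(f"{name}: duplicate labels {sorted(set(dupes))}")
    return ids


@dataclass
class AssociationMatrix:
    """Disease x miRNA association matrix.

    Binary on input; real-valued in [0, 1] after WKNKN completion.  Rows are
    diseases, columns miRNAs, in the order of ``disease_ids``/``mirna_ids``.
    """

    values: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.disease_ids = _check_labels(self.disease_ids, "disease_ids")
        self.mirna_ids = _check_labels(self.mirna_ids, "mirna_ids")
        if self.values.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.mirna_ids)} miRNAs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("association matrix has non-finite entries")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("association matrix entries must lie in [0, 1]")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    def disease_degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def mirna_degrees(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.disease_ids)}

    def mirna_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.mirna_ids)}

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.disease_ids), list(self.mirna_ids)
        )


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor closure of one disease term.

    ``ancestors`` is the term's ancestor set including the term itself;
    ``edges`` the child->parent pairs induced within that closure.
    """

    term_id: str
    ancestors: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ancestors", frozenset(self.ancestors))
        object.__setattr__(
            self, "edges", frozenset((str(c), str(p)) for c, p in self.edges)
        )
        if self.term_id not in self.ancestors:
            raise StructureError(f"term {self.term_id!r} missing from its own closure")
        for c, p in self.edges:
            if c not in self.ancestors or p not in self.ancestors:
                raise StructureError(
                    f"edge ({c!r}, {p!r}) leaves the closure of {self.term_id!r}"
                )
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"closure of {self.term_id!r} contains a cycle: {cycle}")


@dataclass
class SimilarityMatrix:
    """Square, symmetric, label-indexed similarity matrix in [0, 1]."""

    values: np.ndarray
    ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = _check_labels(self.ids, "ids")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} != ({n}, {n})"
            )
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix has non-finite entries")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("similarity matrix is not symmetric within 1e-12")
        if np.max(np.abs(np.diag(self.values) - 1.0)) > 1e-12:
            raise ValueError("similarity matrix diagonal must equal 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {x: i for i, x in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        idx = self.index()
        return float(self.values[idx[a], idx[b]])


@dataclass
class ScoreTable:
    """Real-valued disease x miRNA prediction scores plus the training mask."""

    scores: np.ndarray
    disease_ids: list[str]
    mirna_ids: list[str]
    known_mask: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.known_mask = np.asarray(self.known_mask, dtype=float)
        self.disease_ids = _check_labels(self.disease_ids, "disease_ids")
        self.mirna_ids = _check_labels(self.mirna_ids, "mirna_ids")
        shape = (len(self.disease_ids), len(self.mirna_ids))
        if self.scores.shape != shape:
            raise ValueError(f"score matrix shape {self.scores.shape} != {shape}")
        if self.known_mask.shape != self.scores.shape:
            raise ValueError("known_mask shape differs from score matrix shape")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score matrix has non-finite entries")

    def disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.disease_ids)}


@dataclass
class PipelineParams:
    """Tunable parameters of the full prediction pipeline.

    K, r drive the WKNKN completion; phi is the inter-network jump
    probability, delta the sub-network weight (used both for seeding and for
    fusing the two walks), gamma the restart probability; delta_sem the
    per-generation semantic decay; t_max/tol control the walk iteration.
    """

    K: int = 5
    r: float = 0.7
    phi: float = 0.9
    delta: float = 0.7
    gamma: float = 0.7
    delta_sem: float = 0.5
    t_max: int = 10
    tol: float = 0.0
    gamma_prime: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ParameterError(f"K must be a positive integer, got {self.K!r}")
        if not 0 < self.r <= 1:
            raise ParameterError(f"r must lie in (0, 1], got {self.r!r}")
        for name in ("phi", "delta", "gamma", "delta_sem"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1), got {v!r}")
        if not (isinstance(self.t_max, (int, np.integer)) and self.t_max >= 1):
            raise ParameterError(f"t_max must be >= 1, got {self.t_max!r}")
        if self.tol < 0:
            raise ParameterError(f"tol must be >= 0, got {self.tol!r}")
        if self.gamma_prime <= 0:
            raise ParameterError(f"gamma_prime must be > 0, got {self.gamma_prime!r}")
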