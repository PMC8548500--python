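"""Self-contained synthetic fixtures for the full pipeline.

The generator emulates the three external inputs the method consumes —
disease ontology DAGs, miRNA->disease annotation sets, and a sparse binary
association matrix — with a planted co-cluster structure: diseases and
miRNAs are partitioned into blocks, within-block pairs associate densely
and background pairs sparsely, and each block's diseases share an ontology
subtree so the semantic similarity mirrors the planted structure.  Every
artifact is deterministic in the fixture seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .errors import ParameterError
from . import io as hio
from .pipeline import integrated_similarities
from .similarity import disease_semantic_similarity, mirna_functional_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "simulate_disease_dags",
    "simulate_associations",
    "make_fixture",
    "load_fixture",
    "mask_positives",
]


@dataclass
class FixtureSpec:
    """Shape and density of one synthetic study."""

    n_d: int = 60
    n_m: int = 80
    n_blocks: int = 4
    within_block_density: float = 0.3
    background_density: float = 0.01
    dag_depth: int = 3
    annotations_per_mirna: tuple[int, int] = (1, 5)
    delta_sem: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_d < 1 or self.n_m < 1:
            raise ParameterError("n_d and n_m must be >= 1")
        if not 1 <= self.n_blocks <= min(self.n_d, self.n_m):
            raise ParameterError("n_blocks must lie in [1, min(n_d, n_m)]")
        if not 0 < self.within_block_density <= 1:
            raise ParameterError("within_block_density must lie in (0, 1]")
        if not 0 <= self.background_density < self.within_block_density:
            raise ParameterError(
                "background_density must lie in [0, within_block_density)"
            )
        if self.dag_depth < 1:
            raise ParameterError("dag_depth must be >= 1")
        lo, hi = self.annotations_per_mirna
        if not 1 <= lo <= hi:
            raise ParameterError("annotations_per_mirna must be a 1 <= lo <= hi range")


@dataclass
class Fixture:
    """All in-memory artifacts of one generated study."""

    spec: FixtureSpec
    A: AssociationMatrix
    disease_blocks: np.ndarray
    mirna_blocks: np.ndarray
    dags: dict[str, DiseaseDAG]
    dtt: dict[str, set[str]]
    DSS: SimilarityMatrix
    MFS: SimilarityMatrix
    ISD: SimilarityMatrix
    ISM: SimilarityMatrix


def simulate_disease_dags(
    n_d: int,
    dag_depth: int = 3,
    seed: int = 0,
    groups=None,
    disease_ids: list[str] | None = None,
) -> dict[str, DiseaseDAG]:
    """Random ontology forest: one rooted tree per disease group.

    Diseases in the same group hang off a shared subtree (so their semantic
    similarity is positive); different groups share no ancestors.  With
    ``dag_depth=1`` every disease is a singleton DAG.
    """
    rng = np.random.default_rng(seed)
    ids = list(disease_ids) if disease_ids is not None else [f"d{i:03d}" for i in range(n_d)]
    if len(ids) != n_d:
        raise ParameterError("disease_ids length must equal n_d")
    if dag_depth == 1:
        return {d: DiseaseDAG(d, frozenset({d}), frozenset()) for d in ids}
    if groups is None:
        n_groups = max(1, n_d // 8)
        groups = rng.integers(0, n_groups, size=n_d)
    groups = np.asarray(groups)

    dags: dict[str, DiseaseDAG] = {}
    for g in sorted(set(groups.tolist())):
        members = [ids[i] for i in range(n_d) if groups[i] == g]
        levels: list[list[str]] = [[f"anc{g}_0_0"]]
        for lvl in range(1, dag_depth - 1):
            n_nodes = int(rng.integers(1, 3))
            levels.append([f"anc{g}_{lvl}_{k}" for k in range(n_nodes)])
        parent: dict[str, str] = {}
        for lvl in range(1, len(levels)):
            for node in levels[lvl]:
                parent[node] = levels[lvl - 1][rng.integers(0, len(levels[lvl - 1]))]
        internal = [n for lv in levels for n in lv]
        for d in members:
            attach = internal[rng.integers(0, len(internal))]
            ancestors = {d, attach}
            edges = {(d, attach)}
            node = attach
            while node in parent:
                edges.add((node, parent[node]))
                node = parent[node]
                ancestors.add(node)
            dags[d] = DiseaseDAG(d, frozenset(ancestors), frozenset(edges))
    return dags


def simulate_associations(spec: FixtureSpec) -> tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """Planted-block binary matrix; returns (A, disease_blocks, mirna_blocks).

    Contiguous equal-size blocks; a within-block pair is 1 with probability
    ``within_block_density``, any other pair with ``background_density``.
    A generated all-zero row/column is repaired by forcing one within-block
    positive (logged) so every entity is observable by the pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    d_blocks = np.arange(spec.n_d) * spec.n_blocks // spec.n_d
    m_blocks = np.arange(spec.n_m) * spec.n_blocks // spec.n_m
    same = d_blocks[:, None] == m_blocks[None, :]
    density = np.where(same, spec.within_block_density, spec.background_density)
    values = (rng.random((spec.n_d, spec.n_m)) < density).astype(float)

    for i in np.flatnonzero(values.sum(axis=1) == 0):
        cols = np.flatnonzero(m_blocks == d_blocks[i])
        j = cols[rng.integers(0, len(cols))] if len(cols) else rng.integers(0, spec.n_m)
        values[i, j] = 1.0
        logger.info("repaired all-zero disease row %d with positive at column %d", i, j)
    for j in np.flatnonzero(values.sum(axis=0) == 0):
        rows = np.flatnonzero(d_blocks == m_blocks[j])
        i = rows[rng.integers(0, len(rows))] if len(rows) else rng.integers(0, spec.n_d)
        values[i, j] = 1.0
        logger.info("repaired all-zero miRNA column %d with positive at row %d", j, i)

    ids_d = [f"d{i:03d}" for i in range(spec.n_d)]
    ids_m = [f"m{j:03d}" for j in range(spec.n_m)]
    return AssociationMatrix(values, ids_d, ids_m), d_blocks, m_blocks


def make_fixture(spec: FixtureSpec | None = None, outdir=None) -> Fixture:
    """Generate the full bundle (associations, DAGs, DTT sets, similarities).

    Disease-term sets (DTT) are subsampled from each miRNA's planted
    associations; DAG groups align with the planted disease blocks.  With
    ``outdir`` given, every artifact is also serialized in the TSV dialects
    plus a JSON manifest recording the spec and seed.
    """
    spec = spec or FixtureSpec()
    A, d_blocks, m_blocks = simulate_associations(spec)
    dags = simulate_disease_dags(
        spec.n_d,
        spec.dag_depth,
        seed=spec.seed + 1,
        groups=d_blocks,
        disease_ids=A.disease_ids,
    )
    rng = np.random.default_rng(spec.seed + 2)
    lo, hi = spec.annotations_per_mirna
    dtt: dict[str, set[str]] = {}
    for j, m in enumerate(A.mirna_ids):
        assoc = [A.disease_ids[i] for i in np.flatnonzero(A.values[:, j])]
        n_terms = min(len(assoc), int(rng.integers(lo, hi + 1)))
        chosen = rng.choice(len(assoc), size=max(1, n_terms), replace=False)
        dtt[m] = {assoc[k] for k in chosen}

    DSS = disease_semantic_similarity(dags, spec.delta_sem, ids=A.disease_ids)
    MFS = mirna_functional_similarity(dtt, DSS, ids=A.mirna_ids)
    ISD, ISM = integrated_similarities(A, DSS, MFS)
    fixture = Fixture(spec, A, d_blocks, m_blocks, dags, dtt, DSS, MFS, ISD, ISM)
    if outdir is not None:
        _write_fixture(fixture, Path(outdir))
    return fixture


def _write_fixture(fx: Fixture, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pos = np.argwhere(fx.A.values == 1)
    with open(outdir / "associations.tsv", "w", encoding="utf-8") as fh:
        for i, j in pos:
            fh.write(f"{fx.A.disease_ids[i]}\t{fx.A.mirna_ids[j]}\n")
    edges = sorted({e for dag in fx.dags.values() for e in dag.edges})
    with open(outdir / "dag_edges.tsv", "w", encoding="utf-8") as fh:
        for c, p in edges:
            fh.write(f"{c}\t{p}\n")
    with open(outdir / "mirna_disease_terms.tsv", "w", encoding="utf-8") as fh:
        for m in fx.A.mirna_ids:
            for d in sorted(fx.dtt[m]):
                fh.write(f"{m}\t{d}\n")
    hio.write_association_matrix(outdir / "association_matrix.tsv", fx.A)
    hio.write_similarity(outdir / "DSS.tsv", fx.DSS)
    hio.write_similarity(outdir / "MFS.tsv", fx.MFS)
    hio.write_similarity(outdir / "ISD.tsv", fx.ISD)
    hio.write_similarity(outdir / "ISM.tsv", fx.ISM)
    manifest = asdict(fx.spec)
    manifest["annotations_per_mirna"] = list(manifest["annotations_per_mirna"])
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_fixture(outdir) -> Fixture:
    """Rebuild a Fixture from a directory written by :func:`make_fixture`."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    manifest["annotations_per_mirna"] = tuple(manifest["annotations_per_mirna"])
    spec = FixtureSpec(**manifest)
    A = hio.read_association_matrix(outdir / "association_matrix.tsv")
    all_dags = hio.read_dag_edges(outdir / "dag_edges.tsv")
    dags = {d: all_dags[d] for d in A.disease_ids if d in all_dags}
    dtt: dict[str, set[str]] = {}
    with open(outdir / "mirna_disease_terms.tsv", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                m, d = line.rstrip("\n").split("\t")
                dtt.setdefault(m, set()).add(d)
    DSS = hio.read_similarity(outdir / "DSS.tsv", kind="semantic")
    MFS = hio.read_similarity(outdir / "MFS.tsv", kind="functional")
    ISD = hio.read_similarity(outdir / "ISD.tsv", kind="integrated")
    ISM = hio.read_similarity(outdir / "ISM.tsv", kind="integrated")
    d_blocks = np.arange(spec.n_d) * spec.n_blocks // spec.n_d
    m_blocks = np.arange(spec.n_m) * spec.n_blocks // spec.n_m
    return Fixture(spec, A, d_blocks, m_blocks, dags, dtt, DSS, MFS, ISD, ISM)


def mask_positives(
    A: AssociationMatrix, fraction: float, seed: int = 0
) -> tuple[AssociationMatrix, np.ndarray]:
    """Hide a random fraction of the known positives; returns (A_train, hidden).

    ``hidden`` is the (k, 2) index array of the masked pairs.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction!r}")
    rng = np.random.default_rng(seed)
    pos = np.argwhere(A.values == 1)
    k = max(1, int(round(fraction * len(pos))))
    hidden = pos[rng.choice(len(pos), size=k, replace=False)]
    values = A.values.copy()
    values[hidden[:, 0], hidden[:, 1]] = 0.0
    return AssociationMatrix(values, list(A.disease_ids), list(A.mirna_ids)), hidden
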