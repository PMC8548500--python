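"""Readers and writers for the tab-separated formats the pipeline touches.

Formats
-------
* association list: 2-column TSV ``disease_id<TAB>mirna_id`` (header optional,
  controlled by a flag, never guessed);
* ontology edges: 2-column TSV ``child_id<TAB>parent_id``;
* labelled matrix: TSV with column labels in the first row and row labels in
  the first column; floats serialized with 17 significant digits so a
  write-then-read round trip is bit-stable in practice;
* ranked predictions: TSV ``rank / mirna_id / score / known_flag``.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .containers import AssociationMatrix, DiseaseDAG, ScoreTable, SimilarityMatrix
from .errors import CycleError, LabelError, ParseError

__all__ = [
    "read_associations",
    "read_dag_edges",
    "read_matrix",
    "write_matrix",
    "read_association_matrix",
    "write_association_matrix",
    "read_similarity",
    "write_similarity",
    "rank_mirnas",
    "write_ranked_predictions",
]

_FLOAT_FMT = "%.17g"


def _read_pair_lines(path, what: str) -> list[tuple[str, str]]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields "
                    f"for {what}, got {len(fields)}"
                )
            a, b = (f.strip() for f in fields)
            if not a or not b:
                raise ParseError(f"{path}: line {lineno}: empty field")
            pairs.append((a, b))
    return pairs


def read_associations(
    path,
    all_diseases: list[str] | None = None,
    all_mirnas: list[str] | None = None,
    header: bool = False,
) -> AssociationMatrix:
    """Read a disease/miRNA pair list into a binary association matrix.

    Row and column order follow first appearance in the file unless explicit
    label universes are supplied.  Duplicate pairs collapse to a single 1.
    """
    pairs = _read_pair_lines(path, "an association pair")
    if header:
        pairs = pairs[1:]
    if not pairs:
        raise ParseError(f"{path}: no association pairs found")

    if all_diseases is None:
        diseases = list(dict.fromkeys(d for d, _ in pairs))
    else:
        diseases = list(all_diseases)
    if all_mirnas is None:
        mirnas = list(dict.fromkeys(m for _, m in pairs))
    else:
        mirnas = list(all_mirnas)

    di = {d: i for i, d in enumerate(diseases)}
    mi = {m: j for j, m in enumerate(mirnas)}
    values = np.zeros((len(diseases), len(mirnas)))
    for d, m in pairs:
        if d not in di:
            raise LabelError(f"{path}: disease {d!r} not in the supplied universe")
        if m not in mi:
            raise LabelError(f"{path}: miRNA {m!r} not in the supplied universe")
        values[di[d], mi[m]] = 1.0
    return AssociationMatrix(values, diseases, mirnas)


def read_dag_edges(path) -> dict[str, DiseaseDAG]:
    """Read child->parent edges and build every term's ancestor closure."""
    edges = _read_pair_lines(path, "a child/parent edge")
    g = nx.DiGraph()
    for c, p in edges:
        g.add_edge(c, p)
    for c, _ in edges:
        g.add_node(c)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError(f"{path}: ontology edges contain a cycle: {cycle}")

    dags: dict[str, DiseaseDAG] = {}
    for term in g.nodes:
        closure = set(nx.descendants(g, term)) | {term}
        induced = {
            (c, p) for c, p in g.edges if c in closure and p in closure
        }
        dags[term] = DiseaseDAG(term, frozenset(closure), frozenset(induced))
    return dags


def write_matrix(path, values: np.ndarray, row_ids: list[str], col_ids: list[str]) -> None:
    values = np.asarray(values, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id", *col_ids]) + "\n")
        for label, row in zip(row_ids, values):
            cells = "\t".join(_FLOAT_FMT % v for v in row)
            fh.write(f"{label}\t{cells}\n")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled TSV matrix; returns (values, row_ids, col_ids)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    col_ids = lines[0].split("\t")[1:]
    if not col_ids:
        raise ParseError(f"{path}: header row has no column labels")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(col_ids) + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {len(col_ids) + 1} fields, "
                f"got {len(fields)} (ragged row)"
            )
        row_ids.append(fields[0])
        row = []
        for j, cell in enumerate(fields[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, column {col_ids[j]!r}: "
                    f"non-numeric cell {cell!r}"
                ) from None
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: matrix has no data rows")
    return np.array(rows), row_ids, col_ids


def write_association_matrix(path, A: AssociationMatrix) -> None:
    write_matrix(path, A.values, A.disease_ids, A.mirna_ids)


def read_association_matrix(path) -> AssociationMatrix:
    values, rows, cols = read_matrix(path)
    return AssociationMatrix(values, rows, cols)


def write_similarity(path, sim: SimilarityMatrix) -> None:
    write_matrix(path, sim.values, sim.ids, sim.ids)


def read_similarity(path, kind: str = "integrated") -> SimilarityMatrix:
    values, rows, cols = read_matrix(path)
    if rows != cols:
        raise LabelError(f"{path}: row labels differ from column labels")
    return SimilarityMatrix(values, rows, kind=kind)


def rank_mirnas(table: ScoreTable, disease: str, top_n: int | None = None):
    """Rank one disease's candidate miRNAs by score (desc), label (asc).

    Returns a list of ``(rank, mirna_id, score, known_flag)`` tuples.
    """
    idx = table.disease_index()
    if disease not in idx:
        raise LabelError(f"unknown disease label {disease!r}")
    i = idx[disease]
    entries = sorted(
        zip(table.mirna_ids, table.scores[i], table.known_mask[i]),
        key=lambda t: (-t[1], t[0]),
    )
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        entries = entries[:top_n]
    return [
        (rank, m, float(s), int(k))
        for rank, (m, s, k) in enumerate(entries, start=1)
    ]


def write_ranked_predictions(path, table: ScoreTable, disease: str, top_n: int) -> None:
    rows = rank_mirnas(table, disease, top_n)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmirna_id\tscore\tknown_flag\n")
        for rank, m, s, k in rows:
            fh.write(f"{rank}\t{m}\t{_FLOAT_FMT % s}\t{k}\n")
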