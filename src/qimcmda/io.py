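"""Readers and writers for the tabular inputs and the ranked-score output.

File formats (all UTF-8, tab-separated, labels only — never indices):

* associations.tsv — ``disease<TAB>miRNA`` pairs, optional ``#`` header.
* similarity.tsv — square table; first row and column are labels; missing
  entries encoded by a configurable token (default ``NA``).
* dags.tsv — ``disease_id<TAB>node_id<TAB>parent_id``; parent ``-`` marks
  a DAG root row.
* scores output — ``disease<TAB>miRNA<TAB>score<TAB>rank``.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import AssociationMatrix, DagTable, SimilarityMatrix

logger = logging.getLogger(__name__)

ROOT_MARKER = "-"


def read_associations(path: str | os.PathLike) -> AssociationMatrix:
    """Read a two-column (disease, miRNA) pair list into a binary matrix.

    ``A[i, j] = 1`` iff the pair appears at least once.  Labels are ordered
    by first appearance; duplicate pairs collapse to a single association.
    """
    path = Path(path)
    diseases: dict[str, int] = {}
    mirnas: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            d, m = fields[0].strip(), fields[1].strip()
            i = diseases.setdefault(d, len(diseases))
            j = mirnas.setdefault(m, len(mirnas))
            if (i, j) in pairs:
                n_dup += 1
            else:
                pairs.add((i, j))
    if n_dup:
        logger.info("collapsed %d duplicate association pairs", n_dup)
    values = np.zeros((len(diseases), len(mirnas)))
    for i, j in pairs:
        values[i, j] = 1.0
    return AssociationMatrix(values, list(diseases), list(mirnas))


def write_associations(assoc: AssociationMatrix, path: str | os.PathLike) -> None:
    """Write the known pairs back out as a two-column list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#disease\tmiRNA\n")
        for d, m in assoc.pairs():
            fh.write(f"{d}\t{m}\n")


def read_similarity(path: str | os.PathLike, missing_token: str = "NA") -> SimilarityMatrix:
    """Read a square labelled similarity table with missing-entry masking.

    Cells equal to ``missing_token`` are marked unobserved.  Observed values
    must lie in [0, 1]; asymmetric observed pairs are symmetrized by
    averaging (warning when the discrepancy exceeds 1e-6).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    names = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != names:
        raise ValueError(f"{path}: similarity table must be square with matching labels")
    raw = df.to_numpy()
    mask = raw != missing_token
    values = np.zeros(raw.shape)
    obs = np.asarray(
        [float(v) for v in raw[mask]] if mask.any() else [], dtype=float
    )
    values[mask] = obs
    if obs.size and (obs.min() < 0 or obs.max() > 1):
        raise ValueError(f"{path}: observed similarity outside [0, 1]")
    if not np.array_equal(mask, mask.T):
        raise ValueError(f"{path}: observation pattern is not symmetric")
    asym = np.abs(values - values.T)[mask & mask.T]
    if asym.size and asym.max() > 1e-6:
        logger.warning("asymmetric similarity entries (max |diff| = %.3g); averaging", asym.max())
    values = np.where(mask, (values + values.T) / 2.0, 0.0)
    return SimilarityMatrix(values, names, mask)


def write_similarity(sim: SimilarityMatrix, path: str | os.PathLike,
                     missing_token: str = "NA", fmt: str = "%.10g") -> None:
    """Write a similarity matrix as a labelled square table, masking unobserved cells."""
    cells = np.where(sim.mask, np.char.mod(fmt, sim.values), missing_token)
    df = pd.DataFrame(cells, index=sim.names, columns=sim.names)
    df.to_csv(path, sep="\t")


def read_dags(path: str | os.PathLike) -> DagTable:
    """Read per-disease DAG edge lists.

    Each row is ``disease_id, node_id, parent_id``; parent ``-`` marks the
    root rows.  Acyclicity and parent resolution are verified per disease.
    """
    path = Path(path)
    records: dict[str, list[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            d, node, parent = (f.strip() for f in fields)
            records.setdefault(d, []).append((node, parent))
    table = DagTable()
    for disease, rows in records.items():
        g = nx.DiGraph()
        nodes = {node for node, _ in rows}
        for node, parent in rows:
            g.add_node(node)
            if parent != ROOT_MARKER:
                if parent not in nodes:
                    raise ValueError(
                        f"disease {disease!r}: node {node!r} references missing parent {parent!r}"
                    )
                g.add_edge(parent, node)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"cycle detected in DAG of disease {disease!r}")
        table.dags[disease] = g
    table.validate()
    return table


def write_dags(table: DagTable, path: str | os.PathLike) -> None:
    """Write per-disease DAGs in the three-column edge-list format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#disease\tnode\tparent\n")
        for disease, g in table.dags.items():
            for node in g.nodes:
                parents = list(g.predecessors(node))
                if not parents:
                    fh.write(f"{disease}\t{node}\t{ROOT_MARKER}\n")
                for p in parents:
                    fh.write(f"{disease}\t{node}\t{p}\n")


def write_scores(scores: np.ndarray, known: AssociationMatrix,
                 path: str | os.PathLike, top_k: int,
                 disease_names: list[str] | None = None,
                 mirna_names: list[str] | None = None) -> None:
    """Write, per disease, the top-k candidate miRNAs by descending score.

    Known positives are excluded from the candidate list, so ranked output
    contains only novel predictions — training pairs never appear.
    """
    disease_names = disease_names or known.disease_names
    mirna_names = mirna_names or known.mirna_names
    scores = np.asarray(scores, dtype=float)
    if scores.shape != known.values.shape:
        raise ValueError("score matrix shape does not match the association matrix")
    if disease_names != known.disease_names or mirna_names != known.mirna_names:
        raise ValueError("label mismatch between scores and known associations")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#disease\tmiRNA\tscore\trank\n")
        for i, d in enumerate(disease_names):
            cand = np.nonzero(known.values[i] == 0)[0]
            order = cand[np.argsort(-scores[i, cand], kind="stable")][:top_k]
            for rank, j in enumerate(order, start=1):
                fh.write(f"{d}\t{mirna_names[j]}\t{scores[i, j]:.10g}\t{rank}\n")
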