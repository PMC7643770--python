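"""DAG-based disease semantic similarity.

Two complementary models over a disease's MeSH-style ancestor DAG:

* **Model 1** decays each node's contribution geometrically with its distance
  from the disease: the disease's own node contributes 1, and every other
  node contributes ``delta * max(contribution of its children)``.
* **Model 2** weights each node by its specificity across the whole DAG
  family: ``-ln(#DAGs containing the node / #diseases)``, so terms shared by
  many diseases contribute little and rare terms contribute much.

Either model scores a disease pair by the contributions of their shared DAG
nodes, normalized by the two semantic values, giving a similarity in [0, 1].
The integrated disease semantic similarity SS is the average of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import DagTable, SimilarityMatrix


@dataclass(frozen=True)
class SemanticParams:
    """Semantic similarity knobs.

    delta: semantic contribution factor in (0, 1]; each edge away from the
        disease multiplies a node's model-1 contribution by delta.
    """

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")


def d1_contributions(table: DagTable, disease: str,
                     params: SemanticParams = SemanticParams()) -> dict[str, float]:
    """Model-1 contribution of every node in T(disease) to the disease.

    The disease node scores 1; an ancestor scores ``delta`` times the best
    score among its children, i.e. ``delta ** (shortest hop distance)``
    under the max rule.  Computed by one reverse-topological sweep.
    """
    g = table.dags[disease]
    contrib: dict[str, float] = {}
    # children of a node are its successors in the parent->child orientation
    for node in reversed(list(nx.topological_sort(g))):
        if node == disease:
            contrib[node] = 1.0
            continue
        children = [c for c in g.successors(node) if c in contrib]
        if not children:
            raise ValueError(
                f"node {node!r} in DAG of {disease!r} has no path to the disease"
            )
        contrib[node] = params.delta * max(contrib[c] for c in children)
    return contrib


def d2_contributions(table: DagTable, disease: str) -> dict[str, float]:
    """Model-2 contribution: -ln(frequency of the node across all DAGs).

    Frequency is (#DAGs containing the node) / (#diseases in the table);
    a node present in every DAG contributes 0, rare nodes contribute more.
    """
    if not len(table):
        raise ValueError("empty DAG table")
    n_diseases = len(table)
    contrib: dict[str, float] = {}
    for node in table.node_set(disease):
        count = sum(1 for d in table.dags.values() if node in d)
        if count == 0:
            raise RuntimeError(f"node {node!r} missing from every DAG")
        contrib[node] = -float(np.log(count / n_diseases))
    return contrib


def semantic_value(contrib: dict[str, float]) -> float:
    """Semantic value of a disease: the sum of its node contributions (DV1/DV2)."""
    if not contrib:
        raise ValueError("empty contribution map")
    return float(sum(contrib.values()))


def _pair_similarity(ci: dict[str, float], cj: dict[str, float]) -> float:
    shared = set(ci) & set(cj)
    denom = semantic_value(ci) + semantic_value(cj)
    if denom == 0:
        raise ValueError("degenerate pair: both semantic values are zero")
    return sum(ci[t] + cj[t] for t in shared) / denom


def semantic_similarity(table: DagTable, i: str, j: str, model: int = 1,
                        params: SemanticParams = SemanticParams()) -> float:
    """Semantic similarity between two diseases under model 1 or 2.

    Score = sum over shared DAG nodes of both contributions, divided by the
    sum of the two semantic values; symmetric and in [0, 1].
    """
    if model == 1:
        ci = d1_contributions(table, i, params)
        cj = d1_contributions(table, j, params)
    elif model == 2:
        ci = d2_contributions(table, i)
        cj = d2_contributions(table, j)
    else:
        raise ValueError("model must be 1 or 2")
    return _pair_similarity(ci, cj)


def build_ss(table: DagTable, params: SemanticParams = SemanticParams(),
             diseases: list[str] | None = None) -> SimilarityMatrix:
    """Integrated disease semantic similarity SS = (SS1 + SS2) / 2.

    ``diseases`` fixes the output ordering (defaults to the table's order).
    Diseases without a DAG record get fully masked rows/columns; the q-kernel
    integration later supplies their similarity.
    """
    if not len(table):
        raise ValueError("empty DAG table")
    names = list(diseases) if diseases is not None else table.diseases
    n = len(names)
    values = np.zeros((n, n))
    has_dag = np.array([d in table for d in names])
    mask = np.outer(has_dag, has_dag)

    present = [d for d in names if d in table]
    c1 = {d: d1_contributions(table, d, params) for d in present}
    c2 = {d: d2_contributions(table, d) for d in present}
    dv2_zero = {d for d in present if semantic_value(c2[d]) == 0}

    idx = {d: k for k, d in enumerate(names)}
    for a, di in enumerate(present):
        for dj in present[a:]:
            i, j = idx[di], idx[dj]
            if di == dj:
                values[i, j] = 1.0
                continue
            ss1 = _pair_similarity(c1[di], c1[dj])
            # DV2 can vanish when every shared term is ubiquitous; treat the
            # model-2 score for such pairs as 0 rather than 0/0.
            if di in dv2_zero and dj in dv2_zero:
                ss2 = 0.0
            else:
                ss2 = _pair_similarity(c2[di], c2[dj])
            values[i, j] = values[j, i] = (ss1 + ss2) / 2.0
    return SimilarityMatrix(values, names, mask)
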