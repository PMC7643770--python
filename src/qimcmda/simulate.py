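"""Seeded synthetic inputs: planted low-rank associations, toy DAG families,
and partially observed functional similarity.

The generators emulate the three real inputs of the pipeline — a verified
disease-miRNA association list, MeSH-derived disease DAGs, and a MISIM-style
miRNA functional similarity matrix observed only in part — so every stage is
testable without external downloads.  The planted latent matrix is returned
alongside the binary associations so tests can score recovery against the
ground truth and not only against held-out ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import AssociationMatrix, DagTable, SimilarityMatrix


@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic-study conditions.

    Defaults give a 20 x 30 planted rank-2 problem at density 0.1 — small
    enough that a full LOOCV (~60 refits) runs in seconds — with functional
    similarity observed on 20.58% of entries, matching the completeness of
    the real miRNA functional-similarity network.
    """

    nd: int = 20
    nm: int = 30
    planted_rank: int = 2
    density: float = 0.1
    fs_coverage: float = 0.2058
    dag_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nd < 1 or self.nm < 1:
            raise ValueError("nd and nm must be positive")
        if not 1 <= self.planted_rank <= min(self.nd, self.nm):
            raise ValueError("planted_rank must lie in [1, min(nd, nm)]")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.fs_coverage <= 1:
            raise ValueError("fs_coverage must lie in [0, 1]")
        if self.dag_depth < 0:
            raise ValueError("dag_depth must be >= 0")


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{k + 1}" for k in range(n)]


def generate_planted_associations(spec: FixtureSpec
                                  ) -> tuple[AssociationMatrix, np.ndarray]:
    """Binary association matrix planted on a low-rank latent score matrix.

    Draws nonnegative factors U (nd x r) and V (r x nm), forms L = U @ V and
    marks the top ``density * nd * nm`` entries of L as associations (ties
    broken by seeded jitter), so A carries recoverable low-rank structure.
    Returns the association matrix and the latent L.
    """
    n_ones = int(round(spec.density * spec.nd * spec.nm))
    if n_ones < 1:
        raise ValueError("density * nd * nm must be at least 1")
    rng = np.random.default_rng(spec.seed)
    U = rng.uniform(size=(spec.nd, spec.planted_rank))
    V = rng.uniform(size=(spec.planted_rank, spec.nm))
    L = U @ V
    jitter = rng.uniform(0, 1e-9, size=L.shape)
    order = np.argsort(-(L + jitter), axis=None)
    values = np.zeros(spec.nd * spec.nm)
    values[order[:n_ones]] = 1.0
    A = AssociationMatrix(values.reshape(spec.nd, spec.nm),
                          _names("disease", spec.nd), _names("mirna", spec.nm))
    return A, L


def generate_dag_family(spec: FixtureSpec, latent: np.ndarray | None = None) -> DagTable:
    """Toy MeSH-like DAG family: a shared random ancestor forest.

    A forest of ancestor chains of depth ``dag_depth`` is drawn once; each
    disease attaches below a node of the forest and its DAG is the ancestor
    closure.  When the planted latent matrix is supplied, diseases with
    similar latent rows attach to the same branch, so semantically related
    diseases share more ancestors.  ``dag_depth = 0`` yields singleton DAGs.
    """
    rng = np.random.default_rng(spec.seed + 1)
    diseases = _names("disease", spec.nd)
    table = DagTable()
    if spec.dag_depth == 0:
        for d in diseases:
            g = nx.DiGraph()
            g.add_node(d)
            table.dags[d] = g
        return table

    # branches of the shared forest: chains anc_b_1 (root) -> ... -> anc_b_depth
    n_branches = max(2, spec.nd // 4)
    chains = [[f"anc{b}_{lvl}" for lvl in range(spec.dag_depth)]
              for b in range(n_branches)]
    if latent is not None:
        # diseases with similar latent weight share a branch
        branch_of = (np.argsort(np.argsort(latent.sum(axis=1))) * n_branches
                     // spec.nd)
    else:
        branch_of = rng.integers(0, n_branches, size=spec.nd)
    attach_depth = rng.integers(1, spec.dag_depth + 1, size=spec.nd)
    for i, d in enumerate(diseases):
        chain = chains[int(branch_of[i]) % n_branches]
        g = nx.DiGraph()
        depth = int(attach_depth[i])
        for lvl in range(depth):
            g.add_node(chain[lvl])
            if lvl > 0:
                g.add_edge(chain[lvl - 1], chain[lvl])
        g.add_edge(chain[depth - 1], d)
        table.dags[d] = g
    table.validate()
    return table


def generate_masked_fs(spec: FixtureSpec, latent: np.ndarray) -> SimilarityMatrix:
    """Partially observed functional similarity from latent miRNA profiles.

    FS(i, j) is the cosine similarity of latent columns i and j (nonnegative
    factors keep it in [0, 1]); a seeded symmetric mask retains
    ``fs_coverage`` of the off-diagonal entries, the diagonal always
    observed at 1.
    """
    latent = np.asarray(latent, dtype=float)
    rng = np.random.default_rng(spec.seed + 2)
    norms = np.linalg.norm(latent, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    X = latent / norms
    fs = np.clip(X.T @ X, 0.0, 1.0)
    np.fill_diagonal(fs, 1.0)
    nm = latent.shape[1]
    upper = rng.uniform(size=(nm, nm)) < spec.fs_coverage
    mask = np.triu(upper, k=1)
    mask = mask | mask.T
    np.fill_diagonal(mask, True)
    return SimilarityMatrix(np.where(mask, fs, 0.0), _names("mirna", nm), mask)


def generate_fixture(spec: FixtureSpec
                     ) -> tuple[AssociationMatrix, SimilarityMatrix, DagTable, np.ndarray]:
    """Full co-generated fixture: associations, masked FS, DAG family, latent L."""
    A, L = generate_planted_associations(spec)
    fs = generate_masked_fs(spec, L)
    dags = generate_dag_family(spec, L)
    return A, fs, dags, L
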