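"""Core containers: association matrix, similarity matrix, disease DAG table."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

_SYM_TOL = 1e-8


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA adjacency matrix with row/column labels.

    ``values[i, j] == 1`` iff disease ``disease_names[i]`` has a verified
    association with miRNA ``mirna_names[j]``.
    """

    values: np.ndarray
    disease_names: list[str]
    mirna_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        nd, nm = self.values.shape
        if nd != len(self.disease_names) or nm != len(self.mirna_names):
            raise ValueError("matrix shape does not match label lists")
        if len(set(self.disease_names)) != nd or len(set(self.mirna_names)) != nm:
            raise ValueError("duplicate labels")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def density(self) -> float:
        """Fraction of known associations among all disease-miRNA pairs."""
        nd, nm = self.values.shape
        if nd * nm == 0:
            return 0.0
        return float(self.values.sum()) / (nd * nm)

    def pairs(self) -> list[tuple[str, str]]:
        """Known (disease, miRNA) pairs in row-major order."""
        ii, jj = np.nonzero(self.values)
        return [(self.disease_names[i], self.mirna_names[j]) for i, j in zip(ii, jj)]


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative similarity matrix with an optional observation mask.

    The mask marks which entries are observed; unobserved entries carry no
    meaning and downstream integration supplies a kernel-derived fallback.
    A fully observed matrix has ``mask`` of all True.
    """

    values: np.ndarray
    names: list[str]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match labels")
        if self.mask is None:
            self.mask = np.ones((n, n), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n, n):
                raise ValueError("mask shape mismatch")
            if not np.array_equal(self.mask, self.mask.T):
                raise ValueError("mask must be symmetric")
        obs = self.values[self.mask]
        if obs.size:
            if not np.allclose(self.values * self.mask, (self.values * self.mask).T, atol=_SYM_TOL):
                raise ValueError("observed similarities must be symmetric")
            if obs.min() < -_SYM_TOL or obs.max() > 1 + _SYM_TOL:
                raise ValueError("observed similarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def fully_observed(self) -> bool:
        return bool(self.mask.all())

    @property
    def coverage(self) -> float:
        """Fraction of observed entries (the 'integrity' of the network)."""
        return float(self.mask.mean()) if self.mask.size else 1.0

    def reindex(self, names: list[str]) -> "SimilarityMatrix":
        """Reorder (and subset) rows/columns to a given label order."""
        missing = [n for n in names if n not in self.names]
        if missing:
            raise ValueError(f"labels absent from similarity matrix: {missing[:5]}")
        pos = [self.names.index(n) for n in names]
        ix = np.ix_(pos, pos)
        return SimilarityMatrix(self.values[ix], list(names), self.mask[ix])


@dataclass
class DagTable:
    """One ancestor DAG per disease, parsed from (disease, node, parent) records.

    ``dags[d]`` is a directed graph with edges parent -> child; the node set
    is T(d), the ancestor closure of d including d itself.
    """

    dags: dict[str, nx.DiGraph] = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return list(self.dags)

    def node_set(self, disease: str) -> set[str]:
        """T(disease): the disease plus all its DAG ancestors."""
        return set(self.dags[disease].nodes)

    def __len__(self) -> int:
        return len(self.dags)

    def __contains__(self, disease: str) -> bool:
        return disease in self.dags

    def validate(self) -> None:
        """Check acyclicity and that each DAG terminates at its own disease."""
        for disease, g in self.dags.items():
            if not nx.is_directed_acyclic_graph(g):
                raise ValueError(f"cycle detected in DAG of disease {disease!r}")
            if disease not in g:
                raise ValueError(f"DAG of {disease!r} does not contain the disease node")
            sinks = [n for n in g if g.out_degree(n) == 0]
            if sinks != [disease] and set(sinks) != {disease}:
                raise ValueError(
                    f"DAG of {disease!r} must have the disease as its single terminal node"
                )
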