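"""q-kernel interaction-profile similarity and similarity integration.

An entity's interaction profile is its row (disease) or column (miRNA) of
the binary association matrix.  Pairwise profile distances come from the
q-analog of the inverse multiquadric kernel,

    H_q(x, y) = (1/(1-q)) * (q**(-1/c) - q**(-1/sqrt(||x-y||^2 + c^2))),

which vanishes exactly at x = y and grows monotonically with ||x - y|| for
q in (0, 1).  Distances are min-max scaled to [0, 1] over off-diagonal
pairs and flipped (similarity = 1 - scaled distance), giving the fully
observed kernel similarity matrices QM (miRNAs) and QD (diseases).  These
are blended with externally known similarity (functional similarity FS for
miRNAs, semantic similarity SS for diseases) where that is observed:

    S = omega * known + (1 - omega) * kernel   where known is observed,
    S = kernel                                 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QKernelParams:
    """Kernel shape (c, q) and integration weight omega.

    Defaults are the trained values c=0.1, q=0.6, omega=0.01; omega weights
    the externally known similarity against the kernel similarity.
    """

    c: float = 0.1
    q: float = 0.6
    omega: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.c <= 1:
            raise ValueError("c must lie in (0, 1]")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1); q cannot equal 1")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")


def qkernel_distance(x: np.ndarray, y: np.ndarray, params: QKernelParams) -> float:
    """Inverse-multiquadric q-kernel distance between two profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    d = float(np.linalg.norm(x - y))
    return _hq_from_norm(np.array(d), params).item()


def _hq_from_norm(d: np.ndarray, params: QKernelParams) -> np.ndarray:
    c, q = params.c, params.q
    s = np.sqrt(d * d + c * c)
    return (q ** (-1.0 / c) - q ** (-1.0 / s)) / (1.0 - q)


def qkernel_similarity_matrix(profiles: np.ndarray, names: list[str],
                              params: QKernelParams) -> SimilarityMatrix:
    """Pairwise q-kernel similarity of interaction profiles (rows).

    Distances are min-max scaled to [0, 1] over off-diagonal pairs, then
    similarity = 1 - scaled distance; the diagonal is 1 and the result is
    fully observed.  When all pairwise distances coincide (e.g. identical
    profiles in a degenerate training fold) the similarity is all ones.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profiles")
    dist = _hq_from_norm(pdist(profiles), params)
    lo, hi = dist.min(), dist.max()
    if hi - lo <= 0:
        logger.warning("degenerate q-kernel normalization (all distances equal); "
                       "returning all-ones similarity")
        return SimilarityMatrix(np.ones((profiles.shape[0],) * 2), names)
    sim = 1.0 - squareform((dist - lo) / (hi - lo))
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, names)


def integrate_similarity(base: SimilarityMatrix, kernel: SimilarityMatrix,
                         omega: float) -> SimilarityMatrix:
    """Blend observed external similarity with kernel similarity.

    Observed entries of ``base`` become ``omega*base + (1-omega)*kernel``;
    unobserved entries fall back to the kernel value.  The output is fully
    observed, symmetric, with unit diagonal.
    """
    if base.names != kernel.names:
        raise ValueError("label mismatch between base and kernel similarity")
    if not kernel.fully_observed:
        raise ValueError("kernel similarity must be fully observed")
    values = np.where(base.mask,
                      omega * base.values + (1.0 - omega) * kernel.values,
                      kernel.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(base.names))


def build_sm_sd(assoc: AssociationMatrix, fs: SimilarityMatrix,
                ss: SimilarityMatrix, params: QKernelParams
                ) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA similarity Sm and disease similarity Sd.

    QM comes from miRNA profiles (columns of A), QD from disease profiles
    (rows of A); Sm blends FS with QM and Sd blends SS with QD, each with
    weight omega on the externally known part.
    """
    if fs.names != assoc.mirna_names:
        raise ValueError("FS labels do not match the association miRNA labels")
    if ss.names != assoc.disease_names:
        raise ValueError("SS labels do not match the association disease labels")
    qm = qkernel_similarity_matrix(assoc.values.T, assoc.mirna_names, params)
    qd = qkernel_similarity_matrix(assoc.values, assoc.disease_names, params)
    sm = integrate_similarity(fs, qm, params.omega)
    sd = integrate_similarity(ss, qd, params.omega)
    return sm, sd
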