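"""Cross-validation protocols: LOOCV and repeated five-fold CV with rank-sum AUC.

Each verified association is treated in turn (LOOCV) or by folds (k-fold)
as a test sample: it is zeroed in the training matrix, the interaction-
profile kernel similarities are rebuilt from the training matrix (so the
held-out label cannot leak through the kernels), the factorization is
refit, and the test pair's score is ranked against all candidate pairs —
pairs with no known association.  AUC uses midranks for ties and equals
the probability that a random test positive outscores a random candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .completion import CompletionParams, fit, predict_scores
from .qkernel import QKernelParams, build_sm_sd
from .types import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings.

    recompute_similarity: rebuild QM/QD from each training matrix (default;
        reusing full-data kernels leaks the held-out label).  FS and SS are
        never recomputed — they derive from external knowledge, not from A.
    max_folds: optional LOOCV subsampling for smoke tests; the resulting
        AUC is an approximation of the full protocol.
    """

    scheme: str = "loocv"
    folds: int = 5
    repetitions: int = 10
    seed: int = 0
    recompute_similarity: bool = True
    max_folds: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("loocv", "kfold"):
            raise ValueError("scheme must be 'loocv' or 'kfold'")
        if self.scheme == "kfold" and self.folds < 2:
            raise ValueError("k-fold CV needs folds >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class CVResult:
    """AUC summary plus per-repetition values and per-test-sample records."""

    auc: float
    per_repetition: list[float] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repetition)) if self.per_repetition else self.auc

    @property
    def std(self) -> float:
        if len(self.per_repetition) < 2:
            return 0.0
        return float(np.std(self.per_repetition, ddof=1))


def compute_auc(positive_scores, candidate_scores) -> float:
    """Rank-sum AUC of test positives against candidates, midranks for ties.

    Equals the probability that a uniformly random test positive outscores a
    uniformly random candidate, counting ties as half.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(candidate_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one candidate score")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float((rank_sum - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _fit_and_score(train: AssociationMatrix, fs: SimilarityMatrix,
                   ss: SimilarityMatrix, sm_full: SimilarityMatrix | None,
                   sd_full: SimilarityMatrix | None, kparams: QKernelParams,
                   cparams: CompletionParams, recompute: bool) -> np.ndarray:
    if recompute or sm_full is None:
        sm, sd = build_sm_sd(train, fs, ss, kparams)
    else:
        sm, sd = sm_full, sd_full
    res = fit(train, sd, sm, cparams)
    return predict_scores(sd, res.W, res.H, sm)


def loocv(assoc: AssociationMatrix, fs: SimilarityMatrix, ss: SimilarityMatrix,
          kparams: QKernelParams = QKernelParams(),
          cparams: CompletionParams = CompletionParams(),
          cv: CVConfig = CVConfig()) -> CVResult:
    """Leave-one-out cross-validation over all known associations.

    Each positive is zeroed in turn, similarities rebuilt from the training
    matrix, the model refit, and the held-out pair ranked against all
    unknown pairs of the training matrix.  The global AUC is the mean of the
    per-held-out-pair AUCs.
    """
    positives = np.argwhere(assoc.values == 1)
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    if cv.max_folds is not None and cv.max_folds < len(positives):
        rng = np.random.default_rng(cv.seed)
        sel = rng.choice(len(positives), size=cv.max_folds, replace=False)
        positives = positives[np.sort(sel)]
        logger.info("LOOCV subsampled to %d of %d folds", cv.max_folds, int(assoc.values.sum()))

    sm_full = sd_full = None
    if not cv.recompute_similarity:
        sm_full, sd_full = build_sm_sd(assoc, fs, ss, kparams)

    candidates_mask = assoc.values == 0
    records = []
    aucs = []
    for i, j in positives:
        train_values = assoc.values.copy()
        train_values[i, j] = 0.0
        train = AssociationMatrix(train_values, assoc.disease_names, assoc.mirna_names)
        Z = _fit_and_score(train, fs, ss, sm_full, sd_full, kparams, cparams,
                           cv.recompute_similarity)
        cand_scores = Z[candidates_mask]
        auc = compute_auc([Z[i, j]], cand_scores)
        aucs.append(auc)
        records.append({"disease": assoc.disease_names[i],
                        "mirna": assoc.mirna_names[j],
                        "score": float(Z[i, j]), "auc": auc})
    return CVResult(auc=float(np.mean(aucs)), per_repetition=[], records=records)


def _partition(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def kfold_cv(assoc: AssociationMatrix, fs: SimilarityMatrix, ss: SimilarityMatrix,
             kparams: QKernelParams = QKernelParams(),
             cparams: CompletionParams = CompletionParams(),
             cv: CVConfig = CVConfig(scheme="kfold")) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Per repetition, positives are partitioned uniformly at random into
    ``folds`` groups; each group is zeroed in turn, similarities rebuilt,
    the model refit, and the group's scores ranked against all unknown
    pairs.  Reports per-repetition AUC (mean over folds) and the mean/std
    (sample std, n-1) over repetitions.
    """
    positives = np.argwhere(assoc.values == 1)
    if cv.folds > len(positives):
        raise ValueError("more folds than known associations")
    candidates_mask = assoc.values == 0

    sm_full = sd_full = None
    if not cv.recompute_similarity:
        sm_full, sd_full = build_sm_sd(assoc, fs, ss, kparams)

    per_rep = []
    records = []
    for rep in range(cv.repetitions):
        seed = cv.seed + rep
        parts = _partition(len(positives), cv.folds, np.random.default_rng(seed))
        while any(len(p) == 0 for p in parts):
            seed += cv.repetitions
            logger.info("empty fold; repartitioning with seed %d", seed)
            parts = _partition(len(positives), cv.folds, np.random.default_rng(seed))
        fold_aucs = []
        for k, test_idx in enumerate(parts):
            test = positives[test_idx]
            train_values = assoc.values.copy()
            train_values[test[:, 0], test[:, 1]] = 0.0
            train = AssociationMatrix(train_values, assoc.disease_names,
                                      assoc.mirna_names)
            Z = _fit_and_score(train, fs, ss, sm_full, sd_full, kparams, cparams,
                               cv.recompute_similarity)
            auc = compute_auc(Z[test[:, 0], test[:, 1]], Z[candidates_mask])
            fold_aucs.append(auc)
            records.append({"repetition": rep, "fold": k,
                            "n_test": int(len(test)), "auc": auc})
        per_rep.append(float(np.mean(fold_aucs)))
    return CVResult(auc=float(np.mean(per_rep)), per_repetition=per_rep,
                    records=records)
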