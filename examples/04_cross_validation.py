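"""Leave-one-out and five-fold cross-validation on a planted fixture.

Each known association is hidden in turn, the interaction-profile kernels
are rebuilt from the training matrix (no leakage of the held-out label),
the factorization refit, and the hidden pair ranked against all unknown
pairs.  A shuffled-label control shows the AUC is structure, not leakage.
"""

import numpy as np

from qimcmda import (CompletionParams, CVConfig, FixtureSpec, QKernelParams,
                     SemanticParams, build_ss, generate_fixture, kfold_cv,
                     loocv)
from qimcmda.types import AssociationMatrix

A, fs, dags, _ = generate_fixture(FixtureSpec(seed=7))
ss = build_ss(dags, SemanticParams(), diseases=A.disease_names)
kp = QKernelParams(c=0.1, q=0.6, omega=0.01)
cp = CompletionParams(rank=2, seed=1)

res = loocv(A, fs, ss, kp, cp, CVConfig(seed=7))
print(f"LOOCV over {len(res.records)} held-out associations: AUC = {res.auc:.4f}")

kf = kfold_cv(A, fs, ss, kp, cp,
              CVConfig(scheme="kfold", folds=5, repetitions=10, seed=7))
print(f"five-fold CV, 10 repetitions: AUC = {kf.mean:.4f} +/- {kf.std:.4f}")

rng = np.random.default_rng(99)
flat = A.values.flatten()
rng.shuffle(flat)
shuffled = AssociationMatrix(flat.reshape(A.shape), A.disease_names, A.mirna_names)
null = loocv(shuffled, fs, ss, kp, cp, CVConfig(seed=7))
print(f"shuffled-label control: AUC = {null.auc:.4f}  (chance is 0.5)")
# an AUC near 1 on planted data and near 0.5 on shuffled data means the
# pipeline recovers real low-rank structure and carries no label leakage
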