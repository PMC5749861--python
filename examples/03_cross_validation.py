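"""Evaluate the model by the three cross-validation protocols.

Runs subsampled global and local leave-one-out rounds and one repeat of
5-fold cross-validation on a small synthetic dataset, printing each AUC.
An AUC of 1 would be perfect ranking of every held-out association; 0.5 is
chance. Local LOOCV ranks only within the held-out pair's disease, so its
candidate sets are much smaller and its AUC is generally lower.
"""

import dataclasses

from lrsslmda import SMALL, Dataset, PipelineConfig, generate
from lrsslmda.evaluation import global_loocv, kfold_cv, local_loocv

assoc, fs, dags, _ = generate(dataclasses.replace(SMALL, holdout_frac=0.0))
dataset = Dataset(assoc=assoc, fs=fs, dags=dags)
cfg = PipelineConfig(max_iter=300, tol=1e-5, seed=0)

g = global_loocv(dataset, cfg, budget=30)
print(f"global LOOCV  (30 subsampled rounds): AUC = {g.auc:.3f}")

l = local_loocv(dataset, cfg, budget=30)
print(f"local LOOCV   (30 subsampled rounds): AUC = {l.auc:.3f}")

kf = kfold_cv(dataset, cfg, k=5, repeats=1, seed=0)
print(f"5-fold CV     (1 repeat):             AUC = {kf.auc:.3f}")
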