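"""Generate a small cluster-structured dataset and train the model.

Prints the learned Laplacian weights (alpha) for both perspectives and the
top predicted candidate miRNAs for the best-annotated disease. The alpha
weights say how much each graph (statistical profile, graph-theoretical
profile, association profile) contributes to the smoothness penalty; the
candidate list is the model's ranking of unconfirmed miRNAs for the
disease, which is the output a user would take to experimental follow-up.
"""

import numpy as np

from lrsslmda import SMALL, Dataset, PipelineConfig, generate, rank_candidates, train_and_score

assoc, fs, dags, held_out = generate(SMALL)
print(f"dataset: {assoc.values.shape[0]} miRNAs x {assoc.values.shape[1]} diseases, "
      f"{assoc.n_pairs} visible associations, {len(held_out)} held out")

model = train_and_score(Dataset(assoc=assoc, fs=fs, dags=dags),
                        PipelineConfig(max_iter=300, tol=1e-5, seed=0))

print("miRNA-side alpha (X1, X2, association graph):",
      np.round(model.mirna_state.alpha, 3))
print("disease-side alpha:", np.round(model.disease_state.alpha, 3))

disease = assoc.diseases.names[int(np.argmax(assoc.values.sum(axis=0)))]
print(f"\ntop 5 candidate miRNAs for {disease} (rank, name, score):")
for rank, name, score in rank_candidates(model.scores, assoc, disease, top=5):
    print(f"  {rank}  {name}  {score:.5f}")
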