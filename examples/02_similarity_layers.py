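"""Build the similarity layers one by one on a toy example.

Shows the disease semantic similarity from ancestor DAGs, the Gaussian
interaction-profile kernel from the association matrix, and their
integration (curated values where defined, kernel elsewhere). The printed
matrices illustrate that two diseases sharing a rare ancestor score high
semantically, while the kernel scores reflect shared association partners.
"""

import numpy as np

from lrsslmda.core_io import DiseaseDAG, NameIndex
from lrsslmda.similarity import (
    gaussian_profile_kernel,
    integrate_similarity,
    semantic_similarity,
)


def chain(disease, ancestors):
    nodes = [disease, *ancestors]
    return DiseaseDAG(disease, frozenset(nodes), frozenset(zip(nodes[:-1], nodes[1:])))


from lrsslmda.pipeline import align_similarity

# three diseases have a curated ancestor DAG; a fourth does not
dags = [
    chain("carcinoma-a", ["carcinomas", "neoplasms"]),
    chain("carcinoma-b", ["carcinomas", "neoplasms"]),
    chain("leukemia-a", ["leukemias", "neoplasms"]),
]
diseases = NameIndex.from_names(
    ["carcinoma-a", "carcinoma-b", "leukemia-a", "leukemia-b"]
)
ss = align_similarity(semantic_similarity(dags), diseases)
print("semantic similarity (NaN marks entries with no DAG information):")
print(np.round(np.where(ss.known_mask, ss.values, np.nan), 3))

# association profiles: rows are diseases, columns miRNAs
profiles = np.array(
    [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1], [0, 0, 1, 1]], dtype=float
)
kd, params = gaussian_profile_kernel(profiles, index=diseases)
print(f"\ninteraction-profile kernel (bandwidth gamma = {params.gamma:.3f}):")
print(np.round(kd.values, 3))

sd = integrate_similarity(ss, kd)
print("\nintegrated similarity (semantic where defined, kernel elsewhere):")
print(np.round(sd.values, 3))
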