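"""Score disease-miRNA associations with the regularized least-squares model.

RLSMDA blends two ridge classifiers — one in miRNA-similarity space, one
in disease-phenotype-similarity space — into a single score matrix
F* = w F_M*^T + (1-w) F_D*, without needing negative training examples.
"""

import pandas as pd

import rwrmtn as rw
from rwrmtn.rlsmda import RLSMDAConfig, rank_for_disease, rlsmda_scores

spec = rw.FixtureSpec(rng_seed=7)
interactions, assoc, _ = rw.plant_module(rw.generate_interactions(spec), spec)
homo = rw.build_homogeneous(interactions)

S_M = rw.similarity_from_homogeneous(homo)
S_D = rw.generate_phenotype_similarity(spec.n_diseases, rng_seed=7, labels=list(assoc))

A = pd.DataFrame(0.0, index=list(assoc), columns=list(S_M.index))
for d in assoc:
    for m in assoc[d] & set(A.columns):
        A.loc[d, m] = 1.0
print(f"association matrix A: {A.shape[0]} diseases x {A.shape[1]} miRNAs, "
      f"{int(A.to_numpy().sum())} known associations")

F = rlsmda_scores(S_M, S_D, A, RLSMDAConfig(eta_M=1.0, eta_D=1.0, w=0.9))
disease = list(assoc)[0]
top = rank_for_disease(F, disease, exclude=assoc[disease])[:5]
print(f"{disease}: top 5 novel candidates by F* score")
for rank, (m, s) in enumerate(top, start=1):
    print(f"  {rank}. {m}  {s:.4f}")
# Higher F* means the classifier places the (disease, miRNA) pair closer
# to the known associations in the blended similarity spaces.
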