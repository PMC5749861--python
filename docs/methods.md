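# Methods

## Problem

Curated miRNA–disease association databases record a few thousand
experimentally supported pairs over hundreds of miRNAs and diseases —
under 3% of the possible pairs — and the remaining pairs are unlabeled,
not negative. The package scores every unobserved pair so that candidate
miRNAs for a disease (or candidate diseases for a miRNA) can be
prioritized for experimental follow-up. The working premise is that
functionally similar miRNAs tend to associate with phenotypically similar
diseases.

## Similarity layers

**Disease semantic similarity (SS).** Each disease is described by the DAG
of its ancestor terms (in real use, derived from MeSH descriptors; the
package consumes pre-extracted per-disease edge lists). A term `t`
contributes `-log(n_t / N)` to a disease's semantic value, where `n_t` is
the number of supplied DAGs containing `t` and `N` the number of diseases
under analysis — a rarer term is more informative. The similarity of two
diseases is their shared contribution mass normalized by the sum of their
semantic values. The score is invariant to the logarithm base (the ratio
cancels it); natural log is used internally. A disease whose every term is
ubiquitous has semantic value 0 and its row is flagged undefined rather
than forced to a number. Membership counts are taken over the disease set
under analysis, not over the whole vocabulary, so contributions are
relative to the corpus being modeled.

**Interaction-profile kernel (KM/KD).** A Gaussian kernel on binary
association profiles, `exp(-gamma * ||IP_i - IP_j||^2)`, with `gamma =
gamma' / mean_i ||IP_i||^2` so the bandwidth adapts to the corpus density;
`gamma' = 1` by default. miRNA profiles are the rows of the association
matrix (length = number of diseases), disease profiles the columns. Inside
any cross-validation round the kernel is computed from the masked training
matrix only, so held-out labels never leak into the similarity layer.

**Integration (SM/SD).** The curated similarity (functional similarity for
miRNAs, semantic similarity for diseases) is used wherever the source
defines the pair; the kernel fills the rest. Undefined cells are tracked
with an explicit mask — an empty cell is not the same as a similarity of
0. External similarity matrices are aligned to the association matrix by
exact name match; unmatched names are logged and fall back to the kernel.

## Feature profiles

Two profiles per side, features scaled to [0,1] across entities after
assembly (constant features map to 0). Scaling is a package decision:
count-scale features (association counts, betweenness) and proportion
features enter one regression and the multiplicative optimizer's
conditioning requires commensurate scales.

* **Statistical profile (18 features):** the entity's association count,
  then mean, standard deviation, min, quartiles (linear interpolation),
  median and max of its similarity row with the diagonal excluded
  (self-similarity of 1 is uninformative), then a 10-bin histogram of the
  row as proportions (bins right-open except the last, so each row's
  histogram block sums to 1).
* **Graph-theoretical profile (51 features):** the similarity matrix is
  thresholded at the mean of all its entries (strict inequality) into an
  unweighted graph; features are the degree, the 10 largest similarity
  values (zero-padded), plain and similarity-weighted means of the 18
  statistical features over the 10 nearest neighbours by similarity value
  (ties by entity index), betweenness (raw pair counts), classical
  closeness within the connected component, eigenvector centrality (Perron
  vector of the full adjacency, zero where it vanishes), and PageRank with
  damping 0.85.

## Graphs and Laplacians

Three kNN graphs per side feed combinatorial Laplacians `L = D - S`: one
per feature profile (cosine similarity between entity feature vectors) and
one over association profiles, where the closeness of two entities is the
maximum integrated similarity between their associated partner groups;
entities without any known association stay isolated in that graph. The
directed top-k relation (k = 10) is OR-symmetrized: the printed neighbour
relation is asymmetric, but a symmetric S is required for a positive
semidefinite Laplacian, and OR avoids isolating nodes at small k. Ties in
the neighbour ranking break by ascending entity index for determinism.

## Model and optimization

For one side with association matrix `Y` (entities x targets), profiles
`X_p` and Laplacians `L_1, L_2, L_MDA`:

    min_{F, G_p >= 0}  ||F - Y||_F^2 + Tr(F' L F)
                       + mu sum_p ||X_p' G_p - F||_F^2
                       + lam sum_p sum_j ||G_p(:,j)||_1^2

with `L = sum_q alpha_q^gamma L_q` and alpha on the simplex. Defaults
`mu = lam = 1`, `gamma = 2`; alpha starts at 1/3 each and each `G_p` at
uniform [0,1] draws from a required seed.

Per outer iteration: (1) each `G_p` takes one multiplicative
auxiliary-function step `G <- G * sqrt((A^-G + B^+) / (A^+G + B^- + eps))`
with `A_p = X_p(mu I - mu^2 P)X_p' + lam 11'`,
`B_p = mu X_p P Y + mu^2 sum_{q!=p} X_p P X_q' G_q`,
`P = (L + (1+m*mu)I)^{-1}` and `eps = 1e-12` — this is the standard
semi-NMF rule for the objective with F eliminated in closed form, and it
cannot increase that objective while preserving nonnegativity; (2) F takes
its exact stationary point `F = P(Y + mu sum_p X_p' G_p)`; (3) alpha takes
its closed-form simplex minimizer, `alpha_q` proportional to
`(1/Tr(F' L_q F))^{1/(gamma-1)}` with per-graph Laplacians in the
numerator (using the combined L there would always return uniform
weights, defeating the weighting's purpose); a zero trace receives all
mass, split uniformly among zero-trace graphs. Because every step is a
block minimization (of the full objective, or of its F-eliminated form,
which lower-bounds it at the subsequent F), the objective recorded at the
end of each iteration is provably non-increasing; the test-suite verifies
this on 100 random instances rather than trusting the derivation. The G
step runs before the F step for exactly this reason; the fixed points are
the same in either order. Convergence is declared at relative objective
change below 1e-6 or 1000 iterations; the trace is always kept for audit.

The system solved for P is strictly diagonally shifted (`L` PSD plus
`(1+m*mu)I`), so it is always well-posed.

## Prediction

Each side's score matrix is `sum_p alpha_p * rownormalize(X_p' G_p)`
(rows summing to zero stay zero; the disease side is transposed back to
miRNA x disease orientation). The Laplacian weight `alpha_MDA` is excluded
by the combination rule, so a perspective's nonzero rows sum to
`alpha_1 + alpha_2 < 1`; the package does not renormalize (faithful to the
published rule) but exposes `renormalize_alpha` for sensitivity analysis.
The final score follows three scenarios: a miRNA with no known associated
disease is scored from the miRNA perspective, a disease with no known
associated miRNA from the disease perspective, otherwise the average of
the two. The rule does not cover a pair where both sides are new; the
miRNA-perspective clause applies first (document order) and a warning is
logged. Candidate rankings exclude known pairs and break ties by entity
index.

## Evaluation protocols

Held-out associations are ranked against candidates and the ROC sweeps a
rank threshold: sensitivity is the fraction of test samples at or above
the threshold, the false-positive rate the fraction of candidates above
it; the AUC is trapezoidal. With a shared candidate pool this equals the
Mann–Whitney statistic (cross-checked in the tests against an independent
implementation). Test ranks use strict greater-than counting with
mid-ranks for ties, since the AUC is tie-sensitive.

* **Global LOOCV**: each known pair left out in turn, ranked against every
  pair never labeled 1 in the full data.
* **Local LOOCV**: ranked only against the unconfirmed miRNAs of the same
  disease; the pooled curve is reported along with per-disease AUCs.
* **Repeated 5-fold**: seeded partitions of the known pairs into folds of
  sizes differing by at most one; per-repeat AUC, mean and sd across
  repeats.

Every round refits the whole pipeline — kernels, integrated similarities,
features, graphs — from the masked training matrix. External similarities
(functional, semantic) are not recomputed per round; they do not depend on
the associations. LOOCV offers a `budget` option that subsamples rounds
for smoke runs; it is an approximation and labeled as such.

## Synthetic data

The generator plants the model's own premise. miRNAs and diseases are
assigned to matched clusters with sizes proportional to 1..k (unequal by
design); association probability is `density * u_i * v_j * boost^{same
cluster} / mean`, with gamma-distributed per-entity propensities (shape 4,
mean 1) giving heterogeneous degrees; the functional-similarity matrix is
`base + bonus * [same cluster] + N(0, noise)` clipped to [0,1] and
observed on a random symmetric subset of pairs; disease DAGs hang each
disease under a cluster-specific ancestor chain (per-disease depth drawn
from 1..3) below a shared root, with 20% of diseases lacking a DAG. A
fraction (default 20%) of sampled positives is withheld as ground truth.

Unequal cluster sizes and degree heterogeneity are essential, not
cosmetic: with equal blocks and uniform degrees every entity's similarity
row has the same distribution, the summary-statistic features are
exchangeable across entities, and no feature-based model could separate
clusters — the planted signal would be invisible to the method by
construction. Real corpora are heavy-tailed and unbalanced, which is what
makes the engineered profiles informative. Within a matched block,
held-out positives and negatives remain partially exchangeable, so the
recovery AUC has a ceiling well below 1 even for an oracle scoring each
pair by its true sampling probability (about 0.87 under the small preset);
passing recovery tests therefore demonstrates signal use, not near-perfect
ranking. The generator does not emulate MeSH multiple parentage, miRNA
family structure, or curation bias, so test results bound what to expect
on real data only loosely.

Presets: `SMALL` (60 x 40, 4 clusters, density 0.05, boost 8) used by the
tests and examples; `HMDD_LIKE` (495 x 383, 8 clusters, density 0.0286,
boost 4 — milder because propensity tails grow with matrix size) matching
the shape and sparsity of the HMDD v2.0 corpus. Structurally unreachable
densities raise an error with the feasible range; propensity-tail
probabilities above 1 are clipped.

## Problem sizes and defaults used in reported runs

The acceptance script runs the small preset: 10 recovery replicates with
matched permuted-label nulls, full global and local LOOCV (one refit per
known pair), 10 repeats of 5-fold CV, and 10 new-disease replicates, with
optimizer settings `max_iter = 300`, `tol = 1e-5` (same fixed points as
the library defaults, fewer iterations). The corpus-scale preset is
generated once to report its realized density. Headline results published
for the real HMDD v2.0 corpus additionally require the external curated
functional-similarity matrix and MeSH descriptor files, which are not
redistributable with the package; `repro/` documents the protocol for
users who obtain them.

## Known limitations

* The multiplicative G update can stall at zero entries (zeros are fixed
  points); the uniform random initialization avoids starting there.
* Scores from the two perspectives are averaged without calibration; they
  are comparable only through the shared row-normalization.
* Local LOOCV AUC depends strongly on per-disease candidate counts; pooled
  and per-disease summaries can differ.
* The synthetic recovery ceiling (block exchangeability) means absolute
  AUC values on synthetic data are not comparable to corpus AUCs.
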