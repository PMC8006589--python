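# Methods

## Model

Let the entity families be patients (P), cancer types (C), genes (G),
pathways (M), complexes (X) and drugs (D), assigned to three latent
spaces: space1 = {P, C} with dimension k1, space2 = {G, M, X} with k2,
space3 = {D} with k3.  Each family f has one non-negative factor
G_f ∈ R_{≥0}^{n_f × k}; each tri-factorized relation e has a central
matrix S_e.  The eight default relations and their factorization kinds:

| relation          | families       | kind  | reconstruction        |
|-------------------|----------------|-------|-----------------------|
| diagnosis         | P × C          | NMF   | G_P G_Cᵀ              |
| expression        | P × G          | NMTF  | G_P S G_Gᵀ (S: k1×k2) |
| mutation          | P × G          | NMTF  | G_P S G_Gᵀ            |
| ppi               | G × G          | SNMTF | G_G S G_Gᵀ (S sym.)   |
| gene_complex      | G × X          | NMF   | G_G G_Xᵀ              |
| gene_pathway      | G × M          | NMF   | G_G G_Mᵀ              |
| drug_target       | D × G          | NMTF  | G_D S G_Gᵀ (k3×k2)    |
| drug_similarity   | D × D          | SNMTF | G_D S G_Dᵀ            |

The joint objective is the unweighted sum of squared Frobenius
residuals.  A per-relation weight hook exists (`FitConfig.weights`) but
defaults to 1 for every subobjective; balancing heterogeneous noise
levels across relations is a known open issue and deliberately not
attempted here.

Within-family relations must use SNMTF.  A same-family bi-factorization
(R ≈ G Gᵀ) is rejected by the type rules: its multiplicative update is
quartic in one factor and demonstrably non-monotone, whereas the SNMTF
form (with the central matrix) behaves well in practice.

## Optimization

Updates are multiplicative rules derived from the KKT conditions of the
summed objective.  For a factor G shared by several relations the
numerator/denominator gradient parts are aggregated over every incident
relation (both halves when the family occupies both sides):

* NMF row side: num += R G_b, den += G (G_bᵀ G_b); column side
  transposed accordingly.
* NMTF row side: num += R G_b S_eᵀ, den += G (S_e G_bᵀ G_b S_eᵀ);
  column side: num += Rᵀ G_a S_e, den += G (S_eᵀ G_aᵀ G_a S_e).
* SNMTF contributes both the row- and column-side terms with the same
  factor.

then G ← G ∘ num ⊘ (den + ε).  Central matrices follow with
S ← S ∘ (G_aᵀ R G_b) ⊘ (G_aᵀ G_a S G_bᵀ G_b + ε); symmetric centrals
are re-symmetrized to (S + Sᵀ)/2 afterwards (this cannot increase the
objective, by convexity in S and symmetry of the data).  Factors are
swept sequentially (Gauss–Seidel, bundle family order, then centrals),
so every elementary update is a monotone majorize–minimize step; on a
single NMF relation the sweep reduces exactly to the classical
two-factor multiplicative rule.  The test suite asserts objective
monotonicity (relative 1e−6) across hundreds of random bundles.

Numerical choices:

* ε = 1e−12 denominator stabilizer (zero-lock protection); a factor row
  with all-zero data rows decays to exactly 0 and stays there.
* Initialization: strictly positive uniform draws on (0.1, 1.1),
  deterministic given the seed.  Central matrices are rescaled exactly
  so each tri-factorized relation's initial reconstruction matches the
  data's Frobenius norm; per-family scale factors for NMF relations are
  solved in the log domain by least squares.  This keeps all initial
  subobjectives on comparable footing.
* Convergence: relative objective change < `tol` (default 1e−5) or
  `max_iter` (default 500) iterations; `n_restarts` (default 1) refits
  from consecutive seeds and keeps the lowest final objective.
  Fold-in consistency measurements use a tighter setting
  (max_iter 2000, tol 1e−9) because the identity "re-projected patient ≈
  trained embedding" only holds at (near) convergence.

## Hyperparameters

k1, k2, k3 are selected by grid search: each grid point is fitted and
scored by the macro-F1 of assigning every patient to the cosine-nearest
cancer-type embedding; ties break to the lexicographically smallest
dimension tuple for reproducibility.  `factorization.REFERENCE_DIMS`
(k1=21, k2=70, k3=40) and `REFERENCE_GRID` record the values selected on
the original full-scale pan-cancer corpus; synthetic worlds use
rank-matched dims (k1 = number of cancers, k2/k3 = number of planted
modules, capped by the smallest family per space, since k may not exceed
any family's size).

## Link prediction protocol

Embeddings are unit-normalized before any classifier sees them — the
transfer of a classifier between families sharing a space depends on it.
A candidate pair's features are the concatenated vectors.  Known links
are split into 10 random near-equal folds; all unreported pairs form a
shared negative pool; no class balancing is applied.  Member m trains on
everything except fold-m positives, which are removed entirely (not
relabeled as negatives).  Evaluation scores fold-m positives against the
whole negative pool (AUROC, AUPRC).  Prediction-time candidate scores
are z-standardized per member over the scored candidate set — the
reproducible reading of "standardize, then average": it makes the
aggregate invariant to monotone affine differences in member calibration
— and averaged; a member with zero score spread contributes 0 and is
logged.  Entities already associated with any cancer in the ground truth
can be excluded so rankings surface novel candidates.

Tree settings (ensemble defaults): 200 trees, depth 6, learning rate
0.1, histogram method, seeded, single-threaded for reproducibility.
These are standard defaults; all tests assert recovery of planted
signal, never specific raw scores.

The drug-response experiment uses a 70/10/20 train/validation/test split
repeated 10 times; the validation portion drives early stopping on
log-loss (tuning the tree count), which is how a named-but-unused
validation set is most plausibly spent.  Splits leaving a class empty in
any portion are redrawn from the next derived seed and logged.
Feature importance is total gain per feature, normalized to sum 1 per
model (relative importance) and averaged over the 10 models, split into
the patient block (first k1 features) and drug block (last k3).  Genes
are ranked by projecting their embeddings through central matrices —
G_G (S_exp + S_mut)ᵀ into the patient space, G_G S_dtᵀ into the drug
space — and taking the inner product with the matching importance
vector; rankings are invariant to positive rescaling of the importance
vectors.

## Evaluation suite

* Nearest-centroid and k-NN (k = 10) diagnosis classifiers, cosine
  distance, macro-F1 (unweighted mean of per-class F1; classes absent
  from both truth and predictions are skipped).  Ties and zero vectors
  resolve to the lexicographically first label, with a warning.
* Agglomerative clustering with cosine distance and average linkage
  (UPGMA).  Linkage choice is ours: average linkage is the standard
  robust default with cosine distances.  Zero vectors sit at distance
  1.0 (the maximum attainable for non-negative data) from everything.
* ARI by the pair-counting contingency formula.
* Cluster enrichment: upper-tail hypergeometric p per (cluster, term),
  background = the clustered gene set, Benjamini–Hochberg applied
  jointly across all (cluster, term) tests (the conservative scope), and
  the fraction of clusters with ≥1 enriched term at α = 0.05.  The
  permutation null holds cluster sizes fixed, reassigns genes uniformly,
  and recomputes the full procedure per replicate; the empirical p uses
  the +1 correction and therefore can never return 0.
* Intra/exo membership distances with a two-sided Mann–Whitney U test
  (exact distribution when both samples have ≤ 20 observations).
* AUROC via the tie-corrected rank statistic; AUPRC via step-wise
  precision–recall integration with no interpolation (ties grouped by
  threshold).
* Survival stratification at the cohort mean expression (a value exactly
  at the mean joins the "lower" group — fixed boundary convention) with
  the standard logrank test; groups need ≥ 2 patients each.

## Synthetic worlds

The generator emulates the structure of a pan-cancer corpus, not its
marginal distributions.  Defaults: 10 cancers × 20 patients, 500 genes
in 25 equal modules, 20 within-module complexes, 50 drugs (one targeted
module each), 3 active modules per cancer, drivers = 20 % of each
cancer's active-module genes.  Expression = baseline 1 + activation
boost 1 on active modules + N(0, 0.1) noise truncated at 0; mutations
are Bernoulli(0.02) background with rate 0.5 for a cancer's drivers in
its cohort; the PPI network is a planted partition graph (0.3 within /
0.01 between modules); drug–drug similarity is the Jaccard index of
target sets.  The scale is chosen so the full pipeline (fit, CV link
prediction, evaluation, permutation null) completes in a few minutes on
one CPU while every planted signal remains recoverable.

Response records mirror the real cohort's size (2589 patient–drug
records); the outcome is 1 iff the drug's target module is active in the
patient's cancer, flipped with 2 % label noise.  The noise level is set
from a ceiling analysis: with the ~0.12 active-combination rate, a 5 %
flip rate already caps the Bayes-optimal AUROC near 0.86, which would
leave no room between "mechanism recovered" and "mechanism
unrecoverable"; at 2 % the ceiling is ≈ 0.93, so the recovery checks
measure the method rather than the noise floor.

The exact-recovery fixture (`planted_lowrank_bundle`) builds matrices as
exact products of planted factors covering all three factorization
kinds.  Two deliberate design features: factors are block-structured
(one dominant coordinate per row over a strictly positive background) so
their Gram matrices are well conditioned — flat positive draws make the
data nearly rank-1 and multiplicative updates crawl — and the non-shared
NMF factors are rescaled so all relations carry equal Frobenius norm,
since in an unweighted sum a small-norm relation receives a
proportionally small gradient share and converges much more slowly.

What passing on these worlds does **not** show: robustness to the
long-tailed expression distributions, batch effects, incomplete and
biased annotation, inter-module overlap and label noise of real corpora.
The worlds are a correctness harness for the machinery, not a benchmark
of biological performance.

## Known limitations

* Dense in-memory matrices; fine at desk scale (10³–10⁴ entities per
  family), not engineered for 10⁵+.
* Multiplicative updates converge linearly and can be slow near the
  optimum; no acceleration (no HALS/ANLS variants) is provided.
* Subobjectives are unweighted; strongly heterogeneous noise across
  relations will bias the shared factors toward large-norm relations.
* The grid-search criterion uses only the diagnosis signal; nothing
  guards against k2/k3 values that are poor for gene- or drug-space
  tasks but equal on that criterion (ties break lexicographically).
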