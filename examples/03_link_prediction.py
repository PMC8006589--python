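"""Cross-validated cancer-gene link prediction on pair embeddings.

Known (cancer, driver-gene) links are the positives; every unreported
pair is a negative.  Ten boosted-tree classifiers are trained, each with
one fold of positives held out, and scored by AUROC/AUPRC; candidate
rankings average the members' z-standardized scores.
"""

from panfuse import factorization as fz
from panfuse import linkpred as lp
from panfuse import worlds

world, bundle = worlds.generate_world(worlds.WorldParams(seed=1))
cfg = fz.FitConfig(dims=worlds.matched_dims(world), max_iter=500,
                   tol=1e-7, seed=1)
model = fz.fit(bundle, cfg).model

cancers = fz.embeddings_of(model, "cancers")
genes = fz.embeddings_of(model, "genes")
pos, neg = worlds.planted_truth(world, "cancer-gene")
dataset = lp.pair_features(cancers, genes, pos + neg,
                           [1] * len(pos) + [0] * len(neg))
folds = lp.cv_folds(pos, n_folds=10, seed=1)
ensemble = lp.train_link_ensemble(dataset, folds, lp.TreeParams(seed=1))

cv = lp.evaluate_link_cv(ensemble, dataset)
m, s = cv.attrs["mean"], cv.attrs["sd"]
print(f"10-fold cancer-gene AUROC {m['auroc']:.3f}+/-{s['auroc']:.3f}  "
      f"AUPRC {m['auprc']:.3f}+/-{s['auprc']:.3f}")
print("(held-out positives vs the full non-link pool; AUPRC is the "
      "informative number under this class imbalance)")

# rank genes with no known association for any cancer
known = {g for _, g in pos}
ranking = lp.score_candidates(ensemble, cancers, genes, exclude=known)
print("\ntop 5 novel candidate pairs (standardized ensemble score):")
print(ranking.top(5).to_string(index=False))
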