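"""Zero-shot classifier transfer and drug-response prediction.

Because pathways share the gene latent space, the trees trained on
cancer-gene pairs can score cancer-pathway pairs with no retraining.
Separately, patient-drug response records are predicted from concatenated
patient/drug embeddings, and gain-based feature importances are projected
back onto genes through the central matrices.
"""

import numpy as np

from panfuse import evaluation as ev
from panfuse import factorization as fz
from panfuse import linkpred as lp
from panfuse import worlds

world, bundle = worlds.generate_world(worlds.WorldParams(seed=1))
cfg = fz.FitConfig(dims=worlds.matched_dims(world), max_iter=500,
                   tol=1e-7, seed=1)
model = fz.fit(bundle, cfg).model
cancers = fz.embeddings_of(model, "cancers")
genes = fz.embeddings_of(model, "genes")
pathways = fz.embeddings_of(model, "pathways")
patients = fz.embeddings_of(model, "patients")
drugs = fz.embeddings_of(model, "drugs")

pos, neg = worlds.planted_truth(world, "cancer-gene")
dataset = lp.pair_features(cancers, genes, pos + neg,
                           [1] * len(pos) + [0] * len(neg))
ensemble = lp.train_link_ensemble(dataset, lp.cv_folds(pos, 10, seed=1),
                                  lp.TreeParams(seed=1))

# repurpose the cancer-gene trees for cancer-pathway scoring
ranking = lp.repurpose(ensemble, pathways, cancers)
truth = set(worlds.planted_truth(world, "cancer-pathway")[0])
labels = [1 if p in truth else 0
          for p in zip(ranking.table["left"], ranking.table["right"])]
auroc, auprc = ev.ranking_metrics(ranking.table["score"].to_numpy(), labels)
print(f"repurposed cancer-pathway AUROC {auroc:.3f}  AUPRC {auprc:.3f}")
print("(the trees never saw a pathway; transfer works because pathway and "
      "gene embeddings share a unit-norm latent space)")

# drug response: 70/10/20 split x 10 repeats, early-stopped tree count
resp = worlds.planted_truth(world, "response")
table, models = lp.drug_response_experiment(patients, drugs, resp,
                                            repeats=10, seed=1)
m, s = table.attrs["mean"], table.attrs["sd"]
print(f"\nresponse AUROC {m['auroc']:.3f}+/-{s['auroc']:.3f}  "
      f"AUPRC {m['auprc']:.3f}+/-{s['auprc']:.3f} over {len(resp)} records")

# project gain importance back onto genes, check driver recovery
proj_p = fz.feature_space_projection(model, "genes",
                                     ["expression", "mutation"])
proj_d = fz.feature_space_projection(model, "genes", ["drug_target"])
drivers = set().union(*world.drivers.values())
out = lp.importance_analysis(models, proj_p, proj_d, drivers)
print(f"driver-gene recovery AUROC: patient space "
      f"{out['patient_space']['auroc']:.3f}, drug space "
      f"{out['drug_space']['auroc']:.3f}")
print("(rankings = projected gene embeddings weighted by the importance "
      "the response trees assign to each latent feature)")
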