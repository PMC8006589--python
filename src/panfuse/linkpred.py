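"""Boosted-tree link prediction on concatenated latent embeddings.

A candidate (cancer, entity) pair is represented by the concatenation of
the two unit-normalized embedding vectors; gradient-boosted decision
trees score the pair.  Known links are split into 10 folds; every
non-reported pair forms the shared negative pool (no class balancing).
Prediction-time scores are z-standardized per ensemble member over the
candidate set and averaged.  Because families sharing a latent space are
interchangeable as classifier input, a trained ensemble can be repurposed
to score entities it never saw during training (pathways or complexes in
place of genes) — a zero-shot transfer that only works on unit-norm
embeddings, which is why normalization is enforced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .evaluation import ranking_metrics
from .factorization import EmbeddingSet, FactorModel, ProjectedEmbeddings

__all__ = [
    "TreeParams",
    "PairDataset",
    "LinkEnsemble",
    "AssociationRanking",
    "ImportanceVectors",
    "pair_features",
    "cv_folds",
    "train_link_ensemble",
    "evaluate_link_cv",
    "score_candidates",
    "repurpose",
    "drug_response_experiment",
    "gain_importance",
    "importance_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class TreeParams:
    """Gradient-boosted tree settings (shared by all ensemble members)."""

    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1
    seed: int = 0
    n_jobs: int = 1
    early_stopping_rounds: int | None = None

    def make(self, member_seed: int, early_stopping: bool = False) -> XGBClassifier:
        kwargs = dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=member_seed,
            n_jobs=self.n_jobs,
            tree_method="hist",
            eval_metric="logloss",
        )
        if early_stopping:
            kwargs["early_stopping_rounds"] = self.early_stopping_rounds or 20
        return XGBClassifier(**kwargs)


@dataclass
class PairDataset:
    """Concatenated-pair feature matrix with binary labels."""

    left_family: str
    right_family: str
    left_space: str
    right_space: str
    pairs: list                  # list of (left id, right id)
    features: np.ndarray         # (n_pairs, k_left + k_right)
    labels: np.ndarray           # binary
    k_left: int
    k_right: int


def _require_normalized(emb: EmbeddingSet, side: str) -> None:
    if not emb.normalized:
        raise ValueError(
            f"{side} embeddings must be unit-normalized (normalization is "
            "what makes classifiers transferable across families)")


def pair_features(emb_left: EmbeddingSet, emb_right: EmbeddingSet,
                  pairs, labels=None) -> PairDataset:
    """Build the feature matrix ``[left vector ‖ right vector]`` per pair."""
    _require_normalized(emb_left, "left")
    _require_normalized(emb_right, "right")
    lpos = {i: j for j, i in enumerate(emb_left.ids)}
    rpos = {i: j for j, i in enumerate(emb_right.ids)}
    pairs = list(pairs)
    try:
        li = [lpos[a] for a, _ in pairs]
        ri = [rpos[b] for _, b in pairs]
    except KeyError as exc:
        raise KeyError(f"unknown entity id {exc.args[0]!r}") from exc
    X = np.hstack([emb_left.vectors[li], emb_right.vectors[ri]])
    y = (np.zeros(len(pairs), dtype=int) if labels is None
         else np.asarray(labels, dtype=int))
    return PairDataset(
        left_family=emb_left.family, right_family=emb_right.family,
        left_space=emb_left.space, right_space=emb_right.space,
        pairs=pairs, features=X, labels=y,
        k_left=emb_left.vectors.shape[1], k_right=emb_right.vectors.shape[1])


def cv_folds(positives, n_folds: int = 10, seed: int = 0) -> dict:
    """Randomly partition the known links into near-equal folds.

    Returns a mapping positive pair -> fold index.  All non-reported pairs
    form the shared negative pool and are never folded.
    """
    positives = list(positives)
    if len(positives) < n_folds:
        raise ValueError(f"{len(positives)} positives < {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        for idx in chunk:
            assignment[positives[idx]] = fold
    return assignment


@dataclass
class LinkEnsemble:
    """The 10 fold-trained classifiers plus fold bookkeeping."""

    members: list
    fold_of_positive: dict
    params: TreeParams
    left_space: str
    right_space: str
    k_left: int
    k_right: int
    train_pair_index: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.members)


def train_link_ensemble(dataset: PairDataset, folds: dict,
                        params: TreeParams | None = None) -> LinkEnsemble:
    """Train one member per fold on all pairs except that fold's positives.

    Held-out positives are removed entirely from the member's training
    data (treated as unknown — neither positive nor negative).  The full
    negative pool participates in every member's training, unweighted.
    """
    params = params or TreeParams()
    n_folds = max(folds.values()) + 1
    pair_index = {pair: i for i, pair in enumerate(dataset.pairs)}
    fold_of_row = np.full(len(dataset.pairs), -1)
    for pair, fold in folds.items():
        fold_of_row[pair_index[pair]] = fold
    if np.any((fold_of_row >= 0) & (dataset.labels == 0)):
        raise ValueError("fold assignment contains non-positive pairs")
    members = []
    for m in range(n_folds):
        keep = fold_of_row != m
        y = dataset.labels[keep]
        if len(np.unique(y)) < 2:
            raise ValueError(f"fold {m}: training set has a single class")
        clf = params.make(member_seed=params.seed + m)
        clf.fit(dataset.features[keep], y)
        members.append(clf)
    return LinkEnsemble(members=members, fold_of_positive=dict(folds),
                        params=params, left_space=dataset.left_space,
                        right_space=dataset.right_space,
                        k_left=dataset.k_left, k_right=dataset.k_right,
                        train_pair_index=pair_index)


def evaluate_link_cv(ensemble: LinkEnsemble,
                     dataset: PairDataset) -> pd.DataFrame:
    """Held-out scores: fold-m positives vs the whole negative pool.

    Returns one row per fold with AUROC and AUPRC; ``.attrs["mean"]`` and
    ``.attrs["sd"]`` carry the across-fold summaries.
    """
    pair_index = ensemble.train_pair_index
    fold_of_row = np.full(len(dataset.pairs), -1)
    for pair, fold in ensemble.fold_of_positive.items():
        fold_of_row[pair_index[pair]] = fold
    neg_rows = np.where(dataset.labels == 0)[0]
    rows = []
    for m, clf in enumerate(ensemble.members):
        pos_rows = np.where(fold_of_row == m)[0]
        test = np.concatenate([pos_rows, neg_rows])
        scores = clf.predict_proba(dataset.features[test])[:, 1]
        labels = dataset.labels[test]
        auroc, auprc = ranking_metrics(scores, labels)
        rows.append((m, auroc, auprc))
    table = pd.DataFrame(rows, columns=["fold", "auroc", "auprc"])
    table.attrs["mean"] = {"auroc": float(table["auroc"].mean()),
                           "auprc": float(table["auprc"].mean())}
    table.attrs["sd"] = {"auroc": float(table["auroc"].std(ddof=1)),
                         "auprc": float(table["auprc"].std(ddof=1))}
    return table


@dataclass
class AssociationRanking:
    """Candidate pairs ranked by averaged standardized ensemble score."""

    table: pd.DataFrame          # left, right, score, rank (dense, desc)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


def _standardized_scores(members, X: np.ndarray) -> np.ndarray:
    """Average of per-member z-standardized raw scores over the candidate
    set; members with zero score spread contribute 0 (logged)."""
    acc = np.zeros(X.shape[0])
    for i, clf in enumerate(members):
        raw = clf.predict_proba(X)[:, 1]
        sd = raw.std()
        if sd == 0:
            log.warning("member %d has zero score spread; contributes 0", i)
            continue
        acc += (raw - raw.mean()) / sd
    return acc / len(members)


def score_candidates(ensemble: LinkEnsemble, emb_left: EmbeddingSet,
                     emb_right: EmbeddingSet,
                     exclude=()) -> AssociationRanking:
    """Score every (left, right) candidate pair and rank them.

    ``exclude`` lists right-side entities with any known association in
    the ground truth; they are dropped from the candidate set so the
    ranking surfaces genuinely novel entities.
    """
    _require_normalized(emb_left, "left")
    _require_normalized(emb_right, "right")
    if emb_right.vectors.shape[1] != ensemble.k_right:
        raise ValueError("right-side embedding width does not match ensemble")
    exclude = set(exclude)
    right_ids = [r for r in emb_right.ids if r not in exclude]
    pairs = [(a, b) for a in emb_left.ids for b in right_ids]
    ds = pair_features(emb_left, emb_right, pairs)
    score = _standardized_scores(ensemble.members, ds.features)
    table = pd.DataFrame(pairs, columns=["left", "right"])
    table["score"] = score
    table["rank"] = table["score"].rank(method="dense",
                                        ascending=False).astype(int)
    table = table.sort_values(["rank", "left", "right"]).reset_index(drop=True)
    return AssociationRanking(table=table)


def repurpose(ensemble: LinkEnsemble, emb_substitute: EmbeddingSet,
              emb_cancer: EmbeddingSet, exclude=()) -> AssociationRanking:
    """Zero-shot transfer: score a family the ensemble never trained on.

    The substitute family must live in the same latent space as the
    family used at training time (e.g. pathways in place of genes); the
    scoring path is identical to :func:`score_candidates` with no
    retraining.
    """
    if emb_substitute.space != ensemble.right_space:
        raise ValueError(
            f"substitute family {emb_substitute.family!r} lives in "
            f"{emb_substitute.space!r}; the ensemble was trained on "
            f"{ensemble.right_space!r}")
    return score_candidates(ensemble, emb_cancer, emb_substitute, exclude)


def drug_response_experiment(emb_patients: EmbeddingSet,
                             emb_drugs: EmbeddingSet,
                             responses: pd.DataFrame,
                             split=(0.7, 0.1, 0.2), repeats: int = 10,
                             seed: int = 0,
                             params: TreeParams | None = None):
    """Binary response prediction with a 70/10/20 split, 10 repeats.

    ``responses`` has columns patient, drug, response (1 = complete
    response).  Per repeat, a boosted tree is trained on the training
    portion with the tree count tuned by early stopping on validation
    log-loss, then scored on the test portion.  Splits that leave a class
    empty in train or test are resampled with the next derived seed
    (logged).  Returns ``(per-repeat table, fitted models)``; the table's
    ``.attrs`` carry mean and sd.
    """
    params = params or TreeParams(early_stopping_rounds=20)
    ds = pair_features(emb_patients, emb_drugs,
                       list(zip(responses["patient"], responses["drug"])),
                       labels=responses["response"].to_numpy())
    X, y = ds.features, ds.labels
    n = len(y)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    rows, models = [], []
    draw = 0
    for rep in range(repeats):
        while True:
            rng = np.random.default_rng(seed + 1000 * rep + draw)
            order = rng.permutation(n)
            tr = order[:n_train]
            va = order[n_train:n_train + n_val]
            te = order[n_train + n_val:]
            if (len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
                    and len(np.unique(y[va])) == 2):
                break
            draw += 1
            log.warning("repeat %d: single-class split, resampling", rep)
        clf = params.make(member_seed=params.seed + rep, early_stopping=True)
        clf.fit(X[tr], y[tr], eval_set=[(X[va], y[va])], verbose=False)
        scores = clf.predict_proba(X[te])[:, 1]
        auroc, auprc = ranking_metrics(scores, y[te])
        rows.append((rep, auroc, auprc))
        models.append(clf)
    table = pd.DataFrame(rows, columns=["repeat", "auroc", "auprc"])
    table.attrs["mean"] = {"auroc": float(table["auroc"].mean()),
                           "auprc": float(table["auprc"].mean())}
    table.attrs["sd"] = {"auroc": float(table["auroc"].std(ddof=1)),
                         "auprc": float(table["auprc"].std(ddof=1))}
    return table, models


@dataclass
class ImportanceVectors:
    """Per-feature gain importance split by embedding block."""

    i_patients: np.ndarray       # first k1 features (left block)
    i_drugs: np.ndarray          # last k3 features (right block)


def gain_importance(models, k_left: int, k_right: int) -> ImportanceVectors:
    """Average gain-based feature importance across trained models.

    Each model's total-gain vector is normalized to sum 1 (relative
    importance) before averaging; features a model never split on get 0.
    """
    n_feat = k_left + k_right
    acc = np.zeros(n_feat)
    for clf in models:
        gains = clf.get_booster().get_score(importance_type="total_gain")
        vec = np.zeros(n_feat)
        for name, g in gains.items():
            vec[int(name[1:])] = g
        total = vec.sum()
        if total > 0:
            vec /= total
        acc += vec
    acc /= len(models)
    return ImportanceVectors(i_patients=acc[:k_left], i_drugs=acc[k_left:])


def importance_analysis(models, proj_patient_space: ProjectedEmbeddings,
                        proj_drug_space: ProjectedEmbeddings,
                        reference: set) -> dict:
    """Rank genes by importance-weighted projections; score vs reference.

    The projected gene embeddings (patient space via the expression +
    mutation centrals, drug space via the drug-target central) are
    combined with the importance vectors by inner product; each ranking is
    scored by AUROC/AUPRC against the reference driver set.  Returns the
    importance vectors, both score series and both metric pairs.
    """
    iv = gain_importance(models, proj_patient_space.vectors.shape[1],
                         proj_drug_space.vectors.shape[1])
    out = {"importance": iv}
    for space, proj, vec in (
            ("patient_space", proj_patient_space, iv.i_patients),
            ("drug_space", proj_drug_space, iv.i_drugs)):
        scores = proj.vectors @ vec
        labels = np.array([1 if g in reference else 0 for g in proj.ids])
        auroc, auprc = ranking_metrics(scores, labels)
        out[space] = {"scores": pd.Series(scores, index=list(proj.ids)),
                      "auroc": auroc, "auprc": auprc}
    return out
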