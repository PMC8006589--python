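"""Embedding-quality and statistical validation suite.

Covers: nearest-centroid and k-NN diagnosis classifiers scored by
macro-F1, cosine hierarchical clustering with the adjusted Rand index,
gene-cluster annotation enrichment (hypergeometric + Benjamini-Hochberg)
with a size-preserving permutation null, intra/exo membership distances
with a Mann-Whitney U test, ranking metrics (AUROC/AUPRC), and
expression-stratified survival with a logrank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Labeling",
    "EnrichmentReport",
    "nearest_centroid_macro_f1",
    "knn_macro_f1",
    "cosine_hierarchical_clusters",
    "adjusted_rand_index",
    "cluster_enrichment",
    "randomized_enrichment_null",
    "membership_distance_test",
    "ranking_metrics",
    "survival_split_logrank",
    "projection_holdout",
]

log = logging.getLogger(__name__)


@dataclass
class Labeling:
    """A categorical label per entity."""

    ids: list
    labels: list

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels differ in length")

    def as_dict(self) -> dict:
        return dict(zip(self.ids, self.labels))


def _unit_rows(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale rows to unit norm; returns (scaled, zero-row mask)."""
    V = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(V, axis=1)
    zero = norms == 0
    norms = np.where(zero, 1.0, norms)
    return V / norms[:, None], zero


def _macro_f1(y_true, y_pred) -> float:
    labels = sorted(set(y_true) | set(y_pred))
    return float(f1_score(y_true, y_pred, labels=labels, average="macro",
                          zero_division=0))


def nearest_centroid_macro_f1(entity_emb, centroid_emb, truth: dict) -> float:
    """Macro-F1 of assigning each entity to the cosine-nearest centroid.

    ``centroid_emb`` typically holds the cancer-type embeddings, so the
    centroid ids are the label universe.  Ties (and zero-vector entities,
    which are warned about) resolve to the lexicographically first
    centroid label.  Per-class F1 is averaged unweighted; classes absent
    from both truth and predictions are skipped.
    """
    order = np.argsort(np.asarray(centroid_emb.ids, dtype=object))
    cent_ids = [centroid_emb.ids[i] for i in order]
    C, czero = _unit_rows(centroid_emb.vectors[order])
    E, ezero = _unit_rows(entity_emb.vectors)
    if np.any(ezero):
        log.warning("%d zero-vector entities assigned to tie-break label",
                    int(ezero.sum()))
    sims = E @ C.T
    pred = [cent_ids[j] for j in np.argmax(sims, axis=1)]
    y_true = [truth[i] for i in entity_emb.ids]
    return _macro_f1(y_true, pred)


def knn_macro_f1(train_emb, train_labels: dict, test_emb, test_labels: dict,
                 k: int = 10) -> float:
    """Macro-F1 of the k-nearest-neighbour (cosine) diagnosis classifier.

    The predicted label is the majority among the k nearest training
    entities; ties resolve to the smallest label.
    """
    Tr, _ = _unit_rows(train_emb.vectors)
    Te, _ = _unit_rows(test_emb.vectors)
    if k > Tr.shape[0]:
        raise ValueError(f"k={k} exceeds training size {Tr.shape[0]}")
    sims = Te @ Tr.T
    y_train = [train_labels[i] for i in train_emb.ids]
    preds = []
    for row in sims:
        nn = np.argpartition(-row, k - 1)[:k]
        votes: dict = {}
        for j in nn:
            votes[y_train[j]] = votes.get(y_train[j], 0) + 1
        top = max(votes.values())
        preds.append(min(lab for lab, c in votes.items() if c == top))
    y_true = [test_labels[i] for i in test_emb.ids]
    return _macro_f1(y_true, preds)


def cosine_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances; zero vectors sit at the maximum
    distance (1.0, the maximum attainable for non-negative data) from
    everything, with a warning."""
    V, zero = _unit_rows(vectors)
    if np.any(zero):
        log.warning("%d zero vectors mapped to maximal cosine distance",
                    int(zero.sum()))
    D = 1.0 - V @ V.T
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def cosine_hierarchical_clusters(emb, n_clusters: int) -> Labeling:
    """Agglomerative clustering (cosine distance, average linkage) cut to
    ``n_clusters`` groups."""
    n = len(emb.ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} outside [1, {n}]")
    D = cosine_distance_matrix(emb.vectors)
    Z = scipy.cluster.hierarchy.linkage(
        scipy.spatial.distance.squareform(D, checks=False), method="average")
    assign = scipy.cluster.hierarchy.fcluster(Z, t=n_clusters,
                                              criterion="maxclust")
    return Labeling(ids=list(emb.ids), labels=[int(a) for a in assign])


def adjusted_rand_index(a: Labeling, b: Labeling) -> float:
    """Chance-corrected pair-counting agreement of two partitions."""
    if set(a.ids) != set(b.ids):
        raise ValueError("labelings cover different id universes")
    bmap = b.as_dict()
    la = list(a.labels)
    lb = [bmap[i] for i in a.ids]
    # map to ints for sklearn
    ua = {v: i for i, v in enumerate(dict.fromkeys(la))}
    ub = {v: i for i, v in enumerate(dict.fromkeys(lb))}
    return float(adjusted_rand_score([ua[v] for v in la], [ub[v] for v in lb]))


@dataclass
class EnrichmentReport:
    table: pd.DataFrame          # cluster, term, overlap, p, p_adj, enriched
    fraction_enriched: float     # clusters with >=1 enriched term
    alpha: float
    n_clusters: int


def _enrichment_pvalues(assign: np.ndarray, T: np.ndarray) -> tuple:
    """Upper-tail hypergeometric p for every (cluster, term) pair.

    ``assign`` holds integer cluster indices per gene; ``T`` is the
    (n_genes, n_terms) membership indicator.  The background population is
    the clustered gene set.  Returns (overlap counts, p-value matrix,
    cluster sizes, term sizes).
    """
    n_clusters = int(assign.max()) + 1
    N = assign.shape[0]
    counts = np.zeros((n_clusters, T.shape[1]))
    np.add.at(counts, assign, T)
    sizes = np.bincount(assign, minlength=n_clusters)
    term_sizes = T.sum(axis=0)
    # P[X >= k] with X ~ Hypergeom(N, K_term, n_cluster)
    p = scipy.stats.hypergeom.sf(counts - 1, N, term_sizes[None, :],
                                 sizes[:, None])
    return counts, p, sizes, term_sizes


def _fraction_enriched(p: np.ndarray, alpha: float) -> tuple:
    """BH across all (cluster, term) tests jointly; fraction of clusters
    with at least one enriched term."""
    flat = p.ravel()
    reject, p_adj, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    enriched = reject.reshape(p.shape)
    frac = float(np.mean(enriched.any(axis=1)))
    return frac, p_adj.reshape(p.shape), enriched


def cluster_enrichment(clusters: Labeling, annotations: dict,
                       alpha: float = 0.05) -> EnrichmentReport:
    """Hypergeometric enrichment of each cluster in each annotation term.

    The background population is the set of clustered genes; p-values are
    Benjamini-Hochberg adjusted jointly across all (cluster, term) tests
    at level ``alpha``.  Terms with no member in the population are
    skipped with a log message.
    """
    ids = list(clusters.ids)
    id_pos = {g: i for i, g in enumerate(ids)}
    cluster_names = sorted(set(clusters.labels), key=str)
    cmap = {c: i for i, c in enumerate(cluster_names)}
    assign = np.array([cmap[c] for c in clusters.labels])
    terms, cols = [], []
    for term, members in annotations.items():
        col = np.zeros(len(ids))
        hits = [id_pos[m] for m in members if m in id_pos]
        if not hits:
            log.info("annotation %r has no member in the population; skipped",
                     term)
            continue
        col[hits] = 1.0
        terms.append(term)
        cols.append(col)
    if not terms:
        raise ValueError("no usable annotation sets")
    T = np.column_stack(cols)
    counts, p, _, _ = _enrichment_pvalues(assign, T)
    frac, p_adj, enriched = _fraction_enriched(p, alpha)
    rows = []
    for ci, cname in enumerate(cluster_names):
        for ti, term in enumerate(terms):
            rows.append((cname, term, int(counts[ci, ti]),
                         float(p[ci, ti]), float(p_adj[ci, ti]),
                         bool(enriched[ci, ti])))
    table = pd.DataFrame(rows, columns=["cluster", "term", "overlap",
                                        "p", "p_adj", "enriched"])
    return EnrichmentReport(table=table, fraction_enriched=frac, alpha=alpha,
                            n_clusters=len(cluster_names))


@dataclass
class EnrichmentNull:
    observed: float              # observed fraction of enriched clusters
    null_fractions: np.ndarray   # one fraction per permutation replicate
    p_value: float               # (1 + #{null >= observed}) / (1 + n_reps)


def randomized_enrichment_null(clusters: Labeling, annotations: dict,
                               n_reps: int = 10000, alpha: float = 0.05,
                               seed: int = 0) -> EnrichmentNull:
    """Permutation null for the fraction of enriched clusters.

    Cluster sizes are held constant while genes are randomly reassigned;
    the enrichment procedure (hypergeometric + joint BH) is recomputed for
    each replicate.  The empirical p-value uses the +1 correction, so it
    can never be exactly zero.
    """
    ids = list(clusters.ids)
    id_pos = {g: i for i, g in enumerate(ids)}
    cluster_names = sorted(set(clusters.labels), key=str)
    cmap = {c: i for i, c in enumerate(cluster_names)}
    assign = np.array([cmap[c] for c in clusters.labels])
    cols = []
    for term, members in annotations.items():
        hits = [id_pos[m] for m in members if m in id_pos]
        if not hits:
            continue
        col = np.zeros(len(ids))
        col[hits] = 1.0
        cols.append(col)
    T = np.column_stack(cols)
    _, p_obs, _, _ = _enrichment_pvalues(assign, T)
    observed, _, _ = _fraction_enriched(p_obs, alpha)
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(assign)
        _, p_r, _, _ = _enrichment_pvalues(perm, T)
        fracs[r], _, _ = _fraction_enriched(p_r, alpha)
    p_emp = (1.0 + float(np.sum(fracs >= observed))) / (1.0 + n_reps)
    return EnrichmentNull(observed=observed, null_fractions=fracs,
                          p_value=p_emp)


@dataclass
class MembershipDistanceResult:
    mean_intra: float
    mean_exo: float
    n_intra: int
    n_exo: int
    u_statistic: float
    p_value: float


def membership_distance_test(gene_emb, set_emb,
                             membership: dict) -> MembershipDistanceResult:
    """Intra vs exo cosine distances with a two-sided Mann-Whitney U test.

    ``membership`` maps gene ids to the collection of set ids (pathways or
    complexes) they belong to.  "Intra" distances pair each gene with its
    associated sets, "exo" with all others; genes without membership
    contribute only exo distances.  The exact U distribution is used when
    both samples have at most 20 observations, the normal approximation
    otherwise.
    """
    G, _ = _unit_rows(gene_emb.vectors)
    S, _ = _unit_rows(set_emb.vectors)
    D = 1.0 - G @ S.T
    set_pos = {s: j for j, s in enumerate(set_emb.ids)}
    intra, exo = [], []
    for i, gene in enumerate(gene_emb.ids):
        assoc = {set_pos[s] for s in membership.get(gene, ()) if s in set_pos}
        for j in range(len(set_emb.ids)):
            (intra if j in assoc else exo).append(D[i, j])
    if not intra or not exo:
        raise ValueError("need at least one intra and one exo distance")
    method = "exact" if max(len(intra), len(exo)) <= 20 else "asymptotic"
    res = scipy.stats.mannwhitneyu(intra, exo, alternative="two-sided",
                                   method=method)
    return MembershipDistanceResult(
        mean_intra=float(np.mean(intra)), mean_exo=float(np.mean(exo)),
        n_intra=len(intra), n_exo=len(exo),
        u_statistic=float(res.statistic), p_value=float(res.pvalue))


def ranking_metrics(scores, labels) -> tuple[float, float]:
    """AUROC and AUPRC of a scored binary ranking.

    AUROC is the tie-corrected rank (Mann-Whitney) statistic; AUPRC is
    step-wise precision-recall integration with no interpolation (ties
    grouped by threshold).  Requires both classes present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


@dataclass
class SurvivalSplitResult:
    n_high: int
    n_low: int
    statistic: float
    p_value: float
    threshold: float
    high_ids: list
    low_ids: list


def survival_split_logrank(expression: dict, survival: pd.DataFrame,
                           time_col: str = "time",
                           event_col: str = "event") -> SurvivalSplitResult:
    """Logrank test between above-mean and below-mean expression groups.

    Patients with expression strictly above the cohort mean form the
    "high" group; a value exactly at the mean goes to the "low" group
    (documented boundary convention).  ``survival`` is indexed by patient
    id with duration and event-indicator columns.  Requires at least two
    patients per group.
    """
    from lifelines.statistics import logrank_test

    ids = [i for i in survival.index if i in expression]
    values = np.array([expression[i] for i in ids], dtype=float)
    mean = float(values.mean())
    high = [i for i, v in zip(ids, values) if v > mean]
    low = [i for i, v in zip(ids, values) if v <= mean]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"degenerate split: {len(high)} high vs {len(low)} low patients")
    res = logrank_test(
        survival.loc[high, time_col], survival.loc[low, time_col],
        event_observed_A=survival.loc[high, event_col],
        event_observed_B=survival.loc[low, event_col])
    return SurvivalSplitResult(n_high=len(high), n_low=len(low),
                               statistic=float(res.test_statistic),
                               p_value=float(res.p_value), threshold=mean,
                               high_ids=high, low_ids=low)


def projection_holdout(bundle, cfg, labels: dict,
                       patient_family: str = "patients",
                       cancer_family: str = "cancers",
                       exclude_relations: tuple = ("diagnosis",),
                       test_fraction: float = 0.1, k: int = 10,
                       seed: int = 0) -> dict:
    """Hold out a stratified fraction of patients, refit, fold them in.

    Emulates the robustness check for unseen patients: the model is
    refitted without the held-out patients, their embeddings are recovered
    by non-negative least-squares fold-in from their molecular rows
    (diagnosis-type relations are excluded — they are the prediction
    target), and the result is scored by nearest-cancer macro-F1 and
    k-NN (k=10) macro-F1 against the training patients.
    """
    from . import factorization as fz
    from .relational import subset_family

    fam = bundle.family(patient_family)
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for pid in fam.entity_ids:
        by_label.setdefault(labels[pid], []).append(pid)
    held = []
    for members in by_label.values():
        n_hold = max(1, int(round(test_fraction * len(members))))
        held.extend(rng.choice(members, size=n_hold, replace=False))
    held_set = set(held)
    keep = [pid for pid in fam.entity_ids if pid not in held_set]
    reduced = subset_family(bundle, patient_family, keep)
    result = fz.fit(reduced, cfg)
    model = result.model
    pos = fam.index
    new_rows = {}
    for rel in bundle.relations_of(patient_family):
        if rel.name in exclude_relations:
            continue
        idx = [pos[pid] for pid in held]
        new_rows[rel.name] = (rel.matrix[idx, :] if rel.family_row ==
                              patient_family else rel.matrix[:, idx].T)
    folded = fz.fold_in(model, reduced, patient_family, new_rows, ids=held)
    folded_unit = fz.EmbeddingSet(
        family=patient_family, space=folded.space, ids=folded.ids,
        vectors=_unit_rows(folded.vectors)[0], normalized=True)
    train_emb = fz.embeddings_of(model, patient_family, normalize=True)
    cancer_emb = fz.embeddings_of(model, cancer_family, normalize=True)
    macro = nearest_centroid_macro_f1(folded_unit, cancer_emb, labels)
    knn = knn_macro_f1(train_emb, labels, folded_unit, labels, k=k)
    return {"macro_f1": macro, "knn_macro_f1": knn, "held_out": held,
            "model": model, "folded": folded}
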