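"""Joint non-negative factorization with shared factors.

Every relation matrix R_e contributes one subobjective; the total objective

    J = sum_e || R_e - Hhat_e ||_F^2

is minimized over non-negative factors, where the reconstruction is
``G_a G_b^T`` (NMF), ``G_a S_e G_b^T`` (NMTF) or ``G S_e G^T`` (SNMTF) and
each family's factor G_f is *shared* across every subobjective touching
that family — the mechanism of data fusion.  Optimization uses
multiplicative updates obtained from the KKT conditions of the summed
objective: for each factor the numerator/denominator gradient parts are
aggregated over all incident relations, and factors are swept sequentially
(Gauss–Seidel) so each elementary update is monotone.

The module also provides hyperparameter grid search (nearest-cancer
macro-F1 criterion), out-of-sample fold-in by non-negative least squares,
and projection of gene-space embeddings through central matrices into the
patient or drug space.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .relational import DataBundle, RelationKind

__all__ = [
    "FitConfig",
    "FactorModel",
    "FitResult",
    "EmbeddingSet",
    "ProjectedEmbeddings",
    "init_factors",
    "joint_objective",
    "update_step",
    "fit",
    "select_hyperparameters",
    "embeddings_of",
    "fold_in",
    "feature_space_projection",
]

log = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Optimization settings.

    ``dims`` maps each latent space to its dimensionality (the model's
    hyperparameters k1, k2, k3 in the three-space configuration).
    ``tol`` is the relative objective-change convergence threshold and
    ``eps`` the multiplicative-update denominator stabilizer.
    ``weights`` optionally scales individual subobjectives (default: all 1,
    an unweighted sum).
    """

    dims: dict
    max_iter: int = 500
    tol: float = 1e-5
    eps: float = 1e-12
    seed: int = 0
    n_restarts: int = 1
    weights: dict = field(default_factory=dict)

    def validate(self, bundle: DataBundle) -> None:
        if self.tol < 0 or self.eps <= 0:
            raise ValueError("tol must be >= 0 and eps > 0")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be positive")
        for fam in bundle.families:
            k = self.dims.get(fam.space)
            if k is None:
                raise ValueError(f"no dimensionality for space {fam.space!r}")
            if not 1 <= k <= len(fam):
                raise ValueError(
                    f"k={k} for space {fam.space!r} outside [1, {len(fam)}] "
                    f"(family {fam.name!r})")

    def weight(self, relation: str) -> float:
        return float(self.weights.get(relation, 1.0))


@dataclass
class FactorModel:
    """The fitted state: one non-negative factor per family plus one
    central matrix per tri-factorized relation."""

    factors: dict            # family name -> (n_f, k_space) array
    centrals: dict           # relation name -> central matrix S_e
    family_ids: dict         # family name -> entity labels
    family_space: dict       # family name -> space id
    dims: dict               # space id -> k

    def copy(self) -> "FactorModel":
        return FactorModel(
            factors={f: G.copy() for f, G in self.factors.items()},
            centrals={r: S.copy() for r, S in self.centrals.items()},
            family_ids={f: list(v) for f, v in self.family_ids.items()},
            family_space=dict(self.family_space),
            dims=dict(self.dims),
        )


@dataclass
class FitResult:
    model: FactorModel
    objective_trace: list
    converged: bool
    iterations: int


@dataclass
class EmbeddingSet:
    """Row-per-entity latent coordinates of one family in one space."""

    family: str
    space: str
    ids: list
    vectors: np.ndarray
    normalized: bool


@dataclass
class ProjectedEmbeddings:
    """Embeddings carried into another latent space through central
    matrices (e.g. genes into the drug space via the drug-target S)."""

    family: str
    target_space: str
    ids: list
    vectors: np.ndarray


def _reconstruction(bundle: DataBundle, model: FactorModel, rel) -> np.ndarray:
    Ga = model.factors[rel.family_row]
    Gb = model.factors[rel.family_col]
    if rel.kind is RelationKind.NMF:
        return Ga @ Gb.T
    S = model.centrals[rel.name]
    return Ga @ S @ Gb.T


def init_factors(bundle: DataBundle, cfg: FitConfig) -> FactorModel:
    """Strictly positive random initialization, scaled per relation.

    Factors are drawn uniform on (0.1, 1.1); central matrices are then
    rescaled exactly so each tri-factorized relation's initial
    reconstruction matches the Frobenius norm of its data, and family
    scale factors for bi-factorized (NMF) relations are solved in the log
    domain by least squares.  Deterministic given ``cfg.seed``.
    """
    cfg.validate(bundle)
    rng = np.random.default_rng(cfg.seed)
    factors = {}
    for fam in bundle.families:
        k = cfg.dims[fam.space]
        factors[fam.name] = rng.uniform(0.1, 1.1, size=(len(fam), k))
    # per-family log-scales matching NMF relation norms (least squares)
    fam_names = [f.name for f in bundle.families]
    fam_pos = {n: i for i, n in enumerate(fam_names)}
    rows, rhs = [], []
    for rel in bundle.relations:
        if rel.kind is not RelationKind.NMF:
            continue
        norm_R = np.linalg.norm(rel.matrix)
        if norm_R == 0:
            continue
        recon = factors[rel.family_row] @ factors[rel.family_col].T
        row = np.zeros(len(fam_names))
        row[fam_pos[rel.family_row]] += 1.0
        row[fam_pos[rel.family_col]] += 1.0
        rows.append(row)
        rhs.append(np.log(norm_R / np.linalg.norm(recon)))
    if rows:
        sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        for name, s in zip(fam_names, np.exp(sol)):
            factors[name] *= s
    centrals = {}
    for rel in bundle.relations:
        if rel.kind is RelationKind.NMF:
            continue
        ka = cfg.dims[bundle.family(rel.family_row).space]
        kb = cfg.dims[bundle.family(rel.family_col).space]
        S = rng.uniform(0.1, 1.1, size=(ka, kb))
        if rel.kind is RelationKind.SNMTF:
            S = (S + S.T) / 2.0
        norm_R = np.linalg.norm(rel.matrix)
        recon = factors[rel.family_row] @ S @ factors[rel.family_col].T
        norm_H = np.linalg.norm(recon)
        if norm_R > 0 and norm_H > 0:
            S = S * (norm_R / norm_H)
        centrals[rel.name] = S
    return FactorModel(
        factors=factors,
        centrals=centrals,
        family_ids={f.name: list(f.entity_ids) for f in bundle.families},
        family_space={f.name: f.space for f in bundle.families},
        dims=dict(cfg.dims),
    )


def joint_objective(bundle: DataBundle, model: FactorModel,
                    weights: dict | None = None) -> float:
    """Sum of squared Frobenius residuals over all relations."""
    total = 0.0
    for rel in bundle.relations:
        w = 1.0 if weights is None else float(weights.get(rel.name, 1.0))
        diff = rel.matrix - _reconstruction(bundle, model, rel)
        total += w * float(np.sum(diff * diff))
    return total


def relation_residuals(bundle: DataBundle, model: FactorModel) -> dict:
    """Relative Frobenius residual per relation (NaN for zero matrices)."""
    out = {}
    for rel in bundle.relations:
        norm_R = np.linalg.norm(rel.matrix)
        err = np.linalg.norm(rel.matrix - _reconstruction(bundle, model, rel))
        out[rel.name] = err / norm_R if norm_R > 0 else float("nan")
    return out


def update_step(bundle: DataBundle, model: FactorModel,
                eps: float = 1e-12, weights: dict | None = None) -> FactorModel:
    """One synchronized round of multiplicative updates.

    Factors are swept in bundle family order, each update aggregating the
    numerator/denominator gradient parts over every incident relation
    (both halves when a family occupies both sides, as in SNMTF); central
    matrices are updated afterwards and symmetric ones re-symmetrized.
    Non-negativity is preserved by construction.
    """
    model = model.copy()

    def w(rel):
        return 1.0 if weights is None else float(weights.get(rel.name, 1.0))

    for fam in bundle.families:
        G = model.factors[fam.name]
        num = np.zeros_like(G)
        den = np.zeros_like(G)
        touched = False
        for rel in bundle.relations:
            if fam.name not in (rel.family_row, rel.family_col):
                continue
            touched = True
            R = rel.matrix
            wr = w(rel)
            if rel.kind is RelationKind.NMF:
                if rel.family_row == fam.name:
                    Gb = model.factors[rel.family_col]
                    num += wr * (R @ Gb)
                    den += wr * (G @ (Gb.T @ Gb))
                if rel.family_col == fam.name:
                    Ga = model.factors[rel.family_row]
                    num += wr * (R.T @ Ga)
                    den += wr * (G @ (Ga.T @ Ga))
            else:
                S = model.centrals[rel.name]
                if rel.family_row == fam.name:
                    Gb = model.factors[rel.family_col]
                    num += wr * (R @ Gb @ S.T)
                    den += wr * (G @ (S @ (Gb.T @ Gb) @ S.T))
                if rel.family_col == fam.name:
                    Ga = model.factors[rel.family_row]
                    num += wr * (R.T @ Ga @ S)
                    den += wr * (G @ (S.T @ (Ga.T @ Ga) @ S))
        if touched:
            model.factors[fam.name] = G * num / (den + eps)
    for rel in bundle.relations:
        if rel.kind is RelationKind.NMF:
            continue
        S = model.centrals[rel.name]
        Ga = model.factors[rel.family_row]
        Gb = model.factors[rel.family_col]
        num = Ga.T @ rel.matrix @ Gb
        den = (Ga.T @ Ga) @ S @ (Gb.T @ Gb)
        S = S * num / (den + eps)
        if rel.kind is RelationKind.SNMTF:
            S = (S + S.T) / 2.0
        model.centrals[rel.name] = S
    return model


def fit(bundle: DataBundle, cfg: FitConfig) -> FitResult:
    """Run multiplicative updates to convergence, best of ``n_restarts``.

    Convergence: relative objective change below ``cfg.tol``.  The
    objective trace (one value per iteration, starting from the initial
    model) is recorded; a non-finite objective aborts with a diagnostic.
    """
    cfg.validate(bundle)
    best: FitResult | None = None
    for restart in range(cfg.n_restarts):
        seed = cfg.seed + restart
        model = init_factors(
            bundle, FitConfig(dims=cfg.dims, max_iter=cfg.max_iter,
                              tol=cfg.tol, eps=cfg.eps, seed=seed,
                              weights=cfg.weights))
        trace = [joint_objective(bundle, model, cfg.weights)]
        converged = False
        iterations = 0
        for it in range(cfg.max_iter):
            model = update_step(bundle, model, cfg.eps, cfg.weights)
            J = joint_objective(bundle, model, cfg.weights)
            if not np.isfinite(J):
                raise FloatingPointError(
                    f"objective became non-finite at iteration {it + 1} "
                    f"(restart {restart}, seed {seed})")
            trace.append(J)
            iterations = it + 1
            prev = trace[-2]
            if abs(prev - J) <= cfg.tol * max(prev, np.finfo(float).tiny):
                converged = True
                break
        result = FitResult(model=model, objective_trace=trace,
                           converged=converged, iterations=iterations)
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = result
    return best


def embeddings_of(model: FactorModel, family: str,
                  normalize: bool = True) -> EmbeddingSet:
    """Rows of the family's factor, optionally scaled to unit norm.

    Zero rows cannot be normalized; they are left at zero with a logged
    warning (downstream cosine machinery treats them explicitly).
    """
    if family not in model.factors:
        raise KeyError(f"unknown family {family!r}")
    G = model.factors[family].copy()
    if normalize:
        norms = np.linalg.norm(G, axis=1)
        zero = norms == 0
        if np.any(zero):
            log.warning("%d zero-norm rows in family %r left unnormalized",
                        int(zero.sum()), family)
        norms[zero] = 1.0
        G = G / norms[:, None]
    return EmbeddingSet(family=family, space=model.family_space[family],
                        ids=list(model.family_ids[family]), vectors=G,
                        normalized=normalize)


def fold_in(model: FactorModel, bundle: DataBundle, family: str,
            new_rows: dict, ids: list | None = None) -> EmbeddingSet:
    """Project unseen entities of one family into its latent space.

    ``new_rows`` maps relation names to arrays of shape (n_new, n_other)
    holding the unseen entities' data rows in those relations (if the
    family sits on the column side of a relation, supply the entity's
    *column* of that relation as a row vector).  For each entity the
    embedding solves::

        min_{g >= 0}  sum_e || r_e - g M_e^T ||^2

    with M_e = G_other S_e^T (NMTF row side), G_other (NMF) or the
    matching orientation on the column side — a non-negative least-squares
    problem on the stacked system.  Existing factors are unchanged.
    Relations that are themselves the prediction target (e.g. diagnosis
    when placing new patients) should simply be left out of ``new_rows``.
    """
    if not new_rows:
        raise ValueError("no incident relation rows supplied")
    k = model.dims[model.family_space[family]]
    blocks = {}
    n_new = None
    for rel_name, rows in new_rows.items():
        rel = bundle.relation(rel_name)
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if family == rel.family_row and family == rel.family_col:
            raise ValueError(
                f"relation {rel_name!r} links {family!r} to itself; fold-in "
                "against the trained factor of the same family is ambiguous")
        if family == rel.family_row:
            other = model.factors[rel.family_col]
            if rel.kind is RelationKind.NMF:
                M = other
            else:
                M = other @ model.centrals[rel_name].T
        elif family == rel.family_col:
            other = model.factors[rel.family_row]
            if rel.kind is RelationKind.NMF:
                M = other
            else:
                M = other @ model.centrals[rel_name]
        else:
            raise ValueError(f"family {family!r} not in relation {rel_name!r}")
        if rows.shape[1] != M.shape[0]:
            raise ValueError(
                f"relation {rel_name!r}: rows have length {rows.shape[1]}, "
                f"expected {M.shape[0]}")
        if n_new is None:
            n_new = rows.shape[0]
        elif rows.shape[0] != n_new:
            raise ValueError("inconsistent number of unseen entities")
        blocks[rel_name] = (M, rows)
    A = np.vstack([M for M, _ in blocks.values()])
    B = np.hstack([rows for _, rows in blocks.values()])  # (n_new, sum n_other)
    out = np.zeros((n_new, k))
    for i in range(n_new):
        out[i], _ = scipy.optimize.nnls(A, B[i])
    ids = list(ids) if ids is not None else [f"new_{i}" for i in range(n_new)]
    return EmbeddingSet(family=family, space=model.family_space[family],
                        ids=ids, vectors=out, normalized=False)


def feature_space_projection(model: FactorModel, family: str,
                             via: list) -> ProjectedEmbeddings:
    """Carry a family's embeddings into another space through centrals.

    ``via`` names one or more tri-factorized relations whose central
    matrices (all of identical shape, summed) link the family's space to
    the target space; the result is ``G_f @ S.T``.  With genes and the
    drug-target central this lands genes in the drug space; with the sum
    of the expression and mutation centrals, in the patient space.
    """
    if family not in model.factors:
        raise KeyError(f"unknown family {family!r}")
    if not via:
        raise ValueError("no central matrices given")
    S = None
    for rel_name in via:
        if rel_name not in model.centrals:
            raise KeyError(f"no central matrix for relation {rel_name!r}")
        Se = model.centrals[rel_name]
        if S is None:
            S = Se.copy()
        elif Se.shape != S.shape:
            raise ValueError("central matrices in `via` have differing shapes")
        else:
            S = S + Se
    G = model.factors[family]
    if S.shape[1] != G.shape[1]:
        raise ValueError(
            f"central shape {S.shape} incompatible with factor width "
            f"{G.shape[1]}; expected (k_target, {G.shape[1]})")
    k_target = S.shape[0]
    target_space = next((s for s, kk in model.dims.items() if kk == k_target),
                        f"k{k_target}")
    return ProjectedEmbeddings(family=family, target_space=target_space,
                               ids=list(model.family_ids[family]),
                               vectors=G @ S.T)


def select_hyperparameters(bundle: DataBundle, grid: dict,
                           patient_labels: dict,
                           patient_family: str = "patients",
                           cancer_family: str = "cancers",
                           max_iter: int = 200, tol: float = 1e-5,
                           seed: int = 0, n_restarts: int = 1):
    """Grid search over latent dimensionalities.

    Every combination in the per-space candidate grid is fitted and scored
    by the macro-F1 of the classifier assigning each patient to the
    cosine-nearest cancer-type embedding; the argmax is returned (ties
    broken by the lexicographically smallest dimension tuple).  Returns
    ``(best FitConfig, scores)`` where ``scores`` maps dimension tuples to
    macro-F1.
    """
    from .evaluation import nearest_centroid_macro_f1

    spaces = list(grid)
    if not spaces or any(not grid[s] for s in spaces):
        raise ValueError("empty hyperparameter grid")
    scores: dict = {}
    best_key, best_score = None, -1.0
    for combo in itertools.product(*(sorted(grid[s]) for s in spaces)):
        dims = dict(zip(spaces, combo))
        cfg = FitConfig(dims=dims, max_iter=max_iter, tol=tol,
                        seed=seed, n_restarts=n_restarts)
        result = fit(bundle, cfg)
        f1 = nearest_centroid_macro_f1(
            embeddings_of(result.model, patient_family, normalize=True),
            embeddings_of(result.model, cancer_family, normalize=True),
            patient_labels)
        scores[combo] = f1
        if f1 > best_score or (f1 == best_score and combo < best_key):
            best_key, best_score = combo, f1
    best_dims = dict(zip(spaces, best_key))
    return FitConfig(dims=best_dims, max_iter=max_iter, tol=tol, seed=seed,
                     n_restarts=n_restarts), scores


#: latent dimensionalities selected on the original pan-cancer corpus
#: (21 cancers, ~8k patients): k1=21, k2=70, k3=40.
REFERENCE_DIMS = {"space1": 21, "space2": 70, "space3": 40}

#: the grid searched on that corpus.
REFERENCE_GRID = {"space1": [2, 5, 10, 15, 21],
                  "space2": [70, 80, 90, 100, 110],
                  "space3": [40, 50, 60, 70, 80]}
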