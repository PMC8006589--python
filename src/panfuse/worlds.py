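"""Synthetic multipartite worlds with planted ground truth.

The generator emits the same eight-relation topology as the real
pan-cancer corpus (diagnosis, expression, mutation, PPI, gene-complex,
gene-pathway, drug-target, drug-drug similarity) at desk scale, with an
explicit generative mechanism whose every association is recoverable:

* genes are partitioned into pathway-like modules; complexes are random
  within-module subsets; the PPI network is a planted-partition graph;
* each cancer type activates a distinct subset of modules and its driver
  genes are sampled from those modules;
* expression = baseline + activation boost for active modules + truncated
  Gaussian noise; mutations are Bernoulli with an elevated rate for a
  cancer's drivers within its cohort;
* each drug targets genes of one module; drug-drug similarity is the
  Jaccard index of target sets;
* a cancer-drug association is planted iff the drug targets a module that
  is active and carries drivers for that cancer; patient-drug response is
  a deterministic function of the patient's active modules and the drug's
  targets, flipped with small label noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relational import DataBundle, EntityFamily, Relation, RelationKind

__all__ = [
    "WorldParams",
    "PlantedWorld",
    "generate_world",
    "planted_truth",
    "matched_dims",
    "emit_world",
    "planted_lowrank_bundle",
]


@dataclass
class WorldParams:
    """Scale and noise knobs of the generated world.

    Defaults give a small world (10 cancers x 20 patients, 500 genes in
    25 modules, 20 complexes, 50 drugs) on which the full pipeline — fit,
    cross-validated link prediction and the evaluation suite — runs in
    minutes on one CPU while leaving every planted signal recoverable.
    ``noise_sd`` is the expression noise standard deviation relative to an
    activation boost of 1.
    """

    n_cancers: int = 10
    patients_per_cancer: int = 20
    n_genes: int = 500
    n_modules: int = 25
    n_complexes: int = 20
    n_drugs: int = 50
    modules_per_cancer: int = 3
    noise_sd: float = 0.1
    mutation_rate: float = 0.02
    driver_mutation_rate: float = 0.5
    driver_fraction: float = 0.2
    expression_baseline: float = 1.0
    activation_boost: float = 1.0
    ppi_within: float = 0.3
    ppi_between: float = 0.01
    response_label_noise: float = 0.02
    n_response_records: int = 2589
    seed: int = 0

    def validate(self) -> None:
        positive = ["n_cancers", "patients_per_cancer", "n_genes", "n_modules",
                    "n_complexes", "n_drugs", "modules_per_cancer"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules > self.n_genes:
            raise ValueError("more modules than genes")
        if self.modules_per_cancer > self.n_modules:
            raise ValueError("modules_per_cancer exceeds n_modules")
        if not 0 < self.driver_fraction < 1:
            raise ValueError("driver_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PlantedWorld:
    """The ground truth behind a generated bundle."""

    params: WorldParams
    modules: dict                 # module id -> list of gene ids
    gene_module: dict             # gene id -> module id
    complexes: dict               # complex id -> list of gene ids
    cancer_active: dict           # cancer id -> list of active module ids
    drivers: dict                 # cancer id -> list of driver gene ids
    drug_module: dict             # drug id -> targeted module id
    drug_targets: dict            # drug id -> list of target gene ids
    diagnosis: dict               # patient id -> cancer id
    tissue: dict                  # patient id -> tissue label
    cancer_gene_true: set = field(default_factory=set)
    cancer_drug_true: set = field(default_factory=set)
    response: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    prognostic_gene: str | None = None


def generate_world(params: WorldParams) -> tuple[PlantedWorld, DataBundle]:
    """Generate a planted world and its eight-relation bundle.

    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params

    cancers = [f"C{i:02d}" for i in range(p.n_cancers)]
    patients = [f"P{i:04d}" for i in range(p.n_cancers * p.patients_per_cancer)]
    genes = [f"g{i:04d}" for i in range(p.n_genes)]
    module_ids = [f"M{i:02d}" for i in range(p.n_modules)]
    complex_ids = [f"X{i:02d}" for i in range(p.n_complexes)]
    drugs = [f"D{i:02d}" for i in range(p.n_drugs)]

    # modules: contiguous near-equal partition of the gene list
    gene_chunks = np.array_split(np.arange(p.n_genes), p.n_modules)
    modules = {m: [genes[i] for i in chunk]
               for m, chunk in zip(module_ids, gene_chunks)}
    gene_module = {g: m for m, members in modules.items() for g in members}
    module_index = {m: i for i, m in enumerate(module_ids)}
    gene_mod_idx = np.array([module_index[gene_module[g]] for g in genes])

    # complexes: random within-module subsets
    complexes = {}
    for cx in complex_ids:
        m = module_ids[rng.integers(p.n_modules)]
        members = modules[m]
        size = int(rng.integers(3, min(9, len(members)) + 1))
        complexes[cx] = sorted(rng.choice(members, size=size, replace=False))

    # PPI: planted-partition graph, symmetric, zero diagonal
    same = gene_mod_idx[:, None] == gene_mod_idx[None, :]
    prob = np.where(same, p.ppi_within, p.ppi_between)
    upper = np.triu(rng.random((p.n_genes, p.n_genes)) < prob, k=1)
    ppi = (upper | upper.T).astype(float)

    # each cancer activates a distinct subset of modules; drivers sampled
    # from the active modules
    cancer_active: dict = {}
    seen_sets = set()
    for c in cancers:
        while True:
            act = tuple(sorted(rng.choice(p.n_modules, size=p.modules_per_cancer,
                                          replace=False)))
            if act not in seen_sets:
                seen_sets.add(act)
                break
        cancer_active[c] = [module_ids[i] for i in act]
    drivers = {}
    for c in cancers:
        pool = [g for m in cancer_active[c] for g in modules[m]]
        n_driver = max(1, int(round(p.driver_fraction * len(pool))))
        drivers[c] = sorted(rng.choice(pool, size=n_driver, replace=False))

    diagnosis = {}
    for ci, c in enumerate(cancers):
        for j in range(p.patients_per_cancer):
            diagnosis[patients[ci * p.patients_per_cancer + j]] = c
    tissue = {pt: f"T{cancers.index(c) // 2:02d}" for pt, c in diagnosis.items()}

    # expression: baseline + boost on active modules + truncated noise
    active_mod = np.zeros((p.n_cancers, p.n_modules), dtype=bool)
    for ci, c in enumerate(cancers):
        for m in cancer_active[c]:
            active_mod[ci, module_index[m]] = True
    active_gene = active_mod[:, gene_mod_idx]
    diag_idx = np.array([cancers.index(diagnosis[pt]) for pt in patients])
    expr = (p.expression_baseline
            + p.activation_boost * active_gene[diag_idx].astype(float)
            + rng.normal(0.0, p.noise_sd, size=(len(patients), p.n_genes)))
    expr = np.clip(expr, 0.0, None)

    # mutations: background rate, elevated for the cohort's drivers
    mut_prob = np.full((len(patients), p.n_genes), p.mutation_rate)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for ci, c in enumerate(cancers):
        cols = [gene_pos[g] for g in drivers[c]]
        rows = np.where(diag_idx == ci)[0]
        mut_prob[np.ix_(rows, cols)] = p.driver_mutation_rate
    mutation = (rng.random((len(patients), p.n_genes)) < mut_prob).astype(float)

    # drugs: one targeted module each, similarity = Jaccard of target sets
    drug_module = {}
    drug_targets = {}
    for di, d in enumerate(drugs):
        m = module_ids[di % p.n_modules]
        drug_module[d] = m
        members = modules[m]
        size = int(rng.integers(2, min(6, len(members)) + 1))
        drug_targets[d] = sorted(rng.choice(members, size=size, replace=False))
    target_sets = {d: set(t) for d, t in drug_targets.items()}
    dd = np.zeros((p.n_drugs, p.n_drugs))
    for i, a in enumerate(drugs):
        for j, b in enumerate(drugs):
            inter = len(target_sets[a] & target_sets[b])
            union = len(target_sets[a] | target_sets[b])
            dd[i, j] = inter / union if union else 0.0

    diag_matrix = np.zeros((len(patients), p.n_cancers))
    diag_matrix[np.arange(len(patients)), diag_idx] = 1.0

    gene_complex = np.zeros((p.n_genes, p.n_complexes))
    for j, cx in enumerate(complex_ids):
        gene_complex[[gene_pos[g] for g in complexes[cx]], j] = 1.0
    gene_pathway = np.zeros((p.n_genes, p.n_modules))
    gene_pathway[np.arange(p.n_genes), gene_mod_idx] = 1.0
    drug_target_matrix = np.zeros((p.n_drugs, p.n_genes))
    for i, d in enumerate(drugs):
        drug_target_matrix[i, [gene_pos[g] for g in drug_targets[d]]] = 1.0

    # planted associations
    cancer_gene_true = {(c, g) for c in cancers for g in drivers[c]}
    driver_modules = {c: {gene_module[g] for g in drivers[c]} for c in cancers}
    cancer_drug_true = {
        (c, d) for c in cancers for d in drugs
        if drug_module[d] in cancer_active[c]
        and drug_module[d] in driver_modules[c]
    }

    # patient-drug responses: drug hits an active module of the patient's
    # cancer -> positive, flipped with small label noise
    all_pairs = [(pt, d) for pt in patients for d in drugs]
    order = rng.permutation(len(all_pairs))
    n_rec = min(p.n_response_records, len(all_pairs))
    records = []
    for idx in order[:n_rec]:
        pt, d = all_pairs[idx]
        outcome = int(drug_module[d] in cancer_active[diagnosis[pt]])
        if rng.random() < p.response_label_noise:
            outcome = 1 - outcome
        records.append((pt, d, outcome))
    response = pd.DataFrame(records, columns=["patient", "drug", "response"])

    # survival: shorter times for patients over-expressing a planted
    # prognostic gene (a driver of the first cancer)
    prognostic_gene = drivers[cancers[0]][0]
    gcol = expr[:, gene_pos[prognostic_gene]]
    scale = np.where(gcol > gcol.mean(), 20.0, 60.0)
    times = rng.exponential(scale)
    events = (rng.random(len(patients)) < 0.8).astype(int)
    survival = pd.DataFrame({"time": times, "event": events}, index=patients)
    survival.index.name = "patient"

    families = [
        EntityFamily("patients", patients, "space1"),
        EntityFamily("cancers", cancers, "space1"),
        EntityFamily("genes", genes, "space2"),
        EntityFamily("pathways", module_ids, "space2"),
        EntityFamily("complexes", complex_ids, "space2"),
        EntityFamily("drugs", drugs, "space3"),
    ]
    relations = [
        Relation("diagnosis", "patients", "cancers", RelationKind.NMF,
                 diag_matrix),
        Relation("expression", "patients", "genes", RelationKind.NMTF, expr),
        Relation("mutation", "patients", "genes", RelationKind.NMTF, mutation),
        Relation("ppi", "genes", "genes", RelationKind.SNMTF, ppi),
        Relation("gene_complex", "genes", "complexes", RelationKind.NMF,
                 gene_complex),
        Relation("gene_pathway", "genes", "pathways", RelationKind.NMF,
                 gene_pathway),
        Relation("drug_target", "drugs", "genes", RelationKind.NMTF,
                 drug_target_matrix),
        Relation("drug_similarity", "drugs", "drugs", RelationKind.SNMTF, dd),
    ]
    bundle = DataBundle(families, relations, matched_dims_for(p))
    world = PlantedWorld(
        params=p, modules=modules, gene_module=gene_module,
        complexes=complexes, cancer_active=cancer_active, drivers=drivers,
        drug_module=drug_module, drug_targets=drug_targets,
        diagnosis=diagnosis, tissue=tissue,
        cancer_gene_true=cancer_gene_true, cancer_drug_true=cancer_drug_true,
        response=response, survival=survival, prognostic_gene=prognostic_gene)
    return world, bundle


def matched_dims_for(params: WorldParams) -> dict:
    """Latent dimensionalities matching the planted ranks.

    Each space's k is capped by its smallest family (k cannot exceed the
    number of entities in any family embedded there)."""
    return {"space1": params.n_cancers,
            "space2": min(params.n_modules, params.n_complexes,
                          params.n_genes),
            "space3": min(params.n_modules, params.n_drugs)}


def matched_dims(world: PlantedWorld) -> dict:
    return matched_dims_for(world.params)


def planted_truth(world: PlantedWorld, task: str):
    """Ground-truth pair sets (or response records) for one task.

    Tasks: ``cancer-gene``, ``cancer-drug``, ``cancer-pathway`` return
    ``(positives, negatives)`` pair lists; ``response`` returns the
    response record table restricted to drugs with both outcome classes.
    """
    cancers = list(world.cancer_active)
    if task == "cancer-gene":
        universe = [(c, g) for c in cancers for g in world.gene_module]
        pos = set(world.cancer_gene_true)
    elif task == "cancer-drug":
        universe = [(c, d) for c in cancers for d in world.drug_module]
        pos = set(world.cancer_drug_true)
    elif task == "cancer-pathway":
        universe = [(c, m) for c in cancers for m in world.modules]
        pos = {(c, m) for c in cancers for m in world.cancer_active[c]}
    elif task == "response":
        resp = world.response
        keep = resp.groupby("drug")["response"].nunique()
        return resp[resp["drug"].isin(keep[keep == 2].index)].reset_index(
            drop=True)
    else:
        raise ValueError(f"unknown task {task!r}")
    positives = sorted(pos)
    negatives = [pair for pair in universe if pair not in pos]
    return positives, negatives


def emit_world(world: PlantedWorld, bundle: DataBundle, out_dir: str) -> None:
    """Write the bundle (labeled TSVs + YAML config), truth tables, GMT
    annotations and the survival table to ``out_dir``."""
    import yaml

    from .io import write_gmt, write_labeled_matrix
    from .relational import LabeledMatrix

    os.makedirs(out_dir, exist_ok=True)
    cfg = {"spaces": dict(bundle.space_dims_default),
           "families": [{"name": f.name, "space": f.space}
                        for f in bundle.families],
           "relations": []}
    for rel in bundle.relations:
        fname = f"{rel.name}.tsv"
        write_labeled_matrix(
            LabeledMatrix(bundle.family(rel.family_row).entity_ids,
                          bundle.family(rel.family_col).entity_ids,
                          rel.matrix),
            os.path.join(out_dir, fname))
        cfg["relations"].append({"name": rel.name, "rows": rel.family_row,
                                 "cols": rel.family_col,
                                 "kind": rel.kind.value, "path": fname})
    with open(os.path.join(out_dir, "bundle.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh)
    write_gmt(world.modules, os.path.join(out_dir, "modules.gmt"))
    write_gmt(world.complexes, os.path.join(out_dir, "complexes.gmt"))
    for task in ("cancer-gene", "cancer-drug", "cancer-pathway"):
        pos, _ = planted_truth(world, task)
        pd.DataFrame(pos, columns=["cancer", "entity"]).to_csv(
            os.path.join(out_dir, f"true_{task}.tsv"), sep="\t", index=False)
    world.response.to_csv(os.path.join(out_dir, "response.tsv"), sep="\t",
                          index=False)
    world.survival.to_csv(os.path.join(out_dir, "survival.tsv"), sep="\t")


def _block_factor(rng, n: int, k: int, background: float = 0.2) -> np.ndarray:
    """Strictly positive factor with one dominant coordinate per row.

    The dominant-coordinate structure keeps the factor Gram matrices well
    conditioned (a flat strictly positive draw is dominated by its rank-1
    mean component, which makes recovery by multiplicative updates
    needlessly slow); the positive background keeps the optimum away from
    the non-negativity boundary.  Every latent dimension is guaranteed at
    least one dominant row.
    """
    G = background + background * rng.random((n, k))
    dominant = rng.integers(0, k, size=n)
    dominant[:k] = np.arange(k)
    G[np.arange(n), dominant] = 1.0 + rng.random(n)
    return G


def planted_lowrank_bundle(seed: int = 0, sizes: dict | None = None,
                           dims: dict | None = None):
    """A bundle constructed exactly as products of planted factors.

    Covers all three factorization kinds (one NMTF, one SNMTF, two NMF)
    over two spaces so a rank-matched fit can drive every relation's
    relative residual toward zero.  The non-shared NMF factors are scaled
    so all relations carry comparable Frobenius norm — in an unweighted
    joint objective a relation with a much smaller norm receives a
    proportionally small gradient share and converges far more slowly.
    Returns ``(bundle, truth)`` where ``truth`` maps family/relation names
    to the planted factors and centrals.
    """
    rng = np.random.default_rng(seed)
    sizes = sizes or {"A": 40, "B": 30, "C": 20, "D": 15}
    dims = dims or {"space1": 2, "space2": 2}
    k1, k2 = dims["space1"], dims["space2"]
    GA = _block_factor(rng, sizes["A"], k1)
    GB = _block_factor(rng, sizes["B"], k2)
    GC = _block_factor(rng, sizes["C"], k2)
    GD = _block_factor(rng, sizes["D"], k1)
    S_ab = rng.uniform(0.5, 1.5, size=(k1, k2))
    S_bb = rng.uniform(0.5, 1.5, size=(k2, k2))
    S_bb = (S_bb + S_bb.T) / 2.0
    R_ab = GA @ S_ab @ GB.T
    target = np.linalg.norm(R_ab)
    GC *= target / np.linalg.norm(GB @ GC.T)
    GD *= target / np.linalg.norm(GA @ GD.T)
    families = [
        EntityFamily("A", [f"a{i}" for i in range(sizes["A"])], "space1"),
        EntityFamily("B", [f"b{i}" for i in range(sizes["B"])], "space2"),
        EntityFamily("C", [f"c{i}" for i in range(sizes["C"])], "space2"),
        EntityFamily("D", [f"d{i}" for i in range(sizes["D"])], "space1"),
    ]
    relations = [
        Relation("ab", "A", "B", RelationKind.NMTF, R_ab),
        Relation("bb", "B", "B", RelationKind.SNMTF, GB @ S_bb @ GB.T),
        Relation("bc", "B", "C", RelationKind.NMF, GB @ GC.T),
        Relation("ad", "A", "D", RelationKind.NMF, GA @ GD.T),
    ]
    bundle = DataBundle(families, relations, dict(dims))
    truth = {"A": GA, "B": GB, "C": GC, "D": GD, "ab": S_ab, "bb": S_bb}
    return bundle, truth
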