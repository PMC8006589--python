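"""Declarative data model for multipartite relational data.

Six entity families (cancer types, patients, genes, pathways, complexes,
drugs) are grouped into three shared latent spaces; the relations between
them are non-negative matrices, each factorized with one of three schemes:

* ``NMF``    — R ≈ G_a G_bᵀ, both families share one latent space;
* ``NMTF``   — R ≈ G_a S G_bᵀ, the two families live in different spaces
  and a central matrix S links them;
* ``SNMTF``  — A ≈ G S Gᵀ for a square symmetric relation within one
  family (interaction networks, chemical similarities).

The classes here only describe and validate that structure; the joint
optimization lives in :mod:`panfuse.factorization`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RelationKind",
    "EntityFamily",
    "Relation",
    "DataBundle",
    "LabeledMatrix",
    "ValidationIssue",
    "ValidationReport",
    "validate_bundle",
    "subset_family",
]

#: tolerance used when checking that SNMTF input matrices are symmetric
SYMMETRY_TOL = 1e-9


class RelationKind(str, enum.Enum):
    """Factorization scheme assigned to a relation."""

    NMF = "NMF"
    NMTF = "NMTF"
    SNMTF = "SNMTF"


@dataclass
class LabeledMatrix:
    """A dense real matrix with row and column string labels."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"label counts {(len(self.row_labels), len(self.col_labels))} "
                f"do not match matrix shape {self.values.shape}"
            )

    def reindex(self, row_labels=None, col_labels=None) -> "LabeledMatrix":
        """Return a copy with rows/cols reordered to the given label lists.

        The requested labels must be a permutation of the present ones;
        alignment is by label, never by position.
        """
        values = self.values
        rows = list(self.row_labels)
        cols = list(self.col_labels)
        if row_labels is not None:
            if set(row_labels) != set(rows) or len(row_labels) != len(rows):
                raise ValueError("row label sets differ; cannot align")
            pos = {lab: i for i, lab in enumerate(rows)}
            values = values[[pos[lab] for lab in row_labels], :]
            rows = list(row_labels)
        if col_labels is not None:
            if set(col_labels) != set(cols) or len(col_labels) != len(cols):
                raise ValueError("column label sets differ; cannot align")
            pos = {lab: i for i, lab in enumerate(cols)}
            values = values[:, [pos[lab] for lab in col_labels]]
            cols = list(col_labels)
        return LabeledMatrix(rows, cols, values)


@dataclass
class EntityFamily:
    """A named group of entities embedded together in one latent space.

    Parameters
    ----------
    name
        Family identifier, e.g. ``"patients"``.
    entity_ids
        Ordered unique string labels; matrix rows/columns follow this order.
    space
        Latent-space identifier.  By convention ``"space1"`` holds patients
        and cancer types, ``"space2"`` genes/pathways/complexes and
        ``"space3"`` drugs, but any consistent assignment is accepted.
    """

    name: str
    entity_ids: list[str]
    space: str

    def __post_init__(self) -> None:
        self.entity_ids = list(self.entity_ids)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError(f"family {self.name!r}: entity ids are not unique")

    def __len__(self) -> int:
        return len(self.entity_ids)

    @property
    def index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.entity_ids)}


@dataclass
class Relation:
    """A typed non-negative relation matrix between two entity families."""

    name: str
    family_row: str
    family_col: str
    kind: RelationKind
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.kind = RelationKind(self.kind)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"relation {self.name!r}: matrix must be 2-D")


def _check_relation(rel: Relation, fam_row: EntityFamily, fam_col: EntityFamily,
                    strict: bool = True) -> list[str]:
    """Return a list of human-readable structural problems (empty if none)."""
    problems = []
    if rel.matrix.shape != (len(fam_row), len(fam_col)):
        problems.append(
            f"shape {rel.matrix.shape} does not match families "
            f"({len(fam_row)}, {len(fam_col)})"
        )
        return problems
    if rel.kind is RelationKind.SNMTF:
        if rel.family_row != rel.family_col:
            problems.append("SNMTF requires identical row and column families")
        elif rel.matrix.shape[0] != rel.matrix.shape[1]:
            problems.append("SNMTF requires a square matrix")
        elif not np.allclose(rel.matrix, rel.matrix.T, atol=SYMMETRY_TOL, rtol=0):
            problems.append("SNMTF matrix is not symmetric within 1e-9")
    elif rel.kind is RelationKind.NMF:
        if rel.family_row == rel.family_col:
            problems.append(
                "within-family relations must use SNMTF, not NMF")
        elif fam_row.space != fam_col.space:
            problems.append(
                f"NMF requires both families in one latent space "
                f"({fam_row.space} != {fam_col.space})"
            )
    elif rel.kind is RelationKind.NMTF:
        if fam_row.space == fam_col.space:
            problems.append(
                "NMTF requires the two families to live in different spaces"
            )
    return problems


@dataclass
class DataBundle:
    """The complete multipartite input: families plus typed relations."""

    families: list[EntityFamily]
    relations: list[Relation]
    space_dims_default: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")
        self._fam = {f.name: f for f in self.families}
        for rel in self.relations:
            for side in (rel.family_row, rel.family_col):
                if side not in self._fam:
                    raise ValueError(
                        f"relation {rel.name!r} references unknown family {side!r}"
                    )
            problems = _check_relation(rel, self._fam[rel.family_row],
                                       self._fam[rel.family_col])
            if problems:
                raise ValueError(f"relation {rel.name!r}: " + "; ".join(problems))

    def family(self, name: str) -> EntityFamily:
        return self._fam[name]

    def relation(self, name: str) -> Relation:
        for rel in self.relations:
            if rel.name == name:
                return rel
        raise KeyError(name)

    @property
    def spaces(self) -> list[str]:
        seen: dict = {}
        for f in self.families:
            seen.setdefault(f.space, None)
        return list(seen)

    def relations_of(self, family: str) -> list[Relation]:
        return [r for r in self.relations
                if family in (r.family_row, r.family_col)]


@dataclass
class ValidationIssue:
    category: str          # negativity | symmetry | orphan_family | kind_space | shape
    where: str             # relation or family name
    detail: str


@dataclass
class ValidationReport:
    ok: bool
    issues: list[ValidationIssue]
    density: dict          # relation name -> fraction of nonzero entries

    def by_category(self, category: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.category == category]


def validate_bundle(bundle: DataBundle) -> ValidationReport:
    """Audit a bundle: per-relation density, negativity, symmetry, orphans.

    Reporting only — never raises.  ``ok`` is true iff every invariant of
    the data model holds.
    """
    issues: list[ValidationIssue] = []
    density: dict = {}
    used = set()
    for rel in bundle.relations:
        used.update((rel.family_row, rel.family_col))
        m = rel.matrix
        density[rel.name] = float(np.count_nonzero(m)) / max(m.size, 1)
        neg = np.argwhere(m < 0)
        for i, j in neg[:100]:  # cap the listing, count is in detail
            issues.append(ValidationIssue(
                "negativity", rel.name,
                f"entry ({i},{j}) = {m[i, j]:g} < 0 ({len(neg)} total)"))
        fam_row = bundle.family(rel.family_row)
        fam_col = bundle.family(rel.family_col)
        for problem in _check_relation(rel, fam_row, fam_col):
            category = "symmetry" if "symmetric" in problem else (
                "shape" if "shape" in problem else "kind_space")
            issues.append(ValidationIssue(category, rel.name, problem))
    for fam in bundle.families:
        if fam.name not in used:
            issues.append(ValidationIssue(
                "orphan_family", fam.name, "family appears in no relation"))
    return ValidationReport(ok=not issues, issues=issues, density=density)


def subset_family(bundle: DataBundle, family: str, keep_ids: list[str]) -> DataBundle:
    """Return a new bundle restricted to ``keep_ids`` of one family.

    Rows/columns of every relation touching the family are filtered in the
    order given by ``keep_ids``; other families are untouched.  Used e.g.
    to hold out patients before a fold-in experiment.
    """
    fam = bundle.family(family)
    pos = fam.index
    idx = [pos[i] for i in keep_ids]
    new_families = [
        EntityFamily(f.name, keep_ids if f.name == family else f.entity_ids, f.space)
        for f in bundle.families
    ]
    new_relations = []
    for rel in bundle.relations:
        m = rel.matrix
        if rel.family_row == family:
            m = m[idx, :]
        if rel.family_col == family:
            m = m[:, idx]
        new_relations.append(Relation(rel.name, rel.family_row, rel.family_col,
                                      rel.kind, m))
    return DataBundle(new_families, new_relations,
                      dict(bundle.space_dims_default))
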