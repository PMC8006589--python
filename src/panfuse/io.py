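"""Readers and writers for the plain-text exchange formats.

* labeled TSV — first row column labels, first column row labels;
* Matrix Market coordinate files with ``<name>.rows`` / ``<name>.cols``
  label sidecars (one label per line);
* GMT gene-set collections (set name, description, members);
* a YAML bundle configuration declaring families, spaces and relation
  files;
* fitted-model persistence (one labeled TSV per factor/central plus a
  YAML manifest).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .relational import (
    DataBundle,
    EntityFamily,
    LabeledMatrix,
    Relation,
    RelationKind,
)

__all__ = [
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_gmt",
    "write_gmt",
    "load_bundle",
    "save_model",
    "load_model",
]


def read_labeled_matrix(path: str, format: str | None = None) -> LabeledMatrix:
    """Read a labeled matrix from TSV or Matrix Market format.

    ``format`` may be ``"tsv"`` or ``"mtx"``; if omitted it is inferred
    from the file suffix.  MTX files must be accompanied by ``<stem>.rows``
    and ``<stem>.cols`` label files.
    """
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"malformed TSV {path!r}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        return LabeledMatrix([str(r) for r in df.index],
                             [str(c) for c in df.columns], values)
    if format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = _read_lines(stem + ".rows")
        cols = _read_lines(stem + ".cols")
        return LabeledMatrix(rows, cols, np.asarray(mat, dtype=float))
    raise ValueError(f"unknown format {format!r}")


def write_labeled_matrix(lm: LabeledMatrix, path: str,
                         format: str | None = None) -> None:
    """Write a labeled matrix; inverse of :func:`read_labeled_matrix`."""
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "tsv"
    if format == "tsv":
        df = pd.DataFrame(lm.values, index=lm.row_labels, columns=lm.col_labels)
        df.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(lm.values), precision=17)
        _write_lines(stem + ".rows", lm.row_labels)
        _write_lines(stem + ".cols", lm.col_labels)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_lines(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str, lines) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(f"{line}\n")


def read_gmt(path: str) -> dict:
    """Read a GMT file into ``{set_name: list of member ids}``."""
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{n}: GMT line needs name, "
                                 "description and >=1 member")
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_gmt(sets: dict, path: str, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([str(name), description, *map(str, members)]))
            fh.write("\n")


def load_bundle(config_path: str) -> DataBundle:
    """Build a validated :class:`DataBundle` from a YAML configuration.

    Schema::

        spaces:            # default latent dimensionality per space
          space1: 10
          space2: 25
        families:
          - {name: patients, space: space1}
          - {name: genes,    space: space2}
        relations:
          - {name: expression, rows: patients, cols: genes,
             kind: NMTF, path: expression.tsv}   # path relative to config

    Family entity orders come from the first relation mentioning each
    family; later relations are re-aligned by label (never by position)
    and must cover the identical label set.  Negative entries are
    rejected: relation matrices must be non-negative.
    """
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(config_path))
    fam_space = {}
    for fam in cfg.get("families", []):
        fam_space[fam["name"]] = fam["space"]
    fam_ids: dict = {}
    relations = []
    for rel in cfg.get("relations", []):
        kind = RelationKind(rel["kind"])
        path = rel["path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        if not os.path.exists(path):
            raise FileNotFoundError(f"relation {rel['name']!r}: missing file {path}")
        lm = read_labeled_matrix(path, rel.get("format"))
        if np.any(lm.values < 0):
            raise ValueError(f"relation {rel['name']!r}: negative entries "
                             "are not allowed in relation matrices")
        for side, labels in (("rows", lm.row_labels), ("cols", lm.col_labels)):
            fam = rel[side]
            if fam not in fam_space:
                raise ValueError(f"relation {rel['name']!r} references "
                                 f"undeclared family {fam!r}")
            if fam not in fam_ids:
                fam_ids[fam] = list(labels)
        lm = lm.reindex(fam_ids[rel["rows"]], fam_ids[rel["cols"]])
        relations.append(Relation(rel["name"], rel["rows"], rel["cols"],
                                  kind, lm.values))
    families = [EntityFamily(name, fam_ids.get(name, []), space)
                for name, space in fam_space.items()]
    return DataBundle(families, relations, dict(cfg.get("spaces", {})))


def save_model(model, out_dir: str) -> None:
    """Persist a fitted factor model as labeled TSVs plus a manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"dims": {s: int(k) for s, k in model.dims.items()},
                "factors": {}, "centrals": {}}
    for fam, G in model.factors.items():
        fname = f"factor_{fam}.tsv"
        cols = [f"dim{j}" for j in range(G.shape[1])]
        write_labeled_matrix(LabeledMatrix(model.family_ids[fam], cols, G),
                             os.path.join(out_dir, fname))
        manifest["factors"][fam] = {"file": fname,
                                    "space": model.family_space[fam]}
    for rel, S in model.centrals.items():
        fname = f"central_{rel}.tsv"
        rows = [f"dim{j}" for j in range(S.shape[0])]
        cols = [f"dim{j}" for j in range(S.shape[1])]
        write_labeled_matrix(LabeledMatrix(rows, cols, S),
                             os.path.join(out_dir, fname))
        manifest["centrals"][rel] = {"file": fname}
    with open(os.path.join(out_dir, "manifest.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh)


def load_model(model_dir: str):
    """Inverse of :func:`save_model`."""
    from .factorization import FactorModel

    with open(os.path.join(model_dir, "manifest.yaml"), encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    factors, family_ids, family_space, centrals = {}, {}, {}, {}
    for fam, info in manifest["factors"].items():
        lm = read_labeled_matrix(os.path.join(model_dir, info["file"]))
        factors[fam] = lm.values
        family_ids[fam] = lm.row_labels
        family_space[fam] = info["space"]
    for rel, info in manifest["centrals"].items():
        centrals[rel] = read_labeled_matrix(
            os.path.join(model_dir, info["file"])).values
    return FactorModel(factors=factors, centrals=centrals,
                       family_ids=family_ids, family_space=family_space,
                       dims={s: int(k) for s, k in manifest["dims"].items()})
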