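"""Shared fixtures: generated worlds, fitted models, random bundles.

Fitted models are memoized per seed at session scope because several test
modules (and the acceptance checks) interrogate the same fits.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from panfuse import factorization as fz
from panfuse import worlds
from panfuse.relational import DataBundle, EntityFamily, Relation, RelationKind


@functools.lru_cache(maxsize=None)
def fitted_world(seed: int):
    """World + rank-matched fit (500 iterations, tight tolerance)."""
    world, bundle = worlds.generate_world(worlds.WorldParams(seed=seed))
    cfg = fz.FitConfig(dims=worlds.matched_dims(world), max_iter=500,
                       tol=1e-7, seed=seed)
    result = fz.fit(bundle, cfg)
    return world, bundle, result


@functools.lru_cache(maxsize=None)
def converged_world(seed: int = 0):
    """Same world fitted to (near) convergence, for fold-in consistency."""
    world, bundle = worlds.generate_world(worlds.WorldParams(seed=seed))
    cfg = fz.FitConfig(dims=worlds.matched_dims(world), max_iter=2000,
                       tol=1e-9, seed=seed)
    result = fz.fit(bundle, cfg)
    return world, bundle, result


@pytest.fixture(scope="session")
def small_world():
    world, bundle, _ = fitted_world(0)
    return world, bundle


@pytest.fixture(scope="session")
def small_fit():
    return fitted_world(0)


def random_bundle(rng) -> DataBundle | None:
    """A random well-formed bundle over two spaces, mixing all kinds."""
    spaces = {"s1": int(rng.integers(2, 4)), "s2": int(rng.integers(2, 4))}
    fams = []
    for i in range(int(rng.integers(2, 5))):
        n = int(rng.integers(5, 12))
        sp = "s1" if rng.random() < 0.5 else "s2"
        fams.append(EntityFamily(f"F{i}", [f"F{i}e{j}" for j in range(n)], sp))
    rels = []
    tries = 0
    target = int(rng.integers(1, 5))
    while len(rels) < target and tries < 60:
        tries += 1
        if len(fams) > 1:
            a, b = rng.choice(len(fams), 2, replace=False)
        else:
            a = b = 0
        fa, fb = fams[a], fams[b]
        kind = rng.choice(["NMF", "NMTF", "SNMTF"])
        if kind == "SNMTF":
            fb = fa
            M = rng.random((len(fa), len(fa)))
            M = (M + M.T) / 2
        elif kind == "NMF":
            if fa.space != fb.space or fa.name == fb.name:
                continue
            M = rng.random((len(fa), len(fb)))
        else:
            if fa.space == fb.space:
                continue
            M = rng.random((len(fa), len(fb)))
        rels.append(Relation(f"r{len(rels)}_{tries}", fa.name, fb.name,
                             RelationKind(kind), M))
    if not rels:
        return None
    used = {r.family_row for r in rels} | {r.family_col for r in rels}
    return DataBundle([f for f in fams if f.name in used], rels, spaces)


def random_bundles(seed: int, n: int):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        b = random_bundle(rng)
        if b is not None:
            out.append(b)
    return out
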