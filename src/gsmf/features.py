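"""Drug and disease feature vectors from bipartite gene-interaction maps.

An entity's vector is the arithmetic mean of its interacting genes' feature
vectors, so drugs, diseases and genes live in one Euclidean space of rank k.
Entities without interacting genes get NaN rows that :func:`init_missing`
replaces with small random vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import FeatureSpace


@dataclass(frozen=True)
class BipartiteInteractions:
    """Binary entity-gene interaction map (drug-gene or disease-gene).

    ``pairs`` has set semantics: an interaction is present or absent, and
    duplicates cannot exist, so the aggregation mean is over distinct
    interactors.
    """

    row_ids: list[str]
    col_ids: list[str]
    pairs: frozenset = field(repr=False)

    def __post_init__(self):
        rows, cols = set(self.row_ids), set(self.col_ids)
        if len(rows) != len(self.row_ids) or len(cols) != len(self.col_ids):
            raise ValueError("duplicate IDs in row or column list")
        for r, c in self.pairs:
            if r not in rows:
                raise ValueError(f"pair references undeclared row ID {r!r}")
            if c not in cols:
                raise ValueError(f"pair references undeclared column ID {c!r}")

    @classmethod
    def from_pairs(cls, pairs, row_ids=None, col_ids=None) -> "BipartiteInteractions":
        """Build from (entity, gene) tuples; ID order defaults to first appearance."""
        pairs = [(str(r), str(c)) for r, c in pairs]
        if row_ids is None:
            row_ids = list(dict.fromkeys(r for r, _ in pairs))
        if col_ids is None:
            col_ids = list(dict.fromkeys(c for _, c in pairs))
        return cls(row_ids=list(row_ids), col_ids=list(col_ids), pairs=frozenset(pairs))

    def interactors(self, row_id: str) -> list[str]:
        col_pos = {c: i for i, c in enumerate(self.col_ids)}
        return sorted((c for r, c in self.pairs if r == row_id), key=col_pos.get)

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)


def aggregate_features(
    interactions: BipartiteInteractions, gene_space: FeatureSpace
) -> FeatureSpace:
    """Mean of interactor gene vectors, per entity.

    Entities with no interactors get an all-NaN row (to be filled by
    :func:`init_missing`). Every gene that actually occurs in a pair must be
    present in ``gene_space``.
    """
    gene_pos = {g: i for i, g in enumerate(gene_space.ids)}
    n, k = interactions.n_rows, gene_space.k
    sums = np.zeros((n, k))
    counts = np.zeros(n)
    row_pos = {r: i for i, r in enumerate(interactions.row_ids)}
    for r, c in interactions.pairs:
        if c not in gene_pos:
            raise KeyError(f"gene {c!r} has no feature vector in the gene space")
        sums[row_pos[r]] += gene_space.X[gene_pos[c]]
        counts[row_pos[r]] += 1
    X = np.full((n, k), np.nan)
    has = counts > 0
    X[has] = sums[has] / counts[has, None]
    return FeatureSpace(ids=list(interactions.row_ids), X=X)


def init_missing(space: FeatureSpace, scale: float = 0.1, seed: int = 0) -> FeatureSpace:
    """Replace NaN rows by i.i.d. Uniform(-scale, +scale) draws.

    Defined rows are untouched; output is deterministic given ``seed``. If no
    row is missing the input object is returned as-is.
    """
    missing = np.isnan(space.X).any(axis=1)
    if not missing.any():
        return space
    rng = np.random.default_rng(seed)
    X = space.X.copy()
    X[missing] = rng.uniform(-scale, scale, size=(int(missing.sum()), space.k))
    return FeatureSpace(ids=list(space.ids), X=X, eigenvalues=space.eigenvalues)
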