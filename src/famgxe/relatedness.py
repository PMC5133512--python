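"""Pedigree relatedness and ancestry adjustment.

Provides the numerator (additive) relationship matrix ``A`` used as the
covariance structure of the polygenic random effect, greedy LD pruning,
and founder-based principal components with projection to relatives.

``A`` holds expected additive relationships: twice the kinship coefficient
off the diagonal, ``1 + F_i`` on it (``F_i`` the inbreeding coefficient).
Because families are disjoint, ``A`` is block diagonal; the blocks are
cached and exploited throughout the mixed-model code.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, FamGxEError
from .pedigree import Pedigree


class RelationshipMatrix:
    """Symmetric PSD matrix of expected additive relationships."""

    def __init__(self, values: np.ndarray, ids: list[str]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise FamGxEError("relationship matrix must be square")
        if values.shape[0] != len(ids):
            raise FamGxEError("relationship matrix / id length mismatch")
        self.values = values
        self.ids = list(ids)
        self._blocks: list[np.ndarray] | None = None
        self._groups: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._chol: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def blocks(self) -> list[np.ndarray]:
        """Index arrays of the connected components (families)."""
        if self._blocks is None:
            pattern = csr_matrix(self.values != 0.0)
            n_comp, labels = connected_components(pattern, directed=False)
            self._blocks = [np.flatnonzero(labels == c) for c in range(n_comp)]
        return self._blocks

    @property
    def block_groups(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Blocks batched by size: list of (index matrix (b, s), R stack
        (b, s, s)); lets per-block linear algebra run vectorized."""
        if self._groups is None:
            by_size: dict[int, list[np.ndarray]] = {}
            for b in self.blocks:
                by_size.setdefault(b.size, []).append(b)
            groups = []
            for size in sorted(by_size):
                idx = np.vstack(by_size[size])
                Rst = self.values[idx[:, :, None], idx[:, None, :]]
                groups.append((idx, Rst))
            self._groups = groups
        return self._groups

    def grouped_cholesky(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Batched lower Cholesky factors of the diagonal blocks (cached)."""
        if self._chol is None:
            self._chol = [
                (idx, np.linalg.cholesky(Rst)) for idx, Rst in self.block_groups
            ]
        return self._chol

    def subset(self, idx: np.ndarray) -> "RelationshipMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], [self.ids[i] for i in idx]
        )

    def to_sparse_tsv(self, path) -> None:
        """Write nonzero entries as a 3-column TSV (id1, id2, value)."""
        rows = []
        vals = self.values
        for i in range(self.n):
            for j in range(i, self.n):
                if vals[i, j] != 0.0:
                    rows.append((self.ids[i], self.ids[j], vals[i, j]))
        pd.DataFrame(rows, columns=["id1", "id2", "value"]).to_csv(
            path, sep="\t", index=False
        )


def numerator_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the recursive tabular method.

    In topological order: founders get ``A_ii = 1`` and zero relationship to
    earlier founders of other couples; a non-founder with parents ``f, m``
    gets ``A_ij = (A_fj + A_mj)/2`` for earlier ``j`` and
    ``A_ii = 1 + A_fm/2``.
    """
    n = len(pedigree)
    order = pedigree.topological_order
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    A = np.zeros((n, n))
    fidx, midx = pedigree.father_idx, pedigree.mother_idx
    for k, orig in enumerate(order):
        if fidx[orig] < 0:
            A[k, k] = 1.0
        else:
            f, m = pos[fidx[orig]], pos[midx[orig]]
            row = 0.5 * (A[f, :k] + A[m, :k])
            A[k, :k] = row
            A[:k, k] = row
            A[k, k] = 1.0 + 0.5 * A[f, m]
    # undo the topological permutation
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    A = A[np.ix_(inv, inv)]
    return RelationshipMatrix(A, pedigree.ids)


def ld_prune(
    panel,
    r2_threshold: float = 0.2,
    subset: list[str] | None = None,
) -> list[str]:
    """Greedy LD pruning in position order within chromosome.

    A SNP is retained unless its squared Pearson correlation of dosages
    (computed over ``subset`` individuals, default all) with any previously
    retained SNP on the same chromosome exceeds ``r2_threshold``.
    Monomorphic SNPs are dropped first.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ConfigurationError("r2_threshold must be in (0, 1]")
    rows = (
        np.arange(len(panel.ids))
        if subset is None
        else np.asarray([panel.ids.index(i) for i in subset])
    )
    if rows.size == 0:
        raise ConfigurationError("subset must be non-empty")
    meta = panel.snp_meta
    kept: list[str] = []
    for chrom in meta["chrom"].unique():
        snps = meta[meta["chrom"] == chrom].sort_values("pos").index
        kept_cols: list[np.ndarray] = []
        for snp in snps:
            g = panel.dosages[rows, meta.index.get_loc(snp)]
            sd = g.std()
            if sd == 0.0:
                continue
            gc = (g - g.mean()) / sd
            if kept_cols:
                r = np.array([np.mean(gc * other) for other in kept_cols])
                if np.any(r**2 > r2_threshold):
                    continue
            kept_cols.append(gc)
            kept.append(snp)
    return kept


@dataclass
class PCModel:
    """Founder-trained principal-component model.

    ``scores`` holds the founder scores; scores for relatives come from
    :func:`project_pcs`, which applies the same centering/scaling and
    loadings to any dosage rows.
    """

    snp_subset: list[str]
    founder_means: np.ndarray
    founder_scales: np.ndarray
    loadings: np.ndarray          # m x k, orthonormal columns
    scores: pd.DataFrame          # founders x k
    k: int


def founder_pca(
    panel,
    founders: list[str],
    snp_subset: list[str],
    k: int = 5,
    scale: bool = True,
) -> PCModel:
    """Principal components of founder dosages.

    Dosages are centered by founder per-SNP means (and scaled to unit
    founder variance when ``scale``); the loadings are the top-``k`` right
    singular vectors.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    rows = np.asarray([panel.ids.index(i) for i in founders])
    cols = np.asarray([panel.snp_meta.index.get_loc(s) for s in snp_subset])
    G = panel.dosages[np.ix_(rows, cols)].astype(float)
    means = G.mean(axis=0)
    sds = G.std(axis=0)
    if np.any(sds == 0.0):
        raise ConfigurationError("snp_subset contains SNPs monomorphic among founders")
    scales = sds if scale else np.ones_like(sds)
    Z = (G - means) / scales
    if k > min(Z.shape):
        raise ConfigurationError(f"k={k} exceeds rank bound {min(Z.shape)}")
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:k].T
    scores = pd.DataFrame(
        Z @ loadings, index=list(founders), columns=[f"pc{j+1}" for j in range(k)]
    )
    return PCModel(list(snp_subset), means, scales, loadings, scores, k)


def project_pcs(model: PCModel, panel) -> pd.DataFrame:
    """Score every panel individual with the founder-trained model.

    Founders reproduce their ``founder_pca`` scores exactly; relatives get
    the same linear map applied to their dosages.
    """
    missing = [s for s in model.snp_subset if s not in panel.snp_meta.index]
    if missing:
        raise FamGxEError(f"panel lacks model SNPs: {missing}")
    cols = np.asarray([panel.snp_meta.index.get_loc(s) for s in model.snp_subset])
    Z = (panel.dosages[:, cols] - model.founder_means) / model.founder_scales
    return pd.DataFrame(
        Z @ model.loadings,
        index=list(panel.ids),
        columns=[f"pc{j+1}" for j in range(model.k)],
    )
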