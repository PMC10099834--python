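"""Sample-level structure: PCA, correlation clustering, and NJ expression trees.

PCA follows the common RNA-seq convention of projecting samples on the top
most-variable genes after per-gene centering.  Sample clustering uses
Spearman correlation distance (1 - rho) with the "ward.D" agglomeration
dialect (Lance-Williams update on unsquared dissimilarities).  Expression
trees are neighbor-joining trees on the same 1 - rho distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from skbio import DistanceMatrix
from skbio.tree import nj

from .types import CrossExprError, ExpressionMatrix


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # samples x components
    variance_explained: list[float]
    n_top_genes: int


@dataclass
class ExpressionTree:
    newick: str
    leaves: list[str]
    distances: pd.DataFrame
    negative_branches_clamped: bool


def pca_embed(
    m: ExpressionMatrix, n_top_genes: int = 500, n_components: int = 2
) -> EmbeddingResult:
    """Project samples onto principal components of the top-variable genes."""
    if m.n_samples < 3:
        raise CrossExprError("need >= 3 samples for PCA")
    if n_components > m.n_samples - 1:
        raise CrossExprError("n_components exceeds samples - 1")
    variances = m.values.var(axis=1)
    top = variances.sort_index().sort_values(ascending=False, kind="stable").index[
        : min(n_top_genes, m.n_genes)
    ]
    x = m.values.loc[top].to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    return EmbeddingResult(
        coordinates=pd.DataFrame(
            coords,
            index=m.sample_ids,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        variance_explained=[float(v) for v in pca.explained_variance_ratio_],
        n_top_genes=len(top),
    )


def spearman_distance(m: ExpressionMatrix) -> pd.DataFrame:
    """1 - Spearman rho between all sample pairs."""
    if m.n_samples < 3:
        raise CrossExprError("need >= 3 samples")
    sds = m.values.std(axis=0)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise CrossExprError(f"constant sample {bad}")
    rho, _ = stats.spearmanr(m.values.to_numpy(dtype=float))
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


def ward_d_linkage(d: pd.DataFrame) -> np.ndarray:
    """"ward.D" linkage (Lance-Williams on unsquared dissimilarities).

    Implemented by running the squared-distance Ward update on sqrt(d) and
    squaring the merge heights, which is algebraically identical to applying
    the Lance-Williams Ward coefficients directly to d.
    """
    condensed = squareform(d.to_numpy(), checks=False)
    z = linkage(np.sqrt(condensed), method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2
    return z


def corr_cluster(m: ExpressionMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """ward.D dendrogram on Spearman correlation distance, plus the distances."""
    d = spearman_distance(m)
    return ward_d_linkage(d), d


def nj_tree(d: pd.DataFrame) -> ExpressionTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative estimated branch lengths are clamped to zero with the deficit
    moved to the adjacent branch (the standard adjustment); the result is
    flagged when that happened.
    """
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or arr.shape[0] < 3:
        raise CrossExprError("need a square distance matrix over >= 3 taxa")
    if np.abs(arr - arr.T).max() > 1e-8:
        raise CrossExprError("distance matrix is asymmetric")
    if np.abs(np.diag(arr)).max() > 1e-12:
        raise CrossExprError("distance matrix diagonal must be zero")
    dm = DistanceMatrix((arr + arr.T) / 2, ids=list(d.index))
    tree = nj(dm)
    raw = nj(dm, neg_as_zero=False)
    clamped = any(
        n.length is not None and n.length < 0 for n in raw.traverse()
    )
    return ExpressionTree(
        newick=str(tree).strip(),
        leaves=[t.name for t in tree.tips()],
        distances=d,
        negative_branches_clamped=bool(clamped),
    )
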