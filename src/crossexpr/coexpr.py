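"""Weighted co-expression networks: soft threshold, adjacency/TOM, modules,
eigengenes, module membership (kME) and hub calls.

The network is unsigned: a_ij = |pearson(i, j)|^beta.  The topological
overlap measure (TOM) between genes i and j is

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with unit diagonal.  Modules come from average-linkage clustering of 1 - TOM
with a static cut, a minimum size, and iterative merging of modules whose
eigengenes are more similar than the merge height.  Module labels are
integers ordered by decreasing size, 0 meaning unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .types import CrossExprError, ExpressionMatrix


@dataclass
class SoftThresholdReport:
    powers: list[int]
    r_squared: list[float]  # signed scale-free fit R^2 per power
    mean_connectivity: list[float]
    chosen_power: int


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    module_labels: pd.Series | None = None  # gene -> int, 0 = unassigned
    eigengenes: pd.DataFrame | None = None  # samples x modules
    kme: pd.DataFrame | None = None  # genes x modules


def _corr_matrix(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    x = m.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(m.gene_ids, sd) if s == 0]
        raise CrossExprError(f"constant gene rows: {bad[:5]}")
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0), m.gene_ids


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) on log10(mean k) over connectivity bins.

    Sign is negative when frequency increases with connectivity (anti
    scale-free); the chosen-power rule uses the signed value, as the field's
    convention does.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    m: ExpressionMatrix,
    powers: list[int] | None = None,
    r2_target: float = 0.85,
) -> SoftThresholdReport:
    """Smallest power whose signed scale-free fit R^2 reaches the target.

    Falls back to the argmax power when no candidate reaches the target.
    Constant gene rows are dropped with a warning before correlation.
    """
    if powers is None:
        powers = list(range(1, 13))
    if m.n_samples < 8:
        warnings.warn("fewer than 8 samples: soft-threshold fit is unreliable")
    x = m.values
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant gene rows")
        m = m.subset_genes(list(x.index[sd > 0]))
    corr, _ = _corr_matrix(m)
    abs_c = np.abs(corr)
    np.fill_diagonal(abs_c, 0.0)
    r2s, ks = [], []
    for p in powers:
        a = abs_c**p
        k = a.sum(axis=1)
        r2s.append(_scale_free_fit(k))
        ks.append(float(k.mean()))
    chosen = None
    for p, r2 in zip(powers, r2s):
        if r2 >= r2_target:
            chosen = p
            break
    if chosen is None:
        chosen = powers[int(np.argmax(r2s))]
    return SoftThresholdReport(list(powers), r2s, ks, chosen)


def adjacency_tom(m: ExpressionMatrix, beta: float) -> CoexpressionNetwork:
    """Unsigned adjacency and TOM for the given soft-threshold power."""
    if beta < 1:
        raise CrossExprError("beta must be >= 1")
    corr, genes = _corr_matrix(m)
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    k = a_off.sum(axis=1)
    numer = a_off @ a_off + a_off
    denom = np.minimum.outer(k, k) + 1.0 - a_off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return CoexpressionNetwork(gene_ids=genes, beta=float(beta), adjacency=a, tom=tom)


def _eigengene(x: np.ndarray) -> np.ndarray:
    """First principal component over samples of gene-standardized expression,
    sign-oriented to correlate positively with the module mean profile."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    if z.shape[0] == 1:
        return z[0]
    # first right-singular vector = PC over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e


def eigengenes_kme(
    m: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes (samples x modules) and gene kME (genes x modules)."""
    modules = sorted(set(labels) - {0})
    if not modules:
        raise CrossExprError("no labeled modules")
    x = m.values.to_numpy(dtype=float)
    eig = {}
    for mod in modules:
        rows = np.flatnonzero(labels.loc[m.gene_ids].to_numpy() == mod)
        eig[mod] = _eigengene(x[rows])
    eigengenes = pd.DataFrame(eig, index=m.sample_ids)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    zx = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    emat = eigengenes.to_numpy()
    ez = (emat - emat.mean(axis=0)) / np.where(emat.std(axis=0) == 0, 1, emat.std(axis=0))
    kme = zx @ ez / x.shape[1]
    kme = pd.DataFrame(np.clip(kme, -1, 1), index=m.gene_ids, columns=modules)
    return eigengenes, kme


def detect_modules(
    net: CoexpressionNetwork,
    m: ExpressionMatrix,
    min_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float = 0.995,
) -> pd.Series:
    """Module labels from average-linkage clustering of 1 - TOM.

    Initial static cut at ``cut_height`` times the dendrogram's maximum merge
    height (relative, so it adapts to the TOM's dynamic range); clusters below
    ``min_size`` go to label 0; modules whose eigengene dissimilarity
    (1 - cor) is below ``merge_height`` are merged iteratively until stable.
    Labels are renumbered by decreasing module size.
    """
    if net.tom is None:
        raise CrossExprError("TOM not computed")
    d = 1.0 - net.tom
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # symmetrize round-off
    z = average(squareform(d, checks=False))
    raw = fcluster(z, t=cut_height * z[:, 2].max(), criterion="distance")
    labels = pd.Series(raw, index=net.gene_ids, dtype=int)
    # suppress small clusters
    counts = labels.value_counts()
    small = counts.index[counts < min_size]
    labels[labels.isin(small)] = 0

    def renumber(lab: pd.Series) -> pd.Series:
        sizes = lab[lab != 0].value_counts()
        mapping = {old: i + 1 for i, old in enumerate(sizes.index)}
        mapping[0] = 0
        return lab.map(mapping)

    labels = renumber(labels)
    # iterative eigengene merging
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig, _ = eigengenes_kme(m.subset_genes(list(labels.index)), labels)
        cor = np.corrcoef(eig.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        keep, drop = mods[min(i, j)], mods[max(i, j)]
        labels[labels == drop] = keep
        labels = renumber(labels)
    return labels


def hub_genes(
    net: CoexpressionNetwork,
    m: ExpressionMatrix,
    trait: pd.Series,
    kme_min: float = 0.8,
    gs_min: float = 0.2,
) -> dict[int, list[str]]:
    """Hubs per module: kME > ``kme_min`` and |gene significance| > ``gs_min``.

    Gene significance is the Pearson correlation between a gene's expression
    and the sample trait.  Both thresholds are strict inequalities.
    """
    if net.module_labels is None or net.kme is None:
        raise CrossExprError("run detect_modules and eigengenes_kme first")
    trait = trait.loc[m.sample_ids].astype(float)
    if trait.std() == 0:
        raise CrossExprError("constant trait")
    x = m.values.to_numpy(dtype=float)
    t = (trait - trait.mean()) / trait.std()
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    zx = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    gs = zx @ t.to_numpy() / x.shape[1]
    gs = pd.Series(gs, index=m.gene_ids)
    out: dict[int, list[str]] = {}
    for gene in m.gene_ids:
        mod = int(net.module_labels.get(gene, 0))
        if mod == 0:
            continue
        if net.kme.loc[gene, mod] > kme_min and abs(gs[gene]) > gs_min:
            out.setdefault(mod, []).append(gene)
    return out
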