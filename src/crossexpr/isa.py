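"""Iterative signature algorithm (ISA) biclustering of expression matrices.

ISA alternates between scoring samples by the weighted mean expression of the
current gene set (on the column-standardized matrix) and scoring genes by the
weighted mean over the current sample set (on the row-standardized matrix),
keeping only scores beyond ``t_c`` / ``t_g`` standard deviations.  Each
random gene seed either converges to a transcription module (a bicluster) or
is discarded; converged modules are deduplicated by gene-membership
correlation, keeping the more robust one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CrossExprError, ExpressionMatrix


@dataclass
class Bicluster:
    gene_scores: pd.Series  # nonzero entries are members
    sample_scores: pd.Series
    t_g: float
    t_c: float
    robustness: float
    seed_index: int

    @property
    def genes(self) -> list[str]:
        return list(self.gene_scores.index[self.gene_scores != 0])

    @property
    def samples(self) -> list[str]:
        return list(self.sample_scores.index[self.sample_scores != 0])


def _standardize(x: np.ndarray, axis: int) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    if (sd == 0).any():
        raise CrossExprError("matrix has constant rows or columns; filter first")
    return (x - mu) / sd


def _iterate(
    gene_vec: np.ndarray,
    er: np.ndarray,
    ec: np.ndarray,
    t_g: float,
    t_c: float,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Run ISA updates from a gene score vector; None if not converged."""
    prev_members: frozenset[int] | None = None
    prev_scores: np.ndarray | None = None
    for _ in range(max_iter):
        denom = np.abs(gene_vec).sum()
        if denom == 0:
            return None
        s = ec.T @ gene_vec / denom  # sample scores
        s_sd = s.std()
        if s_sd == 0:
            return None
        s = np.where(np.abs(s) > t_c * s_sd, s, 0.0)
        if not s.any():
            return None
        g = er @ s / np.abs(s).sum()  # gene scores
        g_sd = g.std()
        if g_sd == 0:
            return None
        g = np.where(np.abs(g) > t_g * g_sd, g, 0.0)
        if not g.any():
            return None
        members = frozenset(np.flatnonzero(g))
        if prev_members is not None and members == prev_members:
            return g, s
        if prev_scores is not None:
            both = prev_scores.astype(bool) | g.astype(bool)
            if both.sum() > 1:
                c = np.corrcoef(prev_scores[both], g[both])[0, 1]
                if np.isfinite(c) and c > 0.99:
                    return g, s
        prev_members, prev_scores = members, g
        gene_vec = g
    return None


def run_isa(
    m: ExpressionMatrix,
    t_g: float = 2.0,
    t_c: float = 2.0,
    n_seeds: int = 100,
    seed: int = 0,
    seed_size: int = 10,
    dedup_cor: float = 0.9,
) -> list[Bicluster]:
    """Transcription modules from ``n_seeds`` random gene seeds.

    Non-converging seeds are discarded; modules whose binary gene-membership
    vectors correlate above ``dedup_cor`` are collapsed, keeping the module
    with the larger robustness (norm of the converged score product).
    """
    x = m.values.to_numpy(dtype=float)
    er = _standardize(x, axis=1)  # row-standardized (per gene)
    ec = _standardize(x, axis=0)  # column-standardized (per sample)
    n_genes = x.shape[0]
    rng = np.random.default_rng(seed)
    modules: list[Bicluster] = []
    for si in range(n_seeds):
        g0 = np.zeros(n_genes)
        idx = rng.choice(n_genes, size=min(seed_size, n_genes), replace=False)
        g0[idx] = 1.0
        res = _iterate(g0, er, ec, t_g, t_c)
        if res is None:
            continue
        g, s = res
        robustness = float(np.linalg.norm(g) * np.linalg.norm(s))
        modules.append(
            Bicluster(
                gene_scores=pd.Series(g, index=m.gene_ids),
                sample_scores=pd.Series(s, index=m.sample_ids),
                t_g=t_g,
                t_c=t_c,
                robustness=robustness,
                seed_index=si,
            )
        )
    if not modules:
        warnings.warn("no ISA seed converged to a module")
        return []
    # dedup by membership correlation, most robust first
    modules.sort(key=lambda b: -b.robustness)
    kept: list[Bicluster] = []
    for cand in modules:
        mc = (cand.gene_scores != 0).to_numpy(dtype=float)
        dup = False
        for k in kept:
            mk = (k.gene_scores != 0).to_numpy(dtype=float)
            if mc.std() == 0 or mk.std() == 0:
                continue
            if np.corrcoef(mc, mk)[0, 1] > dedup_cor:
                dup = True
                break
        if not dup:
            kept.append(cand)
    kept.sort(key=lambda b: b.seed_index)
    return kept


def module_tissue_specificity(
    modules: list[Bicluster],
    metadata: pd.DataFrame,
    tissue: str,
    min_frac: float = 1.0,
) -> list[Bicluster]:
    """Modules whose member samples are (at least ``min_frac``) one tissue."""
    out = []
    for b in modules:
        samples = b.samples
        if not samples:
            continue
        frac = float(np.mean([metadata.loc[s, "tissue"] == tissue for s in samples]))
        if frac >= min_frac:
            out.append(b)
    return out


def module_correlation(modules: list[Bicluster]) -> pd.DataFrame:
    """Spearman correlation matrix between modules' gene-score vectors."""
    if len(modules) < 2:
        raise CrossExprError("need >= 2 modules")
    mat = np.column_stack([b.gene_scores.to_numpy() for b in modules])
    rho, _ = stats.spearmanr(mat)
    if np.isscalar(rho) or np.ndim(rho) == 0:  # scipy collapses the 2-module case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    names = [f"module_{i}" for i in range(len(modules))]
    return pd.DataFrame(rho, index=names, columns=names)
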