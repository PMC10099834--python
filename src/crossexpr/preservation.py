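"""Module preservation between a reference network and a test dataset.

For each reference module the preservation of density and connectivity is
measured in the test data and standardized against a permutation null in
which module labels are reassigned at random over the shared genes (sizes
preserved).  The composite follows the density + connectivity semantics of
the standard preservation framework, reduced to three statistics:

* meanAdj - mean off-diagonal test adjacency within the module (density);
* cor.kIM - correlation of intramodular connectivity between reference and
  test (connectivity);
* cor.cor - correlation of the within-module correlation structures
  (connectivity).

Z per statistic is (observed - permutation mean) / permutation sd;
Z_density = Z(meanAdj); Z_connectivity = median(Z(cor.kIM), Z(cor.cor));
Z_summary = (Z_density + Z_connectivity) / 2.  The conventional reading of
Z_summary: > 10 strong preservation, 2..10 weak-to-moderate, < 2 none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpr import CoexpressionNetwork
from .types import CrossExprError, ExpressionMatrix

STAT_NAMES = ("meanAdj", "cor_kIM", "cor_cor")


@dataclass
class PreservationResult:
    module: int
    observed: dict[str, float]
    perm_mean: dict[str, float]
    perm_sd: dict[str, float]
    z: dict[str, float]  # NaN where permutation sd is 0
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int
    seed: int
    n_common_genes: int


def classify_preservation(z_summary: float) -> str:
    """Map a Z_summary value to {strong, weak_to_moderate, none}."""
    if not np.isfinite(z_summary):
        raise CrossExprError("z_summary must be finite")
    if z_summary > 10:
        return "strong"
    if z_summary >= 2:
        return "weak_to_moderate"
    return "none"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _module_stats(
    idx: np.ndarray, ref_adj: np.ndarray, test_adj: np.ndarray,
    ref_cor: np.ndarray, test_cor: np.ndarray,
) -> dict[str, float]:
    sub_t = test_adj[np.ix_(idx, idx)]
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    mean_adj = float(sub_t[off].mean())
    sub_r = ref_adj[np.ix_(idx, idx)]
    kim_r = sub_r.sum(axis=1) - np.diag(sub_r)
    kim_t = sub_t.sum(axis=1) - np.diag(sub_t)
    iu = np.triu_indices(n, k=1)
    return {
        "meanAdj": mean_adj,
        "cor_kIM": _pearson(kim_r, kim_t),
        "cor_cor": _pearson(ref_cor[np.ix_(idx, idx)][iu], test_cor[np.ix_(idx, idx)][iu]),
    }


def module_preservation(
    ref_net: CoexpressionNetwork,
    ref_matrix: ExpressionMatrix,
    test_matrix: ExpressionMatrix,
    n_perm: int = 100,
    seed: int = 0,
) -> list[PreservationResult]:
    """Permutation Z statistics for every reference module in the test data.

    Only genes common to reference and test are used; the test adjacency is
    built with the reference soft-threshold power.  Label-0 (unassigned)
    genes participate in the permutation pool.
    """
    if ref_net.module_labels is None:
        raise CrossExprError("reference network has no module labels")
    if test_matrix.n_samples < 4:
        raise CrossExprError("test set needs >= 4 samples")
    common = [g for g in ref_net.gene_ids if g in set(test_matrix.gene_ids)]
    if len(common) < 3:
        raise CrossExprError("fewer than 3 genes shared between reference and test")

    ref_sub = ref_matrix.subset_genes(common)
    test_sub = test_matrix.subset_genes(common)

    def adj_cor(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        x = m.values.to_numpy(dtype=float)
        sd = x.std(axis=1)
        sd[sd == 0] = np.nan
        c = np.corrcoef(x)
        c = np.nan_to_num(np.clip(c, -1, 1))
        a = np.abs(c) ** ref_net.beta
        np.fill_diagonal(a, 1.0)
        return a, c

    ref_adj, ref_cor = adj_cor(ref_sub)
    test_adj, test_cor = adj_cor(test_sub)

    labels = ref_net.module_labels.loc[common].to_numpy()
    modules = sorted(set(labels) - {0})
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(common)) for _ in range(n_perm)]

    results = []
    for mod in modules:
        idx = np.flatnonzero(labels == mod)
        if len(idx) < 3:
            continue
        obs = _module_stats(idx, ref_adj, test_adj, ref_cor, test_cor)
        null = {s: np.empty(n_perm) for s in STAT_NAMES}
        for p, perm in enumerate(perms):
            pidx = perm[idx]
            stats = _module_stats(pidx, ref_adj, test_adj, ref_cor, test_cor)
            for s in STAT_NAMES:
                null[s][p] = stats[s]
        z, mu, sd = {}, {}, {}
        for s in STAT_NAMES:
            vals = null[s][np.isfinite(null[s])]
            mu[s] = float(vals.mean()) if len(vals) else np.nan
            sd[s] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            if not np.isfinite(obs[s]) or not np.isfinite(sd[s]) or sd[s] == 0:
                if sd[s] == 0:
                    warnings.warn(f"module {mod}: permutation sd of {s} is 0; z undefined")
                z[s] = np.nan
            else:
                z[s] = (obs[s] - mu[s]) / sd[s]
        z_density = z["meanAdj"]
        z_conn = float(np.nanmedian([z["cor_kIM"], z["cor_cor"]]))
        z_summary = (z_density + z_conn) / 2.0
        results.append(
            PreservationResult(
                module=int(mod),
                observed=obs,
                perm_mean=mu,
                perm_sd=sd,
                z=z,
                z_density=float(z_density),
                z_connectivity=z_conn,
                z_summary=float(z_summary),
                n_permutations=n_perm,
                seed=seed,
                n_common_genes=len(common),
            )
        )
    return results


def preservation_table(results: list[PreservationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s in STAT_NAMES:
            rows.append(
                {
                    "module": r.module,
                    "stat": s,
                    "observed": r.observed[s],
                    "perm_mean": r.perm_mean[s],
                    "perm_sd": r.perm_sd[s],
                    "z": r.z[s],
                    "z_summary": r.z_summary,
                    "class": classify_preservation(r.z_summary)
                    if np.isfinite(r.z_summary)
                    else "undefined",
                }
            )
    return pd.DataFrame(rows)
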