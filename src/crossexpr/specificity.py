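"""Tissue-specificity index tau and specific-gene classification.

tau for a gene with per-tissue mean expression X_1..X_n is

    tau = sum_i (1 - X_i / max(X)) / (n - 1)

so tau = 0 for perfectly ubiquitous expression and tau = 1 for expression in
a single tissue.  A gene is called specific to tissue T when tau > 0.8
(strict) and its three highest-expression samples all come from T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import CrossExprError, ExpressionMatrix


def tau_index(x: Iterable[float]) -> float:
    """tau over a per-tissue mean expression vector; NaN when undefined."""
    x = np.asarray(list(x), dtype=float)
    if len(x) < 2:
        return float("nan")
    mx = x.max()
    if mx <= 0:
        return float("nan")
    xhat = x / mx
    return float((1.0 - xhat).sum() / (len(x) - 1))


def assign_specific_genes(
    m: ExpressionMatrix, tau_min: float = 0.8
) -> pd.DataFrame:
    """Per-gene tau and assigned tissue (or None) with per-tissue means.

    tau is computed on per-tissue mean expression; the assignment requires in
    addition that the gene's top three samples by expression all belong to
    the assigned tissue (ties broken by sample id for determinism).
    """
    if m.n_samples < 3:
        raise CrossExprError("need >= 3 samples for the top-3 rule")
    tissues = sorted(m.samples["tissue"].unique())
    if len(tissues) < 2:
        raise CrossExprError("need >= 2 tissue classes")
    x = m.values
    tissue_means = pd.DataFrame(
        {t: x[m.sample_ids_where(tissue=t)].mean(axis=1) for t in tissues}
    )
    taus = tissue_means.apply(lambda row: tau_index(row.to_numpy()), axis=1)

    sample_tissue = m.samples["tissue"]
    # pre-sort columns by sample id so a stable argsort breaks expression
    # ties deterministically
    cols = np.array(sorted(m.sample_ids))
    arr = x[cols].to_numpy(dtype=float)
    order = np.argsort(arr, axis=1, kind="stable")
    assigned = []
    for i, gene in enumerate(m.gene_ids):
        if not (np.isfinite(taus.iloc[i]) and taus.iloc[i] > tau_min):
            assigned.append(None)
            continue
        top3 = cols[order[i, -3:]]
        owners = {sample_tissue[s] for s in top3}
        assigned.append(owners.pop() if len(owners) == 1 else None)
    out = pd.DataFrame(
        {"tau": taus.to_numpy(), "assigned_tissue": assigned},
        index=pd.Index(m.gene_ids, name="gene"),
    )
    return pd.concat([out, tissue_means], axis=1).rename_axis("gene").reset_index()


def orthogroup_overlap(
    assign_a: Iterable[str],
    assign_b: Iterable[str],
    families: Mapping[str, str],
) -> dict[str, object]:
    """Venn counts of specifically expressed orthogroups for two tissues.

    A family is specifically expressed in a tissue when any of its genes is;
    a family with an A-specific gene and a B-specific paralog counts in both
    sets and in the intersection.
    """
    def lift(genes: Iterable[str]) -> set[str]:
        out = set()
        for g in genes:
            if g not in families:
                raise CrossExprError(f"gene {g} has no orthogroup assignment")
            out.add(families[g])
        return out

    fa, fb = lift(assign_a), lift(assign_b)
    return {
        "families_a": len(fa),
        "families_b": len(fb),
        "shared": len(fa & fb),
        "families_a_set": fa,
        "families_b_set": fb,
    }
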