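"""Differentially upregulated genes (DUGs) and the similarity index (SI).

A tissue's DUGs are genes upregulated against reference tissues (ovary and
brain of the same species): fold change (pseudocount 1 on TPM means) strictly
above a threshold and a significant Welch t-test on log2(TPM + 1) - a
distribution-light substitute for a count-model ANOVA, recorded in output
metadata.  The similarity of two tissues' DUG sets over a common gene
universe is

    SI = 1 - sqrt((1 - G_T / G_B) * (1 - G_T / G_A))

with G_A, G_B the DUG counts of tissues A and B, and G_T the shared count.
Resampling draws a fixed number of libraries per tissue type without
replacement and recomputes the DUG calls and SI, giving a distribution of SI
values per tissue pair; group differences are tested with pairwise two-sided
Mann-Whitney U and Benjamini-Hochberg correction.  The corrected SI maps gene
sets to orthogroup (family) sets first, treating paralogs as equivalent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CrossExprError, ExpressionMatrix

DE_METHOD_NOTE = "welch_t_on_log2_tpm_plus_1"  # substitute for a count-model ANOVA


@dataclass
class DEResult:
    """Per-gene differential-expression table plus the call parameters."""

    table: pd.DataFrame  # gene, log2_fold_change, p, fdr, direction
    target_tissue: str
    reference_tissues: tuple[str, ...]
    fc_min: float
    alpha: float
    use_fdr: bool
    method: str = DE_METHOD_NOTE

    @property
    def up_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["direction"] == "up", "gene"])


@dataclass
class DUGSets:
    dugs_a: set[str]
    dugs_b: set[str]

    @property
    def shared(self) -> set[str]:
        return self.dugs_a & self.dugs_b


@dataclass
class SimilarityReport:
    pair: tuple[str, str]
    si_values: list[float]
    corrected_si_values: list[float] | None = None

    @property
    def median_si(self) -> float:
        return float(np.median(self.si_values))


def _linear_tpm(m: ExpressionMatrix) -> np.ndarray:
    """Values on the TPM scale regardless of the stored transform."""
    x = m.values.to_numpy(dtype=float)
    if m.scale == "tpm":
        return x
    if m.scale in ("log2tpm", "log2tpm_qn", "log2tpm_qn_batchfree"):
        return np.maximum(2.0**x - 1.0, 0.0)
    raise CrossExprError(f"cannot compute fold changes on scale {m.scale!r}")


def _log_tpm(m: ExpressionMatrix) -> np.ndarray:
    x = m.values.to_numpy(dtype=float)
    if m.scale == "tpm":
        return np.log2(x + 1.0)
    return x


def call_dugs(
    m: ExpressionMatrix,
    target_tissue: str,
    reference_tissues: Sequence[str] = ("ovary", "brain"),
    fc_min: float = 2.0,
    alpha: float = 0.05,
    use_fdr: bool = False,
    target_samples: Sequence[str] | None = None,
    reference_samples: Sequence[str] | None = None,
) -> DEResult:
    """Call genes upregulated in ``target_tissue`` vs pooled references.

    ``target_samples`` / ``reference_samples`` override the tissue-based
    sample selection (used by the resampling scheme).  Fold change uses a
    strict > comparison; significance uses raw p or BH FDR per ``use_fdr``.
    """
    if target_samples is None:
        target_samples = m.sample_ids_where(tissue=target_tissue)
    if reference_samples is None:
        reference_samples = []
        for rt in reference_tissues:
            found = m.sample_ids_where(tissue=rt)
            if not found:
                raise CrossExprError(f"missing reference tissue {rt}")
            reference_samples.extend(found)
    if len(target_samples) < 2 or len(reference_samples) < 2:
        raise CrossExprError("need >= 2 replicates per group")

    tgt = m.subset_samples(list(target_samples))
    ref = m.subset_samples(list(reference_samples))
    tpm_t, tpm_r = _linear_tpm(tgt), _linear_tpm(ref)
    log_t, log_r = _log_tpm(tgt), _log_tpm(ref)

    fc = (tpm_t.mean(axis=1) + 1.0) / (tpm_r.mean(axis=1) + 1.0)
    with np.errstate(invalid="ignore"):
        tstat, p = stats.ttest_ind(log_t, log_r, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    crit = fdr if use_fdr else p
    direction = np.where(
        (fc > fc_min) & (crit <= alpha),
        "up",
        np.where((fc < 1.0 / fc_min) & (crit <= alpha), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2_fold_change": np.log2(fc),
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    )
    return DEResult(
        table=table,
        target_tissue=target_tissue,
        reference_tissues=tuple(reference_tissues),
        fc_min=fc_min,
        alpha=alpha,
        use_fdr=use_fdr,
    )


def similarity_index(duo: DUGSets) -> float:
    """SI = 1 - sqrt((1 - G_T/G_B)(1 - G_T/G_A)); NaN when a set is empty."""
    ga, gb = len(duo.dugs_a), len(duo.dugs_b)
    if ga == 0 or gb == 0:
        return float("nan")
    gt = len(duo.shared)
    return 1.0 - float(np.sqrt((1.0 - gt / gb) * (1.0 - gt / ga)))


def corrected_si(
    dugs_a: set[str], dugs_b: set[str], families: Mapping[str, str]
) -> float:
    """SI after lifting both DUG sets to their orthogroup images."""
    for g in itertools.chain(dugs_a, dugs_b):
        if g not in families:
            raise CrossExprError(f"gene {g} has no orthogroup assignment")
    fa = {families[g] for g in dugs_a}
    fb = {families[g] for g in dugs_b}
    return similarity_index(DUGSets(fa, fb))


def si_resample(
    m_a: ExpressionMatrix,
    tissue_a: str,
    m_b: ExpressionMatrix,
    tissue_b: str,
    reference_tissues: Sequence[str] = ("ovary", "brain"),
    n_reps: int = 100,
    libs_per_tissue: int = 3,
    seed: int = 0,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    use_fdr: bool = False,
    map_a: Callable[[str], str] | None = None,
    map_b: Callable[[str], str] | None = None,
    families_a: Mapping[str, str] | None = None,
    families_b: Mapping[str, str] | None = None,
    pair_name: tuple[str, str] | None = None,
) -> SimilarityReport:
    """Resampled SI between two tissues (possibly from different matrices).

    Per replicate: draw ``libs_per_tissue`` libraries without replacement for
    each tissue type involved (targets and references per side), call DUGs,
    map gene ids through ``map_a`` / ``map_b`` into a common universe
    (identity by default), and compute the SI.  If family maps are given the
    orthogroup-corrected SI is computed alongside.
    """
    rng = np.random.default_rng(seed)
    map_a = map_a or (lambda g: g)
    map_b = map_b or (lambda g: g)

    def groups(m: ExpressionMatrix, tissue: str) -> dict[str, list[str]]:
        out = {tissue: m.sample_ids_where(tissue=tissue)}
        for rt in reference_tissues:
            out[rt] = m.sample_ids_where(tissue=rt)
        for t, libs in out.items():
            if len(libs) < libs_per_tissue:
                raise CrossExprError(
                    f"tissue {t} has {len(libs)} libraries; need {libs_per_tissue}"
                )
        return out

    groups_a, groups_b = groups(m_a, tissue_a), groups(m_b, tissue_b)

    def draw(groups_: dict[str, list[str]]) -> dict[str, list[str]]:
        out = {}
        for t, libs in groups_.items():
            idx = rng.choice(len(libs), size=libs_per_tissue, replace=False)
            out[t] = [libs[i] for i in sorted(idx)]
        return out

    si_values, corr_values = [], []
    both_fams = families_a is not None and families_b is not None
    for _ in range(n_reps):
        pick_a, pick_b = draw(groups_a), draw(groups_b)
        de_a = call_dugs(
            m_a, tissue_a, reference_tissues, fc_min, alpha, use_fdr,
            target_samples=pick_a[tissue_a],
            reference_samples=[s for rt in reference_tissues for s in pick_a[rt]],
        )
        de_b = call_dugs(
            m_b, tissue_b, reference_tissues, fc_min, alpha, use_fdr,
            target_samples=pick_b[tissue_b],
            reference_samples=[s for rt in reference_tissues for s in pick_b[rt]],
        )
        ups_a = {map_a(g) for g in de_a.up_genes}
        ups_b = {map_b(g) for g in de_b.up_genes}
        si_values.append(similarity_index(DUGSets(ups_a, ups_b)))
        if both_fams:
            fa = {families_a[g] for g in de_a.up_genes if g in families_a}
            fb = {families_b[g] for g in de_b.up_genes if g in families_b}
            corr_values.append(similarity_index(DUGSets(fa, fb)))
    return SimilarityReport(
        pair=pair_name or (tissue_a, tissue_b),
        si_values=si_values,
        corrected_si_values=corr_values if both_fams else None,
    )


def compare_si_groups(
    reports: Mapping[str, Sequence[float]], fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U across SI groups with BH correction."""
    names = list(reports)
    if len(names) < 2:
        raise CrossExprError("need >= 2 groups")
    for n in names:
        if len(reports[n]) < 3:
            raise CrossExprError(f"group {n} has fewer than 3 SI values")
    rows = []
    for a, b in itertools.combinations(names, 2):
        xa = np.asarray(reports[a], dtype=float)
        xb = np.asarray(reports[b], dtype=float)
        method = "exact" if (len(xa) <= 8 and len(xb) <= 8 and
                             len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb)) else "auto"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append({"group_a": a, "group_b": b, "U": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out
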