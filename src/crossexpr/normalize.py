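"""Expression normalization: TPM, log2(N+1) + quantile normalization, batch
correction, and low-expression filtering.

The quantile-normalization tie rule follows the limma dialect: tied values in
a column receive the mean of the reference quantiles they span.  Batch
correction is a plain two-way location/scale adjustment protecting the tissue
covariate; with additive per-(gene, batch) effects - the generating model used
throughout this package - that adjustment removes the batch signal exactly,
without empirical-Bayes shrinkage.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .types import CrossExprError, ExpressionMatrix


def compute_tpm(counts: ExpressionMatrix, lengths: Mapping[str, float] | pd.Series) -> ExpressionMatrix:
    """Transcripts per million from counts and gene lengths (bp).

    Per sample: ``rate_g = count_g / length_g``; ``TPM_g = rate_g / sum(rate) * 1e6``.
    Every column then sums to 1e6 (up to floating-point round-off).
    """
    if counts.scale != "counts":
        raise CrossExprError(f"expected counts, got scale {counts.scale!r}")
    lengths = pd.Series(lengths)
    missing = set(counts.gene_ids) - set(lengths.index)
    if missing:
        raise CrossExprError(f"missing gene lengths for {sorted(missing)[:5]}")
    lens = lengths.loc[counts.gene_ids].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise CrossExprError(f"non-positive length for gene {bad}")
    rate = counts.values.div(lens, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise CrossExprError(f"sample {zero[0]} has zero total counts")
    tpm = rate.div(totals, axis=1) * 1e6
    return counts.with_values(tpm, "tpm")


def _quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns; ties get the mean of spanned quantiles."""
    arr = values.to_numpy(dtype=float)
    n, k = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.zeros(n)
    for j in range(k):
        ref += arr[order[:, j], j]
    ref /= k
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        ranked = ref  # ref[i] is the mean i-th order statistic
        # average reference quantiles across tied runs
        srt = col[order[:, j]]
        result = np.empty(n)
        i = 0
        while i < n:
            jj = i
            while jj + 1 < n and srt[jj + 1] == srt[i]:
                jj += 1
            result[i : jj + 1] = ranked[i : jj + 1].mean()
            i = jj + 1
        out[order[:, j], j] = result
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_quantile(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) followed by quantile normalization across samples."""
    if m.scale != "tpm":
        raise CrossExprError(f"expected tpm, got scale {m.scale!r}")
    logged = np.log2(m.values + 1.0)
    if m.n_samples < 2:
        warnings.warn("fewer than 2 samples: skipping quantile normalization")
        return m.with_values(logged, "log2tpm")
    return m.with_values(_quantile_normalize(logged), "log2tpm_qn")


def batch_correct(m: ExpressionMatrix, covariate: str = "tissue") -> ExpressionMatrix:
    """Remove additive batch effects per gene while protecting ``covariate``.

    Per gene: subtract covariate-class means, estimate each batch's residual
    location and scale, centre and rescale residuals so batch means are 0 and
    batch variances equal the pooled variance, then restore covariate means.
    A single batch is the identity transform; batches perfectly confounded
    with the covariate are left uncorrected with a warning.
    """
    if m.scale not in ("log2tpm", "log2tpm_qn"):
        raise CrossExprError(f"batch correction expects log-scale data, got {m.scale!r}")
    batches = m.samples["batch"]
    out_scale = "log2tpm_qn_batchfree"
    if batches.nunique() <= 1:
        return m.with_values(m.values.copy(), out_scale)
    sizes = batches.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise CrossExprError(f"batch {small} has fewer than 2 samples")
    # confounding check: every covariate class must span >1 batch or vice versa
    cross = pd.crosstab(m.samples[covariate], batches)
    if ((cross > 0).sum(axis=1) == 1).all():
        warnings.warn("batches perfectly confounded with covariate; skipping correction")
        return m.with_values(m.values.copy(), out_scale)

    x = m.values.to_numpy(dtype=float)
    classes = m.samples[covariate].to_numpy()
    batch_arr = batches.to_numpy()
    fitted = np.zeros_like(x)
    for c in np.unique(classes):
        cols = classes == c
        fitted[:, cols] = x[:, cols].mean(axis=1, keepdims=True)
    resid = x - fitted
    pooled_var = resid.var(axis=1, ddof=1)
    adjusted = np.empty_like(resid)
    for b in np.unique(batch_arr):
        cols = batch_arr == b
        loc = resid[:, cols].mean(axis=1, keepdims=True)
        sd = resid[:, cols].std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (resid[:, cols] - loc) / sd
        adjusted[:, cols] = z * np.sqrt(pooled_var)[:, None]
    values = pd.DataFrame(fitted + adjusted, index=m.values.index, columns=m.values.columns)
    return m.with_values(values, out_scale)


def filter_low_expression(m: ExpressionMatrix, threshold: float = 0.05) -> ExpressionMatrix:
    """Keep genes whose mean TPM across samples is >= ``threshold``."""
    if m.scale != "tpm":
        raise CrossExprError(f"expected tpm, got scale {m.scale!r}")
    keep = m.values.mean(axis=1) >= threshold
    if not keep.any():
        raise CrossExprError("low-expression filter removed every gene")
    return m.subset_genes(list(m.values.index[keep]))
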