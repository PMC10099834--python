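"""Shared containers for expression data and sample annotation.

The central object is :class:`ExpressionMatrix`: a genes x samples table of
non-negative expression values together with per-sample metadata (species,
tissue class, batch) and a declared value scale.  Every transformation in the
package consumes and returns this container so that the scale a matrix is on
is always explicit rather than implied by where it came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Value scales an ExpressionMatrix can carry, in pipeline order.
SCALES = (
    "counts",
    "tpm",
    "log2tpm",
    "log2tpm_qn",
    "log2tpm_qn_batchfree",
)

#: Tissue classes of the sampling design: three secretory gland classes, a
#: catch-all gland class, and three non-glandular reference/body tissues.
TISSUES = (
    "venom_gland",
    "silk_gland",
    "salivary_gland",
    "other_gland",
    "ovary",
    "brain",
    "fat_body",
)

#: Glandular subset of :data:`TISSUES` (tissues with a secretory function).
GLAND_TISSUES = ("venom_gland", "silk_gland", "salivary_gland", "other_gland")

SAMPLE_COLUMNS = ("species", "tissue", "batch")


class CrossExprError(ValueError):
    """Base error for invalid inputs anywhere in the package."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata and a scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``species``, ``tissue``
        and ``batch``.  Row order must match the columns of ``values``.
    scale
        One of :data:`SCALES`.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise CrossExprError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise CrossExprError(f"duplicate gene ids: {dupes[:5]}")
        if not self.samples.index.is_unique:
            raise CrossExprError("duplicate sample ids in metadata")
        if list(self.values.columns) != list(self.samples.index):
            raise CrossExprError("values columns and samples index disagree")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise CrossExprError(f"sample metadata missing columns {missing}")
        if self.scale in ("counts", "tpm"):
            arr = self.values.to_numpy()
            if arr.size and np.nanmin(arr) < 0:
                raise CrossExprError(f"negative values not allowed on scale {self.scale!r}")

    # -- basic introspection ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- subsetting ---------------------------------------------------------

    def sample_ids_where(
        self,
        tissue: str | Iterable[str] | None = None,
        species: str | Iterable[str] | None = None,
        batch: str | Iterable[str] | None = None,
    ) -> list[str]:
        """Sample ids matching the given metadata values (AND-combined)."""
        mask = pd.Series(True, index=self.samples.index)
        for col, want in (("tissue", tissue), ("species", species), ("batch", batch)):
            if want is None:
                continue
            if isinstance(want, str):
                want = [want]
            mask &= self.samples[col].isin(list(want))
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise CrossExprError(f"unknown samples {sorted(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values[sample_ids],
            samples=self.samples.loc[sample_ids],
            scale=self.scale,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise CrossExprError(f"unknown genes {sorted(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[gene_ids],
            samples=self.samples,
            scale=self.scale,
        )

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        """A copy carrying new values (same samples) on a new scale."""
        return ExpressionMatrix(values=values, samples=self.samples, scale=scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(), self.scale)


def concat_matrices(matrices: Sequence[ExpressionMatrix], scale: str | None = None) -> ExpressionMatrix:
    """Column-concatenate matrices sharing a gene index (e.g. per-species slices)."""
    if not matrices:
        raise CrossExprError("no matrices to concatenate")
    scale = scale or matrices[0].scale
    base = list(matrices[0].values.index)
    for m in matrices[1:]:
        if list(m.values.index) != base:
            raise CrossExprError("matrices have different gene indexes")
        if m.scale != scale:
            raise CrossExprError("matrices on different scales")
    values = pd.concat([m.values for m in matrices], axis=1)
    samples = pd.concat([m.samples for m in matrices], axis=0)
    return ExpressionMatrix(values=values, samples=samples, scale=scale)
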