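"""Shared fixtures: small expression matrices and scaled-down studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crossexpr.synthdata import PlantedProgram, SynthConfig, generate_study
from crossexpr.types import ExpressionMatrix, TISSUES


def make_matrix(values, tissues=None, species=None, batches=None, scale="tpm", genes=None):
    """Build an ExpressionMatrix from a 2-D array and light metadata."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    sample_ids = [f"s{i}" for i in range(n_s)]
    samples = pd.DataFrame(
        {
            "species": species or ["spA"] * n_s,
            "tissue": tissues or ["venom_gland"] * n_s,
            "batch": batches or ["b1"] * n_s,
        },
        index=sample_ids,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        samples=samples,
        scale=scale,
    )


def small_config(seed=0, **overrides):
    """A fast three-species study with one planted program per gland."""
    defaults = dict(
        seed=seed,
        species={"sp01": 30, "sp02": 30, "sp03": 30},
        anchor_species="sp01",
        tissues={t: 4 for t in TISSUES},
        one2one_count=300,
        n_orthogroups=30,
        # program fractions mirror the default study (7.5% / 15% / 5%)
        programs=(
            PlantedProgram("secretion", 22, ("venom_gland", "silk_gland", "salivary_gland", "other_gland"), 1.5, 0.5),
            PlantedProgram("venom_silk_core", 45, ("venom_gland", "silk_gland"), 2.0, 0.8),
            PlantedProgram("venom_specific", 15, ("venom_gland",), 4.5, 0.8),
        ),
        go_terms=120,
        go_max_depth=7,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config(seed=11))


@pytest.fixture(scope="session")
def latent_block_matrix():
    """120 genes x 40 samples with two independent 30-gene latent-factor
    modules; returns (matrix, truth labels, factors)."""
    rng = np.random.default_rng(42)
    n_g, n_s = 120, 40
    x = rng.normal(0, 1, (n_g, n_s))
    f1, f2 = rng.normal(0, 1, n_s), rng.normal(0, 1, n_s)
    x[:30] += 2.0 * f1
    x[30:60] += 2.0 * f2
    truth = np.zeros(n_g, dtype=int)
    truth[:30], truth[30:60] = 1, 2
    m = make_matrix(x - x.min() + 0.1, scale="log2tpm_qn")
    return m, truth, (f1, f2)
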