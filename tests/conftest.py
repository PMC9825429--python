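import numpy as np
import pytest

from coexkit import (
    CoexpressionMatrix,
    ExpressionMatrix,
    ModuleSpec,
    PCSampleMatrix,
    generate_modular_counts,
)


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 4 samples of raw counts, hand-chosen values."""
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2", "s3", "s4"],
        np.array([[10.0, 20, 30, 40], [40, 30, 20, 10], [5, 5, 5, 5]]),
        "raw_counts",
    )


@pytest.fixture
def modular_pcs() -> tuple[PCSampleMatrix, dict[str, int]]:
    """PC pseudo-samples from a small modular compendium with known truth."""
    from coexkit import filter_genes, log_transform, pca_reorganize

    spec = ModuleSpec(n_modules=3, genes_per_module=10, n_background_genes=10,
                      n_samples=40, within_correlation=0.85, seed=11)
    expr, truth = generate_modular_counts(spec)
    m = log_transform(filter_genes(expr))
    return pca_reorganize(m), truth


def symmetric_coex(values: np.ndarray, gene_ids=None, scale="zscore") -> CoexpressionMatrix:
    """Build a CoexpressionMatrix from an upper-triangle-complete array."""
    values = np.asarray(values, dtype=float)
    g = values.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    out = np.where(np.isnan(values), values.T, values)
    return CoexpressionMatrix(list(gene_ids), out, scale=scale)


@pytest.fixture
def random_coex() -> CoexpressionMatrix:
    """A fully-defined random z-score matrix over 12 genes."""
    rng = np.random.default_rng(7)
    g = 12
    vals = np.full((g, g), np.nan)
    iu = np.triu_indices(g, k=1)
    vals[iu] = rng.standard_normal(iu[0].size)
    vals.T[iu] = vals[iu]
    return CoexpressionMatrix([f"g{i:02d}" for i in range(g)], vals, scale="zscore")
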