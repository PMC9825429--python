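"""Expression-matrix filtering and principal-component reorganization.

The preprocessing chain for RNAseq count matrices is: drop low-depth runs
(column sum < 2M reads), drop low-abundance genes (mean count < 30),
log2-transform with a pseudo-count of 0.125, then rearrange samples into
principal-component pseudo-samples by row-centered PCA, keeping the top
1000 components.  Batch correction is an external stage exposed only as a
pass-through hook.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .containers import ExpressionMatrix, PCSampleMatrix
from .errors import EmptyResultError, ValidationError

__all__ = [
    "filter_runs",
    "filter_genes",
    "log_transform",
    "pca_reorganize",
    "batch_hook",
]


def filter_runs(m: ExpressionMatrix, min_total: float = 2_000_000) -> ExpressionMatrix:
    """Remove sample columns whose total count is below ``min_total``.

    The comparison is strict: a column summing to exactly ``min_total`` is
    retained.  Column order of survivors is preserved.
    """
    if m.value_kind != "raw_counts":
        raise ValidationError("filter_runs requires raw counts")
    totals = m.values.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise EmptyResultError(
            f"all {m.n_samples} runs fall below the {min_total:g}-count threshold"
        )
    return ExpressionMatrix(
        m.gene_ids,
        [s for s, k in zip(m.sample_ids, keep) if k],
        m.values[:, keep],
        value_kind="raw_counts",
    )


def filter_genes(m: ExpressionMatrix, min_avg: float = 30) -> ExpressionMatrix:
    """Remove gene rows whose mean count is below ``min_avg`` (strict)."""
    if m.value_kind != "raw_counts":
        raise ValidationError("filter_genes requires raw counts")
    means = m.values.mean(axis=1)
    keep = means >= min_avg
    if not keep.any():
        raise EmptyResultError(
            f"all {m.n_genes} genes fall below the mean-count threshold {min_avg:g}"
        )
    return ExpressionMatrix(
        [g for g, k in zip(m.gene_ids, keep) if k],
        m.sample_ids,
        m.values[keep],
        value_kind="raw_counts",
    )


def log_transform(m: ExpressionMatrix, pseudo: float = 0.125) -> ExpressionMatrix:
    """log2(v + pseudo) per cell; flips ``value_kind`` to ``log2``.

    The default pseudo-count 0.125 = 2^-3 maps a zero count to exactly -3.
    """
    if m.value_kind != "raw_counts":
        raise ValidationError("log_transform requires raw counts")
    if m.values.size and m.values.min() < 0:
        raise ValidationError("negative values cannot be log-transformed")
    return ExpressionMatrix(
        m.gene_ids, m.sample_ids, np.log2(m.values + pseudo), value_kind="log2"
    )


def pca_reorganize(m: ExpressionMatrix, n_pc: int = 1000) -> PCSampleMatrix:
    """Rearrange samples into principal-component pseudo-samples.

    Each gene row is centered (its mean over samples subtracted) and the
    centered matrix is decomposed by SVD over the sample axis.  The returned
    gene scores ``U * S`` keep the singular-value weighting, so leading
    pseudo-samples carry more variance — correlations over them reflect the
    original variance structure.  At most ``min(n_pc, n_samples - 1,
    n_genes)`` components are retained.  Component signs are fixed so each
    component's largest-magnitude gene score is positive.
    """
    if m.value_kind != "log2":
        raise ValidationError("pca_reorganize expects log2 values")
    if m.n_samples < 2:
        raise ValidationError("PCA reorganization needs at least 2 samples")
    centered = m.values - m.values.mean(axis=1, keepdims=True)
    k = min(n_pc, m.n_samples - 1, m.n_genes)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    u, s = u[:, :k], s[:k]
    scores = u * s
    # deterministic sign: largest-|score| entry of each component positive
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    if m.values.size and not np.any(s > 1e-12):
        import warnings

        warnings.warn("expression matrix has zero row-centered variance; "
                      "all component scores are zero")
    return PCSampleMatrix(m.gene_ids, scores, s)


def batch_hook(
    m: ExpressionMatrix,
    batch_labels: list[str] | None = None,
    corrector: Callable[[ExpressionMatrix, list[str]], ExpressionMatrix] | None = None,
) -> ExpressionMatrix:
    """Extension point for batch correction (e.g. Combat run externally).

    By default the matrix passes through unchanged.  A ``corrector``
    callable receives the matrix and per-sample batch labels and must
    return a valid :class:`ExpressionMatrix` over the same samples.
    """
    if batch_labels is not None and len(batch_labels) != m.n_samples:
        raise ValidationError(
            f"{len(batch_labels)} batch labels for {m.n_samples} samples"
        )
    if corrector is None:
        return m
    if batch_labels is None:
        raise ValidationError("a corrector requires batch labels")
    out = corrector(m, batch_labels)
    if not isinstance(out, ExpressionMatrix):
        raise ValidationError("batch corrector must return an ExpressionMatrix")
    if out.sample_ids != m.sample_ids:
        raise ValidationError("batch corrector must preserve sample identity")
    return out
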