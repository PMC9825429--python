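"""Subagged Mutual-Rank coexpression.

Pipeline per subagging iteration: draw a random subset of the
principal-component pseudo-samples, compute the Pearson correlation matrix
over that subset, convert it to Mutual Rank (geometric mean of the two
directed rank positions, rank 1 = strongest partner, self excluded, ties
averaged), and logit-transform the MR values so that stronger coexpression
maps to larger values.  The iterations are averaged element-wise on the
logit scale, and the averaged matrix is finally standardized to z-scores
over all defined unordered pairs.

Mutual Rank removes the per-gene baseline differences in correlation
magnitude; the logit transform linearizes the heavily skewed MR
distribution before averaging; subagging stabilizes the estimate against
sampling noise in the expression compendium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import CoexpressionMatrix, PCSampleMatrix
from .errors import ValidationError

__all__ = [
    "SubaggingConfig",
    "pcc_matrix",
    "mutual_rank",
    "logit_of_mr",
    "subagging_coexpression",
    "standardize_z",
]


@dataclass
class SubaggingConfig:
    """Subagging parameters.

    Defaults follow the production settings: 1000 iterations, 50
    pseudo-samples drawn per iteration from a pool of up to 1000
    principal components.
    """

    n_iter: int = 1000
    n_subsample: int = 50
    pool_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if not 1 <= self.n_subsample <= self.pool_size:
            raise ValidationError("need 1 <= n_subsample <= pool_size")


def pcc_matrix(pcs: PCSampleMatrix, columns: np.ndarray | list[int] | None = None) -> np.ndarray:
    """Pearson correlation of gene score rows over the selected columns.

    A gene with zero variance over the selected columns gets correlation 0
    with every partner (its rank information is vacuous).  The diagonal is
    set to 1 but is never consumed downstream.
    """
    if columns is None:
        sub = pcs.values
    else:
        columns = np.asarray(columns, dtype=int)
        sub = pcs.values[:, columns]
    if sub.shape[1] < 2:
        raise ValidationError("need at least 2 columns for correlation")
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero_var = norms == 0
    safe = np.where(zero_var, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def mutual_rank(corr: np.ndarray) -> np.ndarray:
    """Mutual Rank: sqrt(rank_a(b) * rank_b(a)).

    For each gene, all other genes are ranked by descending correlation
    (rank 1 = highest; self excluded; ties receive average ranks).  The
    result is symmetric with all values in [1, G-1]; the diagonal is NaN.
    """
    corr = np.asarray(corr, dtype=float)
    g = corr.shape[0]
    if corr.shape != (g, g) or g < 2:
        raise ValidationError("mutual_rank needs a square matrix with >= 2 genes")
    if not np.allclose(corr, corr.T):
        raise ValidationError("correlation matrix must be symmetric")
    ranks = np.empty((g, g), dtype=float)
    others = np.arange(g)
    for i in range(g):
        mask = others != i
        # rankdata ranks ascending; negate so rank 1 = highest correlation
        r = rankdata(-corr[i, mask], method="average")
        ranks[i, mask] = r
        ranks[i, i] = np.nan
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, np.nan)
    return mr


def logit_of_mr(mr: np.ndarray, n_genes: int | None = None) -> np.ndarray:
    """Logit transform of Mutual Rank, oriented so larger = more coexpressed.

    MR is mapped into (0, 1) by the affine p = (MR - 0.5) / (G - 1), which
    is symmetric about the attainable rank midpoint, then transformed as
    ln((1 - p) / p).  MR = 1 (each other's top partner) gives the largest
    value; the transform is strictly decreasing in MR.
    """
    mr = np.asarray(mr, dtype=float)
    g = n_genes if n_genes is not None else mr.shape[0]
    if g <= 2:
        raise ValidationError("logit transform needs more than 2 genes")
    finite = mr[~np.isnan(mr)]
    if finite.size and (finite.min() < 1 - 1e-9 or finite.max() > g - 1 + 1e-9):
        raise ValidationError("MR values must lie in [1, G-1]")
    p = (mr - 0.5) / (g - 1)
    return np.log((1.0 - p) / p)


def subagging_coexpression(
    pcs: PCSampleMatrix, cfg: SubaggingConfig, platform_label: str = ""
) -> CoexpressionMatrix:
    """Average of the pcc → MR → logit pipeline over random column subsets.

    Each iteration draws ``cfg.n_subsample`` distinct pseudo-sample columns
    (without replacement) from one seeded generator consumed sequentially,
    so the output is deterministic given the seed.
    """
    n_cols = min(pcs.n_pc, cfg.pool_size)
    if cfg.n_subsample > n_cols:
        raise ValidationError(
            f"n_subsample={cfg.n_subsample} exceeds available columns ({n_cols})"
        )
    if n_cols < 2:
        raise ValidationError("need at least 2 pseudo-sample columns")
    rng = np.random.default_rng(cfg.seed)
    g = pcs.n_genes
    acc = np.zeros((g, g))
    for _ in range(cfg.n_iter):
        cols = rng.choice(n_cols, size=cfg.n_subsample, replace=False)
        logit = logit_of_mr(mutual_rank(pcc_matrix(pcs, cols)), g)
        np.fill_diagonal(logit, 0.0)
        acc += logit
    acc /= cfg.n_iter
    np.fill_diagonal(acc, np.nan)
    return CoexpressionMatrix(pcs.gene_ids, acc, scale="logit_mr",
                              platform_label=platform_label)


def standardize_z(m: CoexpressionMatrix) -> CoexpressionMatrix:
    """Standardize defined off-diagonal pairs to mean 0, sd 1 (ddof=1).

    Missing pairs stay missing.  The statistics are computed over unordered
    pairs (each pair counted once).
    """
    vals = m.defined_pair_values()
    if vals.size < 2:
        raise ValidationError("need at least 2 defined pairs to standardize")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("zero variance: cannot standardize to z-scores")
    z = (m.values - mean) / sd
    return CoexpressionMatrix(m.gene_ids, z, scale="zscore",
                              platform_label=m.platform_label)
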