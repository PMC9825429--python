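"""Shrinkage-penalized integration of coexpression z-scores.

When a gene pair is covered by only m of n data subsets (or by one of the
two platforms), its averaged z-score is pulled toward zero by the factor
(m/n)^k: a coverage penalty for low-reliability pairs.  k = 0.2 is the
production default for all species.

Two integration modes:

* subset integration — the per-species experiment partition (n = 7 in
  production) is combined per pair as (m/n)^k * mean(z_i) without
  re-standardization: the penalized mean is the released value.
* union-type coexpression — the RNAseq and microarray platforms of one
  species are averaged per pair; a pair covered only by the complete
  platform is shrunk with n = 2, m = 1, and the result is re-standardized
  to z-scores ("z-score of the average").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import CoexpressionMatrix
from .coex import standardize_z
from .errors import ValidationError

__all__ = [
    "ShrinkageParams",
    "shrinkage_integrate",
    "integrate_subsets",
    "select_genes_by_coverage",
    "union_coexpression",
]


@dataclass
class ShrinkageParams:
    """n = total number of subsets, k = shrinkage strength (0 disables)."""

    n: int
    k: float = 0.2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.k < 0:
            raise ValidationError("k must be >= 0")


def shrinkage_integrate(z_values: Sequence[float], params: ShrinkageParams) -> float:
    """Penalized mean (m/n)^k * (1/m) * sum(z_i) with m = len(z_values)."""
    m = len(z_values)
    if m == 0:
        raise ValidationError("cannot integrate an empty z-score list")
    if m > params.n:
        raise ValidationError(f"m={m} exceeds total subset count n={params.n}")
    return (m / params.n) ** params.k * float(np.mean(z_values))


def integrate_subsets(
    subsets: Sequence[CoexpressionMatrix],
    params: ShrinkageParams,
    genes: Sequence[str] | None = None,
    restandardize: bool = False,
) -> CoexpressionMatrix:
    """Combine per-subset z-score matrices into one penalized-mean matrix.

    For every unordered gene pair the z-scores from the subsets where both
    genes are present (and the pair defined) are collected and combined by
    :func:`shrinkage_integrate`; pairs covered by zero subsets stay missing.
    ``genes`` restricts the output universe (e.g. to the coverage-selected
    genes); by default the union of all subset gene ids is used.
    Re-standardization after integration is off by default and available
    behind ``restandardize``.
    """
    if not subsets:
        raise ValidationError("no subsets to integrate")
    if params.n != len(subsets):
        raise ValidationError(
            f"params.n={params.n} does not match {len(subsets)} subsets"
        )
    for s in subsets:
        if s.scale != "zscore":
            raise ValidationError("subset integration expects z-score matrices")
    if genes is None:
        universe: list[str] = sorted(set().union(*(set(s.gene_ids) for s in subsets)))
    else:
        universe = list(genes)
    g = len(universe)
    idx = {gene: i for i, gene in enumerate(universe)}
    sums = np.zeros((g, g))
    counts = np.zeros((g, g), dtype=int)
    for s in subsets:
        rows = [idx.get(gene, -1) for gene in s.gene_ids]
        present = [(i, r) for i, r in enumerate(rows) if r >= 0]
        if not present:
            continue
        sub_i = np.array([i for i, _ in present])
        uni_i = np.array([r for _, r in present])
        block = s.values[np.ix_(sub_i, sub_i)]
        defined = ~np.isnan(block)
        target = np.ix_(uni_i, uni_i)
        sums[target] += np.where(defined, block, 0.0)
        counts[target] += defined
    values = np.full((g, g), np.nan)
    covered = counts > 0
    factor = (counts[covered] / params.n) ** params.k
    values[covered] = factor * sums[covered] / counts[covered]
    out = CoexpressionMatrix(universe, values, scale="zscore")
    if restandardize:
        out = standardize_z(out)
    return out


def select_genes_by_coverage(
    subsets: Sequence[CoexpressionMatrix], min_subsets: int = 4
) -> set[str]:
    """Genes present in at least ``min_subsets`` of the subsets.

    The default 4-of-7 rule ("more than three of the seven") guarantees by
    pigeonhole that every retained gene pair co-occurs in at least one
    subset, so every pair of the integrated matrix has a value.
    """
    if not subsets:
        raise ValidationError("no subsets given")
    counts: dict[str, int] = {}
    for s in subsets:
        for gene in s.gene_ids:
            counts[gene] = counts.get(gene, 0) + 1
    return {gene for gene, c in counts.items() if c >= min_subsets}


def union_coexpression(
    a: CoexpressionMatrix, b: CoexpressionMatrix, k: float = 0.2
) -> CoexpressionMatrix:
    """Union-type coexpression of a complete platform ``a`` and a possibly
    partial platform ``b``.

    Pairs defined in both are averaged; pairs defined only in ``a`` are
    shrunk by 2^(-k) (the n = 2, m = 1 case of the shrinkage formula).  A
    pair defined in ``b`` but not in ``a`` violates the complete-platform
    contract and raises.  The combined matrix is re-standardized to
    z-scores over its defined pairs.
    """
    if a.scale != "zscore" or b.scale != "zscore":
        raise ValidationError("union requires z-score inputs")
    universe = a.gene_ids
    idx = {gene: i for i, gene in enumerate(universe)}
    g = len(universe)

    b_vals = np.full((g, g), np.nan)
    b_rows = [idx.get(gene, -1) for gene in b.gene_ids]
    inside = [(i, r) for i, r in enumerate(b_rows) if r >= 0]
    if len(inside) < len(b.gene_ids):
        # any defined pair touching a gene outside a's universe breaks the
        # complete-platform contract
        sub = np.array([i for i, r in enumerate(b_rows) if r < 0])
        if np.any(~np.isnan(b.values[sub])):
            raise ValidationError(
                "platform b defines pairs outside the complete platform a"
            )
    if inside:
        sub_i = np.array([i for i, _ in inside])
        uni_i = np.array([r for _, r in inside])
        b_vals[np.ix_(uni_i, uni_i)] = b.values[np.ix_(sub_i, sub_i)]

    a_def = ~np.isnan(a.values)
    b_def = ~np.isnan(b_vals)
    if np.any(b_def & ~a_def):
        raise ValidationError("platform b defines pairs missing from platform a")

    values = np.full((g, g), np.nan)
    both = a_def & b_def
    only_a = a_def & ~b_def
    values[both] = 0.5 * (a.values[both] + b_vals[both])
    values[only_a] = 2.0 ** (-k) * a.values[only_a]
    out = CoexpressionMatrix(universe, values, scale="zscore",
                             platform_label=a.platform_label)
    return standardize_z(out)
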