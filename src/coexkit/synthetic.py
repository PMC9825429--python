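"""Synthetic expression data, annotations and orthogroups with known truth.

The expression generator is a shared-factor Gaussian model on the log2
scale: every coexpression module has one latent factor per sample, and a
member gene's log2 expression is

    count_mean_log + noise_sd * (sqrt(rho) * factor + sqrt(1 - rho) * eps)

so that any two member genes have log-scale correlation exactly ``rho``
(the ``within_correlation`` parameter) in expectation.  Counts are the
rounded base-2 exponential of the log2 expression (log-normal counts,
matching the pipeline's log2 transform).  Background genes are pure noise.

Defaults are chosen as a small but realistic desk-scale compendium: 5
modules of 40 genes plus 100 background genes over 60 samples, rho = 0.85,
unit log2 noise, and a mean log2 count of 8 (~256 counts per gene), the
order of magnitude of a moderately expressed transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AnnotationCatalog, CoexpressionMatrix, ExpressionMatrix, OrthoGroups
from .errors import ValidationError

__all__ = [
    "ModuleSpec",
    "generate_modular_counts",
    "generate_annotations",
    "generate_orthogroups",
    "generate_null_coexpression",
]


@dataclass
class ModuleSpec:
    """Ground-truth layout of the synthetic expression matrix."""

    n_modules: int = 5
    genes_per_module: int = 40
    n_background_genes: int = 100
    n_samples: int = 60
    within_correlation: float = 0.85
    noise_sd: float = 1.0
    count_mean_log: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_modules", "genes_per_module", "n_background_genes",
                     "n_samples"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0 <= self.within_correlation < 1:
            raise ValidationError("within_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


def generate_modular_counts(
    spec: ModuleSpec,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Generate a count matrix with known module membership.

    Returns the expression matrix (raw counts) and the truth map
    gene id → module index (background genes are absent from the map).
    Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_correlation
    n_member = spec.n_modules * spec.genes_per_module
    n_genes = n_member + spec.n_background_genes
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{j:03d}" for j in range(spec.n_samples)]

    log2_expr = np.empty((n_genes, spec.n_samples))
    truth: dict[str, int] = {}
    row = 0
    for mod in range(spec.n_modules):
        factor = rng.standard_normal(spec.n_samples)
        for _ in range(spec.genes_per_module):
            eps = rng.standard_normal(spec.n_samples)
            latent = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
            log2_expr[row] = spec.count_mean_log + spec.noise_sd * latent
            truth[gene_ids[row]] = mod
            row += 1
    for _ in range(spec.n_background_genes):
        eps = rng.standard_normal(spec.n_samples)
        log2_expr[row] = spec.count_mean_log + spec.noise_sd * eps
        row += 1

    counts = np.maximum(np.round(2.0**log2_expr), 0.0)
    return ExpressionMatrix(gene_ids, sample_ids, counts, "raw_counts"), truth


def generate_annotations(
    truth: dict[str, int],
    coverage: float = 1.0,
    extra_terms: int = 0,
    seed: int = 0,
    max_term_genes: int = 50,
) -> AnnotationCatalog:
    """One annotation term per module, plus optional random noise terms.

    Each module term holds a random ``coverage`` fraction of the module's
    genes; extra terms draw random genes from the full truth universe.
    Term sizes are capped below ``max_term_genes`` so the terms survive
    informative-term selection by construction.
    """
    if not 0 < coverage <= 1:
        raise ValidationError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    modules: dict[int, list[str]] = {}
    for gene, mod in truth.items():
        modules.setdefault(mod, []).append(gene)
    term_to_genes: dict[str, set[str]] = {}
    for mod in sorted(modules):
        genes = sorted(modules[mod])
        size = min(max(1, round(coverage * len(genes))), max_term_genes - 1)
        chosen = rng.choice(genes, size=size, replace=False)
        term_to_genes[f"M{mod:03d}"] = set(chosen.tolist())
    all_genes = sorted(truth)
    for t in range(extra_terms):
        size = int(rng.integers(2, min(max_term_genes - 1, max(3, len(all_genes) // 4))))
        chosen = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
        term_to_genes[f"X{t:03d}"] = set(chosen.tolist())
    return AnnotationCatalog(term_to_genes=term_to_genes)


def generate_orthogroups(
    gene_ids: list[str],
    paralog_fraction: float = 0.0,
    seed: int = 0,
    species: str = "SpA",
) -> OrthoGroups:
    """Assign a fraction of genes into shared two-gene orthogroups.

    ``paralog_fraction`` of the genes (rounded down to an even count) are
    paired into multi-gene groups; the remainder become singletons.
    """
    if not 0 <= paralog_fraction < 1:
        raise ValidationError("paralog_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    n_paired = int(len(genes) * paralog_fraction) // 2 * 2
    perm = rng.permutation(len(genes))
    group_to_genes: dict[str, dict[str, list[str]]] = {}
    gid = 0
    for i in range(0, n_paired, 2):
        a, b = genes[perm[i]], genes[perm[i + 1]]
        group_to_genes[f"OG{gid:05d}"] = {species: sorted([a, b])}
        gid += 1
    for i in range(n_paired, len(genes)):
        group_to_genes[f"OG{gid:05d}"] = {species: [genes[perm[i]]]}
        gid += 1
    return OrthoGroups(species_labels=[species], group_to_genes=group_to_genes)


def generate_null_coexpression(n_genes: int, seed: int = 0) -> CoexpressionMatrix:
    """An i.i.d. standard-normal z-score matrix, independent of any labels.

    Unordered pairs receive independent draws, symmetrized, and the matrix
    is standardized so the z-score invariant holds exactly.
    """
    if n_genes < 3:
        raise ValidationError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    values = np.full((n_genes, n_genes), np.nan)
    iu = np.triu_indices(n_genes, k=1)
    draws = rng.standard_normal(iu[0].size)
    draws = (draws - draws.mean()) / draws.std(ddof=1)
    values[iu] = draws
    values.T[iu] = draws
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    return CoexpressionMatrix(gene_ids, values, scale="zscore")
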