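"""In-memory containers shared across the toolkit.

The containers are thin, validated wrappers around numpy arrays and plain
dicts.  Gene and sample identifiers are opaque strings; no identifier
mapping is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "PCSampleMatrix",
    "CoexpressionMatrix",
    "AnnotationCatalog",
    "OrthoGroups",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix.

    ``value_kind`` is ``"raw_counts"`` (non-negative counts or intensities)
    or ``"log2"`` (after pseudo-count log transform).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str = "raw_counts"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.value_kind not in ("raw_counts", "log2"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.value_kind == "raw_counts" and self.values.size and self.values.min() < 0:
            raise ValidationError("raw_counts values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PCSampleMatrix:
    """Gene scores over principal-component pseudo-samples.

    Columns are ordered by decreasing singular value; the scores keep the
    singular-value weighting (no whitening), so the leading components carry
    more variance, exactly as in the source expression data.
    """

    gene_ids: list[str]
    values: np.ndarray
    component_scales: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.component_scales = np.asarray(self.component_scales, dtype=float)
        _check_unique(self.gene_ids, "gene")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValidationError("row count does not match gene id count")
        if self.values.shape[1] != len(self.component_scales):
            raise ValidationError("column count does not match component scales")
        if np.any(np.diff(self.component_scales) > 1e-12):
            raise ValidationError("components must be ordered by decreasing scale")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pc(self) -> int:
        return self.values.shape[1]


@dataclass
class CoexpressionMatrix:
    """Symmetric gene × gene coexpression values.

    ``values`` is a dense symmetric float array; missing pairs and the
    (undefined) diagonal are NaN.  ``scale`` records the stage:
    ``"logit_mr"`` for logit-transformed Mutual Rank, ``"zscore"`` after
    per-platform standardization.
    """

    gene_ids: list[str]
    values: np.ndarray
    scale: str = "logit_mr"
    platform_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValidationError(f"expected {g}x{g} matrix, got {self.values.shape}")
        if self.scale not in ("logit_mr", "zscore"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        np.fill_diagonal(self.values, np.nan)
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            self.values[defined], self.values.T[defined], equal_nan=True
        ):
            raise ValidationError("coexpression matrix must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in coexpression matrix") from None

    def defined_pair_values(self) -> np.ndarray:
        """Values of all defined unordered off-diagonal pairs (each once)."""
        iu = np.triu_indices(self.n_genes, k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])


@dataclass
class AnnotationCatalog:
    """Term → gene-set annotation, optionally with a term-parent DAG."""

    term_to_genes: dict[str, set[str]]
    term_to_parents: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            for g in genes:
                if not g:
                    raise ValidationError(f"term {term!r} references an empty gene id")
        if self.term_to_parents is not None:
            _assert_acyclic(self.term_to_parents)

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return out


def _assert_acyclic(parents: dict[str, set[str]]) -> None:
    """Depth-first cycle check over the child → parent graph."""
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str) -> None:
        color[node] = GREY
        for p in sorted(parents.get(node, ())):
            c = color.get(p, WHITE)
            if c == GREY:
                raise ValidationError(f"cycle in term-parent graph involving {p!r}")
            if c == WHITE:
                visit(p)
        color[node] = BLACK

    for n in sorted(parents):
        if color.get(n, WHITE) == WHITE:
            visit(n)


@dataclass
class OrthoGroups:
    """Orthogroup assignments per species (OrthoFinder-style)."""

    species_labels: list[str]
    group_to_genes: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species_labels = list(self.species_labels)
        _check_unique(self.species_labels, "species")
        for sp in self.species_labels:
            seen: dict[str, str] = {}
            for group, per_species in self.group_to_genes.items():
                for g in per_species.get(sp, ()):
                    if g in seen:
                        raise ValidationError(
                            f"gene {g!r} assigned to groups {seen[g]!r} and "
                            f"{group!r} in species {sp!r}"
                        )
                    seen[g] = group

    @property
    def n_groups(self) -> int:
        return len(self.group_to_genes)

    def group_of(self, species: str, gene: str) -> str | None:
        for group, per_species in self.group_to_genes.items():
            if gene in per_species.get(species, ()):
                return group
        return None

    def gene_to_group(self, species: str) -> dict[str, str]:
        """Mapping gene → group id for one species."""
        out: dict[str, str] = {}
        for group, per_species in self.group_to_genes.items():
            for g in per_species.get(species, ()):
                out[g] = group
        return out
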