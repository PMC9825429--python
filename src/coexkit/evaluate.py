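"""Pathway-consistency scoring and cross-platform similarity.

The consistency score asks how well a coexpression matrix ranks gene pairs
that share a functional annotation above pairs that do not.  Annotation
terms are first propagated up the term DAG (children's genes mapped to all
ancestors), then restricted to informative terms (< 50 genes); gene pairs
over the annotated universe are labeled positive when they share at least
one informative term, and pairs of genes from the same orthogroup are
excluded entirely to suppress the trivial signal of large gene families.
The score is the partial area under the ROC curve for FPR in [0, 0.01],
scaled by 10 000 so that 0.5 marks a random prediction and 100 the maximum.

Cross-platform similarity is the Pearson correlation of two platforms'
z-scores over an aligned list of one-to-one-ortholog gene pairs, clustered
by average linkage for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_curve

from .containers import AnnotationCatalog, CoexpressionMatrix, OrthoGroups
from .errors import EmptyResultError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairLabeling",
    "ConsistencyScore",
    "propagate_annotations",
    "select_informative_terms",
    "label_pairs",
    "consistency_score",
    "platform_similarity",
    "one_to_one_pairs",
    "average_linkage_cluster",
    "confusion_metrics",
]


@dataclass
class PairLabeling:
    """Positive / excluded labeling of gene pairs over an annotated universe.

    ``positives`` are unordered pairs sharing >= 1 informative term;
    ``excluded`` pairs (same orthogroup) are removed from evaluation
    entirely — exclusion wins over positivity.  Every other pair of the
    universe is a negative.
    """

    universe: list[str]
    positives: set[tuple[str, str]]
    excluded: set[tuple[str, str]] = field(default_factory=set)

    def iter_pairs(self):
        """Yield (a, b, label) for every evaluable pair; label True = positive."""
        for a, b in combinations(sorted(self.universe), 2):
            pair = (a, b)
            if pair in self.excluded:
                continue
            yield a, b, pair in self.positives


@dataclass
class ConsistencyScore:
    """Scaled partial ROC AUC with its evaluation census."""

    value: float
    n_pos: int
    n_neg: int
    fpr_ceiling: float = 0.01
    scale_factor: float = 10000.0


def propagate_annotations(cat: AnnotationCatalog) -> AnnotationCatalog:
    """Map every term's genes onto all ancestor terms (transitive closure).

    Flat catalogs (no parent map) pass through unchanged.  Idempotent.
    """
    if cat.term_to_parents is None:
        return cat
    parents = cat.term_to_parents
    # ancestors via memoized DFS (acyclicity is enforced by the container)
    memo: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in memo:
            out: set[str] = set()
            for p in parents.get(term, ()):
                out.add(p)
                out |= ancestors(p)
            memo[term] = out
        return memo[term]

    propagated: dict[str, set[str]] = {t: set(g) for t, g in cat.term_to_genes.items()}
    for term, genes in cat.term_to_genes.items():
        for anc in ancestors(term):
            propagated.setdefault(anc, set()).update(genes)
    return AnnotationCatalog(term_to_genes=propagated, term_to_parents=parents)


def select_informative_terms(
    cat: AnnotationCatalog, max_genes: int = 50
) -> AnnotationCatalog:
    """Keep terms with strictly fewer than ``max_genes`` genes.

    Large terms are too generic to be discriminative; the strict < 50
    default retains a 49-gene term and drops a 50-gene one.  Empty terms
    are dropped.  The parent map is not carried over — after informative
    selection the catalog is treated as flat.
    """
    kept = {
        t: set(g)
        for t, g in cat.term_to_genes.items()
        if 0 < len(g) < max_genes
    }
    if not kept:
        logger.warning("no informative terms (< %d genes) remain", max_genes)
    return AnnotationCatalog(term_to_genes=kept)


def label_pairs(
    cat: AnnotationCatalog,
    ortho: OrthoGroups | None = None,
    species: str | None = None,
) -> PairLabeling:
    """Label pairs of annotated genes as positive / negative / excluded.

    The universe is the genes carrying >= 1 (informative) term.  Positives
    share a term; pairs whose two genes sit in the same orthogroup are
    excluded from evaluation.
    """
    if species is not None and ortho is None:
        raise ValidationError("species label given without orthogroup data")
    universe = sorted(cat.annotated_genes())
    positives: set[tuple[str, str]] = set()
    for term, genes in cat.term_to_genes.items():
        members = sorted(genes)
        for a, b in combinations(members, 2):
            positives.add((a, b))
    excluded: set[tuple[str, str]] = set()
    if ortho is not None:
        if species is None:
            if len(ortho.species_labels) != 1:
                raise ValidationError(
                    "species must be named when orthogroups cover several species"
                )
            species = ortho.species_labels[0]
        g2g = ortho.gene_to_group(species)
        in_uni: dict[str, list[str]] = {}
        for g in universe:
            grp = g2g.get(g)
            if grp is not None:
                in_uni.setdefault(grp, []).append(g)
        for members in in_uni.values():
            for a, b in combinations(sorted(members), 2):
                excluded.add((a, b))
    return PairLabeling(universe=universe, positives=positives, excluded=excluded)


def consistency_score(
    coex: CoexpressionMatrix,
    labels: PairLabeling,
    fpr_ceiling: float = 0.01,
    scale: float = 10000.0,
) -> ConsistencyScore:
    """Scaled partial ROC AUC of coexpression against shared annotation.

    Pairs are ranked by descending coexpression; the ROC over positives vs
    negatives (excluded pairs omitted, pairs with missing coexpression
    dropped with a logged count) is integrated by trapezoids over FPR in
    [0, ``fpr_ceiling``], with vertical interpolation at the ceiling, and
    scaled by ``scale``.  Tied coexpression values are traversed as one
    diagonal ROC segment, which the trapezoid integrates exactly.
    """
    if not 0 < fpr_ceiling <= 1:
        raise ValidationError("fpr_ceiling must be in (0, 1]")
    universe = sorted(labels.universe)
    n = len(universe)
    upos = {g: i for i, g in enumerate(universe)}
    cidx = {g: i for i, g in enumerate(coex.gene_ids)}

    vals = np.full((n, n), np.nan)
    present = [(i, cidx[g]) for i, g in enumerate(universe) if g in cidx]
    if present:
        ui = np.array([i for i, _ in present])
        ci = np.array([j for _, j in present])
        vals[np.ix_(ui, ui)] = coex.values[np.ix_(ci, ci)]

    pos = np.zeros((n, n), dtype=bool)
    for a, b in labels.positives:
        if a in upos and b in upos:
            pos[upos[a], upos[b]] = pos[upos[b], upos[a]] = True
    exc = np.zeros((n, n), dtype=bool)
    for a, b in labels.excluded:
        if a in upos and b in upos:
            exc[upos[a], upos[b]] = exc[upos[b], upos[a]] = True

    iu = np.triu_indices(n, k=1)
    keep = ~exc[iu]
    pair_vals = vals[iu][keep]
    pair_pos = pos[iu][keep]
    defined = ~np.isnan(pair_vals)
    n_missing = int((~defined).sum())
    if n_missing:
        logger.info("dropped %d labeled pairs with missing coexpression", n_missing)
    scores = pair_vals[defined]
    y_arr = pair_pos[defined]
    n_pos = int(y_arr.sum())
    n_neg = int((~y_arr).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"need both positives and negatives (got {n_pos} / {n_neg})"
        )
    fpr, tpr, _ = roc_curve(y_arr, scores, drop_intermediate=False)
    area = _partial_auc(fpr, tpr, fpr_ceiling)
    return ConsistencyScore(
        value=float(scale * area),
        n_pos=n_pos,
        n_neg=n_neg,
        fpr_ceiling=fpr_ceiling,
        scale_factor=scale,
    )


def _partial_auc(fpr: np.ndarray, tpr: np.ndarray, ceiling: float) -> float:
    """Trapezoidal area under (fpr, tpr) for fpr in [0, ceiling], with
    vertical interpolation exactly at the ceiling."""
    if ceiling >= fpr[-1]:
        return float(np.trapezoid(tpr, fpr))
    cut = np.searchsorted(fpr, ceiling, side="right")
    f = np.concatenate([fpr[:cut], [ceiling]])
    lo, hi = fpr[cut - 1], fpr[cut]
    t_at = tpr[cut - 1] + (tpr[cut] - tpr[cut - 1]) * (ceiling - lo) / (hi - lo)
    t = np.concatenate([tpr[:cut], [t_at]])
    return float(np.trapezoid(t, f))


def platform_similarity(
    vectors: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    display_rounding: bool = False,
) -> np.ndarray:
    """Pearson correlation matrix of per-platform aligned z-score vectors.

    Every platform must supply its values over the same aligned unordered
    pair list (typically one-to-one-ortholog pairs mapped per species).
    With ``display_rounding`` the correlations are multiplied by 10 and
    rounded to integers (the compact display convention).
    """
    if labels is not None and len(labels) != len(vectors):
        raise ValidationError("label count does not match platform count")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValidationError(f"aligned vectors have unequal lengths: {sorted(lengths)}")
    mat = np.vstack([np.asarray(v, dtype=float) for v in vectors])
    sim = np.corrcoef(mat)
    sim = np.atleast_2d(sim)
    np.fill_diagonal(sim, 1.0)
    if display_rounding:
        sim = np.round(sim * 10)
    return sim


def one_to_one_pairs(
    ortho: OrthoGroups, species_list: Sequence[str]
) -> tuple[dict[str, list[str]], int]:
    """Aligned gene lists of groups with exactly one gene in every species.

    Returns ``(per-species aligned gene lists, number of unordered gene
    pairs)`` where the pair count is n(n-1)/2 for n qualifying groups.
    The aligned lists share one order (sorted group id), so index i refers
    to the same orthogroup in every species.
    """
    if len(species_list) < 2:
        raise ValidationError("need at least 2 species for one-to-one orthologs")
    for sp in species_list:
        if sp not in ortho.species_labels:
            raise ValidationError(f"unknown species {sp!r}")
    aligned: dict[str, list[str]] = {sp: [] for sp in species_list}
    n = 0
    for group in sorted(ortho.group_to_genes):
        per_species = ortho.group_to_genes[group]
        if all(len(per_species.get(sp, ())) == 1 for sp in species_list):
            for sp in species_list:
                aligned[sp].append(per_species[sp][0])
            n += 1
    if n == 0:
        raise EmptyResultError("no one-to-one orthologous groups across the species")
    return aligned, n * (n - 1) // 2


def aligned_pair_vector(
    coex: CoexpressionMatrix, genes: Sequence[str]
) -> np.ndarray:
    """Coexpression values over all unordered pairs of ``genes`` in aligned
    order — the per-platform input to :func:`platform_similarity`."""
    idx = [coex.index_of(g) for g in genes]
    out = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            out.append(coex.values[idx[a], idx[b]])
    return np.asarray(out, dtype=float)


def average_linkage_cluster(sim: np.ndarray) -> np.ndarray:
    """UPGMA dendrogram of a similarity matrix.

    Similarity s is converted to distance 1 - s and clustered with
    unweighted average linkage.  Returns the scipy linkage matrix (merge
    list with heights).
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValidationError("similarity matrix must be square")
    if not np.allclose(sim, sim.T):
        raise ValidationError("similarity matrix must be symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float | None]:
    """Standard binary-classification metrics from confusion counts.

    Ratios with a zero denominator are reported as ``None`` (missing),
    never as 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValidationError("all confusion counts are zero")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }
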