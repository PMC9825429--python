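"""CoexMap: a genome-scale 2-D embedding of coexpression.

Genes are laid out by UMAP with ``n_neighbors = 10`` on a precomputed
dissimilarity derived from the coexpression z-scores: conceptually the
negated z-scores, shifted by the matrix maximum (d = z_max - z) so the
dissimilarities are nonnegative while the pair ordering is untouched.
Points extremely far from the map center are moderately displaced —
formalized here as radial clamping at a quantile radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import CoexpressionMatrix
from .errors import ValidationError

__all__ = ["Embedding2D", "coexmap_embed", "displace_outliers", "overlay_geneset"]


@dataclass
class Embedding2D:
    gene_ids: list[str]
    coordinates: np.ndarray  # (n_genes, 2)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.gene_ids), 2):
            raise ValidationError("need one (x, y) pair per gene")


def coexmap_embed(
    coex: CoexpressionMatrix, n_neighbors: int = 10, seed: int = 0
) -> Embedding2D:
    """Embed a complete coexpression matrix into 2-D.

    Requires every off-diagonal pair defined (the map is built on a full
    platform).  Deterministic given ``seed``.  ``n_neighbors`` is clamped
    to G - 1 on small inputs.
    """
    import umap  # deferred: heavy import

    iu = np.triu_indices(coex.n_genes, k=1)
    n_missing = int(np.isnan(coex.values[iu]).sum())
    if n_missing:
        raise ValidationError(
            f"coexmap needs a complete matrix; {n_missing} pairs are missing"
        )
    z_max = coex.values[iu].max() if iu[0].size else 0.0
    dist = z_max - coex.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    nn = min(n_neighbors, coex.n_genes - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=nn,
            n_components=2,
            metric="precomputed",
            random_state=seed,
            init="random",
        )
        coords = reducer.fit_transform(dist)
    return Embedding2D(
        gene_ids=list(coex.gene_ids),
        coordinates=np.asarray(coords, dtype=float),
        params={"n_neighbors": nn, "seed": seed},
    )


def displace_outliers(emb: Embedding2D, quantile: float = 0.99) -> Embedding2D:
    """Pull points beyond the radial ``quantile`` onto that radius.

    The map center and the quantile radius are properties of the original
    layout: they are computed on first application and recorded in the
    embedding's params, so re-applying the displacement at the same
    quantile is an exact no-op (angular positions are preserved and radii
    only shrink).
    """
    if len(emb.gene_ids) < 2:
        raise ValidationError("need at least 2 genes")
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    if (emb.params.get("displacement_quantile") == quantile
            and "map_center" in emb.params):
        center = np.asarray(emb.params["map_center"], dtype=float)
        r_q = float(emb.params["displacement_radius"])
        rel = emb.coordinates - center
        radii = np.hypot(rel[:, 0], rel[:, 1])
    else:
        center = emb.coordinates.mean(axis=0)
        rel = emb.coordinates - center
        radii = np.hypot(rel[:, 0], rel[:, 1])
        r_q = float(np.quantile(radii, quantile))
    out = rel.copy()
    over = radii > r_q
    if r_q > 0:
        out[over] = rel[over] * (r_q / radii[over])[:, None]
    else:
        out[over] = 0.0
    params = dict(emb.params)
    params["displacement_quantile"] = quantile
    params["map_center"] = [float(center[0]), float(center[1])]
    params["displacement_radius"] = r_q
    return Embedding2D(emb.gene_ids, out + center, params)


def overlay_geneset(
    emb: Embedding2D,
    highlight: dict[str, set[str]] | None = None,
    out_image: str | Path | None = None,
    out_coords: str | Path | None = None,
    colors: dict[str, str] | None = None,
):
    """Scatter the embedding with optional highlighted gene sets.

    ``highlight`` maps a role label (e.g. ``"guide"``, ``"coexpressed"``)
    to a gene set; highlighted genes are drawn above the grey background.
    Genes absent from the embedding are logged and skipped.  Writes a
    static image and/or a coordinate TSV when paths are given; returns the
    matplotlib figure.
    """
    import logging

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logger = logging.getLogger(__name__)
    highlight = highlight or {}
    colors = colors or {}
    default_colors = ["red", "green", "blue", "orange", "purple"]
    pos = {g: i for i, g in enumerate(emb.gene_ids)}

    fig, ax = plt.subplots(figsize=(6, 6))
    xy = emb.coordinates
    ax.scatter(xy[:, 0], xy[:, 1], s=4, c="lightgrey", zorder=1, label=None)
    for rank, (role, genes) in enumerate(highlight.items()):
        missing = [g for g in genes if g not in pos]
        if missing:
            logger.warning("%d highlight genes not in embedding (role %r)",
                           len(missing), role)
        idx = [pos[g] for g in genes if g in pos]
        if not idx:
            continue
        ax.scatter(
            xy[idx, 0], xy[idx, 1], s=14,
            c=colors.get(role, default_colors[rank % len(default_colors)]),
            zorder=2 + rank, label=role,
        )
    if highlight:
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    if out_image is not None:
        fig.savefig(out_image, dpi=150)
    if out_coords is not None:
        with open(out_coords, "w") as fh:
            fh.write("gene_id\tx\ty\n")
            for g, (x, y) in zip(emb.gene_ids, emb.coordinates):
                fh.write(f"{g}\t{x!r}\t{y!r}\n")
    return fig
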