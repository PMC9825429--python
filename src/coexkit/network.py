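"""User-facing network views of a coexpression matrix.

* ranked coexpressed-gene list for a guide gene (z < 3 flagged weak:
  z-scores on random profiles are near-normal, so 3 is a practical
  co-regulation threshold)
* genome network from the union of every gene's top-k (default 3)
  coexpression edges — a transitive-reduction-style drawing rule
* guide-gene subnetwork restricted to 20 genes directly or indirectly
  coexpressed with the guide
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CoexpressionMatrix
from .errors import ValidationError

__all__ = ["CoexEdgeNetwork", "RankedGene", "ranked_list", "topk_network",
           "guide_subnetwork"]

WEAK_Z_THRESHOLD = 3.0


@dataclass
class RankedGene:
    gene: str
    z: float
    weak: bool


@dataclass
class CoexEdgeNetwork:
    """An undirected coexpression network with z-score edge weights."""

    nodes: set[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on {a!r}")
            if a > b:
                raise ValidationError("edge keys must be ordered (a < b)")
            if np.isnan(self.edges[(a, b)]):
                raise ValidationError(f"edge ({a}, {b}) has undefined weight")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> dict[str, float]:
        out = {}
        for (a, b), w in self.edges.items():
            if a == gene:
                out[b] = w
            elif b == gene:
                out[a] = w
        return out


def ranked_list(
    coex: CoexpressionMatrix, guide: str, top_n: int | None = None
) -> list[RankedGene]:
    """Partners of ``guide`` in descending coexpression order.

    Ties are broken by gene id; partners with missing coexpression are
    omitted; rows with z < 3 are flagged ``weak`` (strict: z = 3.0 is not
    weak).  ``top_n`` larger than the partner count returns the full list.
    """
    gi = coex.index_of(guide)
    rows = []
    for j, gene in enumerate(coex.gene_ids):
        if j == gi:
            continue
        v = coex.values[gi, j]
        if np.isnan(v):
            continue
        rows.append(RankedGene(gene, float(v), bool(v < WEAK_Z_THRESHOLD)))
    rows.sort(key=lambda r: (-r.z, r.gene))
    if top_n is not None:
        rows = rows[:top_n]
    return rows


def topk_network(coex: CoexpressionMatrix, k: int = 3) -> CoexEdgeNetwork:
    """Union over all genes of each gene's k strongest defined edges.

    Ties at the k-th rank are broken by partner id.  Edges are
    deduplicated; the union is asymmetric, so a hub gene can end up with
    degree above k.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for i, g in enumerate(coex.gene_ids):
        partners = [
            (coex.gene_ids[j], float(coex.values[i, j]))
            for j in range(coex.n_genes)
            if j != i and not np.isnan(coex.values[i, j])
        ]
        if partners:
            nodes.add(g)
        partners.sort(key=lambda t: (-t[1], t[0]))
        for p, w in partners[:k]:
            nodes.add(p)
            key = (g, p) if g < p else (p, g)
            edges[key] = w
    return CoexEdgeNetwork(nodes=nodes, edges=edges)


def guide_subnetwork(
    net: CoexEdgeNetwork, guide: str, max_genes: int = 20
) -> CoexEdgeNetwork:
    """Induced subgraph of up to ``max_genes`` genes around ``guide``.

    Breadth-first expansion over the network: within each BFS layer,
    candidate nodes are admitted in descending order of their strongest
    edge weight to the already-admitted set (ties broken by gene id) until
    ``max_genes`` nodes are collected or the connected component is
    exhausted.
    """
    if guide not in net.nodes:
        raise ValidationError(f"guide gene {guide!r} not in network")
    if max_genes < 1:
        raise ValidationError("max_genes must be >= 1")
    admitted: list[str] = [guide]
    admitted_set = {guide}
    frontier = [guide]
    while frontier and len(admitted) < max_genes:
        layer: set[str] = set()
        for node in frontier:
            for nb in net.neighbors(node):
                if nb not in admitted_set:
                    layer.add(nb)
        if not layer:
            break
        scored = sorted(
            layer,
            key=lambda gene: (
                -max(
                    w
                    for p, w in net.neighbors(gene).items()
                    if p in admitted_set
                ),
                gene,
            ),
        )
        next_frontier: list[str] = []
        for gene in scored:
            if len(admitted) >= max_genes:
                break
            admitted.append(gene)
            admitted_set.add(gene)
            next_frontier.append(gene)
        frontier = next_frontier
    sub_edges = {
        (a, b): w
        for (a, b), w in net.edges.items()
        if a in admitted_set and b in admitted_set
    }
    return CoexEdgeNetwork(nodes=admitted_set, edges=sub_edges)
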