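"""Readers and writers for every external representation the toolkit touches.

Formats
-------
* expression matrix — TSV, genes as rows, header row of sample ids
* gene sets — GMT (term, description, genes...)
* term parents — two-column TSV ``child<TAB>parent``
* orthogroups — OrthoFinder ``Orthogroups.tsv`` dialect
* coexpression — square TSV or long-form TSV (geneA, geneB, value with
  geneA < geneB lexicographically); missing values serialize as ``NA``

All writers are deterministic and round-trip bit-stably through the paired
reader for values representable at full ``repr`` precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnnotationCatalog, CoexpressionMatrix, ExpressionMatrix, OrthoGroups
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


def read_expression(path: str | Path, value_kind: str = "raw_counts") -> ExpressionMatrix:
    """Read a genes × samples TSV into an :class:`ExpressionMatrix`.

    The first row is the sample-id header, the first column holds gene ids.
    Non-numeric cells raise :class:`ParseError` naming the offending
    row/column; duplicate identifiers raise :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty expression file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed TSV structure
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene identifiers")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample identifiers")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{path}: non-numeric value at gene {bad!r}, sample {col!r}"
            ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values, value_kind=value_kind)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> AnnotationCatalog:
    """Read a GMT file (term, description, genes per tab-separated line).

    Duplicate term ids on separate lines are unioned with a logged warning;
    a term with zero genes is a parse error.
    """
    path = Path(path)
    term_to_genes: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} has zero genes")
            if term in term_to_genes:
                logger.warning("duplicate GMT term %r; gene sets unioned", term)
                term_to_genes[term] |= set(genes)
            else:
                term_to_genes[term] = set(genes)
    return AnnotationCatalog(term_to_genes=term_to_genes)


def write_gmt(cat: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(cat.term_to_genes):
            genes = sorted(cat.term_to_genes[term])
            fh.write("\t".join([term, "na"] + genes) + "\n")


def read_term_parents(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``child<TAB>parent`` TSV into an acyclic parent map."""
    path = Path(path)
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected 'child<TAB>parent'")
            child, parent = fields
            parents.setdefault(child, set()).add(parent)
    from .containers import _assert_acyclic

    _assert_acyclic(parents)
    return parents


def read_orthogroups(path: str | Path) -> OrthoGroups:
    """Read an OrthoFinder ``Orthogroups.tsv``-dialect file.

    Header: group-id column then one column per species.  Cells hold
    comma-separated gene lists; empty cells are allowed.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: missing header line")
        cols = header.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}: header needs a group column and >=1 species")
        species = cols[1:]
        group_to_genes: dict[str, dict[str, list[str]]] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            group = fields[0]
            if group in group_to_genes:
                raise ValidationError(f"{path}:{lineno}: duplicate group id {group!r}")
            per_species: dict[str, list[str]] = {}
            for sp, cell in zip(species, fields[1:]):
                genes = [g.strip() for g in cell.split(",") if g.strip()]
                if genes:
                    per_species[sp] = genes
            group_to_genes[group] = per_species
    return OrthoGroups(species_labels=species, group_to_genes=group_to_genes)


def write_orthogroups(og: OrthoGroups, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["Orthogroup"] + og.species_labels) + "\n")
        for group in sorted(og.group_to_genes):
            cells = [
                ", ".join(og.group_to_genes[group].get(sp, []))
                for sp in og.species_labels
            ]
            fh.write("\t".join([group] + cells) + "\n")


def _fmt(v: float) -> str:
    return NA_TOKEN if np.isnan(v) else repr(float(v))


def write_coexpression(
    matrix: CoexpressionMatrix, path: str | Path, layout: str = "square"
) -> None:
    """Serialize a coexpression matrix.

    ``layout`` is ``"square"`` (full symmetric TSV, diagonal NA) or
    ``"long"`` (geneA, geneB, value; one row per unordered pair with
    geneA < geneB lexicographically; missing pairs written as NA).
    """
    path = Path(path)
    if layout == "square":
        with open(path, "w") as fh:
            fh.write("\t".join(["gene_id"] + matrix.gene_ids) + "\n")
            for i, g in enumerate(matrix.gene_ids):
                fh.write(
                    "\t".join([g] + [_fmt(v) for v in matrix.values[i]]) + "\n"
                )
    elif layout == "long":
        order = sorted(range(matrix.n_genes), key=lambda i: matrix.gene_ids[i])
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tvalue\n")
            for ai in range(len(order)):
                for bi in range(ai + 1, len(order)):
                    i, j = order[ai], order[bi]
                    fh.write(
                        f"{matrix.gene_ids[i]}\t{matrix.gene_ids[j]}\t"
                        f"{_fmt(matrix.values[i, j])}\n"
                    )
    else:
        raise ValidationError(f"unknown layout {layout!r}")


def read_coexpression(
    path: str | Path, scale: str = "logit_mr", platform_label: str = ""
) -> CoexpressionMatrix:
    """Read a coexpression TSV; the layout (square vs long) is auto-detected
    from the header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:3] == ["gene_a", "gene_b", "value"]:
        return _read_coexpression_long(path, scale, platform_label)
    return _read_coexpression_square(path, scale, platform_label)


def _read_coexpression_square(path: Path, scale: str, platform_label: str) -> CoexpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     float_precision="round_trip")
    gene_ids = [str(g) for g in df.index]
    if gene_ids != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: row and column gene ids differ")
    return CoexpressionMatrix(gene_ids, df.to_numpy(dtype=float), scale=scale,
                              platform_label=platform_label)


def _read_coexpression_long(path: Path, scale: str, platform_label: str) -> CoexpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                     na_values=[NA_TOKEN], float_precision="round_trip")
    gene_ids = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    idx = {g: i for i, g in enumerate(gene_ids)}
    values = np.full((len(gene_ids), len(gene_ids)), np.nan)
    for a, b, v in df.itertuples(index=False):
        i, j = idx[a], idx[b]
        values[i, j] = values[j, i] = v
    return CoexpressionMatrix(gene_ids, values, scale=scale, platform_label=platform_label)
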