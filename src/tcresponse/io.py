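"""Readers and writers for the tabular and annotation formats the pipeline touches.

Formats: TSV (counts, design, lengths, grid, result tables), GFF3 (exon-union
gene lengths), GMT gene sets, OBO (the id/name/is_a subset) and two-column
gene-to-term annotation tables. All outputs are tab-separated UTF-8 with "."
as decimal separator.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import obonet
import pandas as pd

from tcresponse.containers import CountExperiment, StructuralError
from tcresponse.enrichment import OntologyGraph
from tcresponse.spatial import SpatialGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# counts + design
# ---------------------------------------------------------------------------

def read_counts(counts_path, design_path, lengths_path=None) -> CountExperiment:
    """Read a gene x sample count TSV plus a sample design TSV.

    The count file has a ``gene_id`` column (first) and one column per
    sample; the design file has columns ``sample_id``, ``time``,
    ``replicate``. Non-integer or negative counts, duplicate gene ids and
    sample mismatches between the two files are rejected.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in design.columns:
        raise StructuralError("design file needs a 'sample_id' column")
    design = design.set_index("sample_id")
    counts.columns = counts.columns.astype(str)
    lengths = read_gene_lengths(lengths_path) if lengths_path else None
    return CountExperiment(counts, design, lengths)


def read_gene_lengths(path) -> pd.Series:
    """Two-column TSV ``gene_id <tab> length`` (bp)."""
    tab = pd.read_csv(path, sep="\t")
    tab.columns = [c.lower() for c in tab.columns]
    return tab.set_index(tab.columns[0])[tab.columns[1]].astype(float)


def write_experiment(exp: CountExperiment, counts_path, design_path) -> None:
    out = exp.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    design = exp.design.copy()
    design.index.name = "sample_id"
    design.to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3 exon-union lengths
# ---------------------------------------------------------------------------

def gene_lengths_from_gff3(
    gff3_path,
    feature: str = "exon",
    gene_types: tuple[str, ...] = ("gene", "protein_coding_gene", "pseudogene"),
) -> pd.Series:
    """Exon-union gene lengths (bp) from a GFF3 annotation.

    For every gene, the ``feature`` intervals of all of its transcripts
    are merged (union of 1-based closed intervals, strand ignored) and
    the merged lengths summed — the "per kilobase of exon" denominator
    of RPKM. Exons are assigned to genes by following ``Parent``
    attributes transitively (exon -> mRNA -> gene); an exon whose
    parentage cannot be resolved to a feature of a type in
    ``gene_types`` is skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    def resolve_gene(feat, _seen=None):
        seen = _seen or set()
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id in seen:
                continue
            seen.add(parent_id)
            try:
                parent = db[parent_id]
            except gffutils.FeatureNotFoundError:
                continue
            if parent.featuretype in gene_types:
                return parent.id
            found = resolve_gene(parent, seen)
            if found is not None:
                return found
        return None

    intervals: dict[str, list[tuple[int, int]]] = {}
    n_unresolved = 0
    for exon in db.features_of_type(feature):
        gene = resolve_gene(exon)
        if gene is None:
            n_unresolved += 1
            continue
        intervals.setdefault(gene, []).append((exon.start, exon.end))
    if n_unresolved:
        logger.warning(
            "%d %s features without resolvable gene parent were skipped",
            n_unresolved, feature,
        )

    lengths = {}
    for gene, ivals in intervals.items():
        ivals.sort()
        total = 0
        cur_start, cur_end = ivals[0]
        for start, end in ivals[1:]:
            if start <= cur_end + 1:  # overlapping or adjacent
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        total += cur_end - cur_start + 1
        lengths[gene] = total
    out = pd.Series(lengths, dtype=float).sort_index()
    out.index.name = "gene_id"
    out.name = "length"
    return out


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(gmt_path) -> dict[str, set[str]]:
    """GMT file: ``name <tab> description <tab> gene1 <tab> gene2 ...``"""
    sets: dict[str, set[str]] = {}
    for line in Path(gmt_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise StructuralError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gene_sets(sets: dict[str, set[str]], gmt_path, description: str = "") -> None:
    with open(gmt_path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# ontology (OBO subset) + annotations
# ---------------------------------------------------------------------------

def read_obo(obo_path) -> OntologyGraph:
    """Read the id/name/is_a subset of an OBO file into an is_a DAG.

    Obsolete terms are dropped; a cyclic is_a structure is a structural
    error.
    """
    multigraph = obonet.read_obo(str(obo_path))
    edges = [
        (child, parent)
        for child, parent, key in multigraph.edges(keys=True)
        if key == "is_a"
    ]
    names = {t: data.get("name", t) for t, data in multigraph.nodes(data=True)}
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(multigraph.nodes)
    g.add_edges_from(edges)
    return OntologyGraph(g, names)


def write_obo(graph: OntologyGraph, obo_path, ontology_name: str = "synthetic") -> None:
    """Write the minimal [Term] stanza subset (id, name, is_a)."""
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {graph.name(term)}\n")
            for parent in sorted(graph.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {graph.name(parent)}\n")


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV ``gene_id <tab> term_id`` (GAF-like, no header required)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if {"gene_id", "term_id"} <= set(tab.iloc[0]):
        tab = tab.iloc[1:]
    annot: dict[str, set[str]] = {}
    for gene, term in zip(tab.iloc[:, 0], tab.iloc[:, 1]):
        annot.setdefault(gene, set()).add(term)
    return annot


def write_annotation(annotation: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(annotation):
            for term in sorted(annotation[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# spatial grid
# ---------------------------------------------------------------------------

def read_grid(tsv_path) -> SpatialGrid:
    """Grid TSV with columns row, col, analyte, value."""
    return SpatialGrid(pd.read_csv(tsv_path, sep="\t"))


def write_grid(grid: SpatialGrid, tsv_path) -> None:
    grid.data.to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each table as ``<out_dir>/<name>.tsv``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=not isinstance(table.index, pd.RangeIndex))
        paths.append(path)
    return paths
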