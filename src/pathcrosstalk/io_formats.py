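"""Readers, writers and validated containers for every external format.

The pipeline consumes gene-level TCGA-like matrices (expression, methylation
betas), a gene-level copy-number call table, a MAF-like mutation table, a
protein-protein interaction (PPI) edge list (two-column TSV or SIF) and a
pathway collection (GMT membership plus a pathway edge list). Everything is
gene-symbol keyed; identifier matching is exact-string.

All readers validate hard: files violating the container invariants raise
instead of silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MethylationMatrix",
    "CnaCallSet",
    "MutationTable",
    "PpiNetwork",
    "PathwayGraph",
    "OmicsBundle",
    "read_class_map",
    "read_expression_matrix",
    "read_methylation_matrix",
    "read_cna_calls",
    "read_mutation_table",
    "read_ppi",
    "largest_connected_component",
    "read_pathway_collection",
    "write_network",
    "read_network",
]

CLASS_LABELS = ("tumor", "normal")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene x sample log-scale expression with tumor/normal labels."""

    values: pd.DataFrame            # index = genes, columns = samples
    sample_class: pd.Series         # sample -> "tumor" | "normal"

    def __post_init__(self) -> None:
        _validate_matrix(self.values, self.sample_class, kind="expression")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def split_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(tumor array, normal array), genes x samples."""
        t = self.values.loc[:, self.sample_class == "tumor"].to_numpy(float)
        n = self.values.loc[:, self.sample_class == "normal"].to_numpy(float)
        return t, n


@dataclass
class MethylationMatrix:
    """Gene x sample methylation beta values in [0, 1]."""

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        _validate_matrix(self.values, self.sample_class, kind="methylation")
        arr = self.values.to_numpy(float)
        bad = np.argwhere((arr < 0) | (arr > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0, 1] at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )

    gene_ids = ExpressionMatrix.gene_ids
    sample_ids = ExpressionMatrix.sample_ids
    split_classes = ExpressionMatrix.split_classes


@dataclass
class CnaCallSet:
    """Gene-level copy-number calls: gene -> 'amplified' | 'deleted'."""

    calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, direction in self.calls.items():
            if direction not in ("amplified", "deleted"):
                raise ValueError(
                    f"CNA direction for {gene!r} must be amplified/deleted, got {direction!r}"
                )

    @property
    def amplified(self) -> set[str]:
        return {g for g, d in self.calls.items() if d == "amplified"}

    @property
    def deleted(self) -> set[str]:
        return {g for g, d in self.calls.items() if d == "deleted"}


#: mutation classes accepted by the reader (case-insensitive)
MUTATION_CLASSES = {
    "silent", "missense", "nonsense", "frameshift", "splice_site",
    "nonstop", "in_frame_indel", "translation_start_site",
}


@dataclass
class MutationTable:
    """(gene, sample, mutation_class) records; classes from a controlled vocabulary."""

    records: pd.DataFrame           # columns gene, sample, mutation_class

    def __post_init__(self) -> None:
        need = {"gene", "sample", "mutation_class"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"mutation table needs columns {sorted(need)}")
        bad = set(self.records["mutation_class"].str.lower()) - MUTATION_CLASSES
        if bad:
            raise ValueError(f"unknown mutation classes: {sorted(bad)}")


@dataclass
class PpiNetwork:
    """Simple undirected protein-interaction network."""

    graph: nx.Graph
    provenance: str = ""

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops present: {loops[:3]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class PathwayGraph:
    """One pathway as an undirected gene-gene graph."""

    pathway_id: str
    name: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise ValueError(f"pathway {self.pathway_id}: self-loop on {u!r}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass
class OmicsBundle:
    """The four per-gene data layers of one study plus sample labels."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    cna: CnaCallSet
    mutations: MutationTable


# ---------------------------------------------------------------------------
# validation helpers


def _validate_matrix(df: pd.DataFrame, sample_class: pd.Series, kind: str) -> None:
    dupg = df.index[df.index.duplicated()].unique()
    if len(dupg):
        raise ValueError(f"duplicate gene id in {kind} matrix: {dupg[0]!r}")
    dups = df.columns[df.columns.duplicated()].unique()
    if len(dups):
        raise ValueError(f"duplicate sample id in {kind} matrix: {dups[0]!r}")
    if df.isna().all(axis=1).any():
        gene = df.index[df.isna().all(axis=1)][0]
        raise ValueError(f"gene {gene!r} has no observed values")
    missing = set(df.columns) - set(sample_class.index)
    if missing:
        raise ValueError(f"samples without class label: {sorted(missing)[:5]}")
    bad = set(sample_class.loc[list(df.columns)]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"sample classes must be tumor/normal, got {sorted(bad)}")


# ---------------------------------------------------------------------------
# matrix readers


def read_class_map(path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>label`` with labels tumor/normal."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    return dict(zip(df["sample"], df["label"]))


def _read_gene_matrix(path, class_map: Mapping[str, str]) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene id: {dup[0]!r}")
    unlabeled = [s for s in df.columns if s not in class_map]
    if unlabeled:
        raise ValueError(f"samples missing from class map: {unlabeled[:5]}")
    sample_class = pd.Series({s: class_map[s] for s in df.columns})
    return df.astype(float), sample_class


def _impute_within_class(df: pd.DataFrame, sample_class: pd.Series) -> pd.DataFrame:
    """Mean-impute missing values per gene within tumor/normal class."""
    if not df.isna().any().any():
        return df
    out = df.copy()
    for label in CLASS_LABELS:
        cols = [s for s in df.columns if sample_class[s] == label]
        block = out.loc[:, cols]
        out.loc[:, cols] = block.T.fillna(block.mean(axis=1)).T
    # a gene missing an entire class falls back to its overall mean
    if out.isna().any().any():
        out = out.T.fillna(df.mean(axis=1)).T
    return out


def read_expression_matrix(path, class_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes-x-samples TSV of log-scale expression.

    Genes with more than 50% missing values are dropped (count logged);
    remaining missing entries are mean-imputed per gene within class.
    """
    df, sample_class = _read_gene_matrix(path, class_map)
    frac_missing = df.isna().mean(axis=1)
    drop = frac_missing > 0.5
    if drop.any():
        logger.warning("dropping %d genes with >50%% missing expression values", int(drop.sum()))
        df = df.loc[~drop]
    if df.empty:
        raise ValueError("no genes left after missingness filter")
    df = _impute_within_class(df, sample_class)
    return ExpressionMatrix(values=df, sample_class=sample_class)


def read_methylation_matrix(path, class_map: Mapping[str, str]) -> MethylationMatrix:
    """Read a genes-x-samples TSV of beta values; any value outside [0,1] is fatal."""
    df, sample_class = _read_gene_matrix(path, class_map)
    df = _impute_within_class(df, sample_class)
    return MethylationMatrix(values=df, sample_class=sample_class)


def read_cna_calls(path) -> CnaCallSet:
    """Two-column TSV ``gene<TAB>direction`` with direction amplified/deleted."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "direction"], dtype=str)
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"gene {dup.iloc[0]!r} has more than one CNA call")
    return CnaCallSet(calls=dict(zip(df["gene"], df["direction"].str.lower())))


def read_mutation_table(path) -> MutationTable:
    """TSV with header gene, sample, mutation_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return MutationTable(records=df)


# ---------------------------------------------------------------------------
# networks


def read_ppi(path, provenance: str = "") -> PpiNetwork:
    """Read a PPI edge list (two-column TSV, or SIF with an interaction column).

    Self-loops are removed (logged) and duplicate edges collapsed; isolated
    endpoint nodes of removed self-loops are retained.
    """
    path = Path(path)
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        logger.warning("PPI file %s is empty", path)
        return PpiNetwork(graph=g, provenance=provenance or str(path))
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) == 1:
            parts = ln.split()
        if len(parts) == 2:
            u, v = parts
        elif len(parts) == 3:        # SIF: nodeA relation nodeB
            u, _, v = parts
        else:
            raise ValueError(f"{path}:{lineno}: expected 2 (edge list) or 3 (SIF) columns, got {len(parts)}")
        u, v = u.strip(), v.strip()
        if not u or not v:
            raise ValueError(f"{path}:{lineno}: empty node identifier")
        if u == v:
            n_loops += 1
            g.add_node(u)
            continue
        g.add_edge(u, v)
    if n_loops:
        logger.warning("removed %d self-loop(s) while reading %s", n_loops, path)
    return PpiNetwork(graph=g, provenance=provenance or str(path))


def largest_connected_component(net: PpiNetwork) -> PpiNetwork:
    """The maximal connected subnetwork; ties broken by the component
    containing the lexicographically smallest node id."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot take the largest component of an empty network")
    comps = list(nx.connected_components(net.graph))
    best_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == best_size]
    best = min(tied, key=lambda c: min(c))
    sub = net.graph.subgraph(best).copy()
    return PpiNetwork(graph=sub, provenance=net.provenance)


def read_pathway_collection(gmt_path, edges_path=None) -> list[PathwayGraph]:
    """Read pathways from a GMT file plus an optional 3-column edge TSV.

    GMT lines are ``name<TAB>description<TAB>gene...``; edge lines are
    ``pathway_id<TAB>geneA<TAB>geneB`` and must reference member genes.
    Pathways without edge lines become edgeless graphs (logged).
    """
    pathways: dict[str, PathwayGraph] = {}
    with open(gmt_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{gmt_path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in pathways:
                raise ValueError(f"duplicate pathway id {name!r}")
            g = nx.Graph()
            g.add_nodes_from(genes)
            pathways[name] = PathwayGraph(pathway_id=name, name=desc or name, graph=g)
    if edges_path is not None:
        with open(edges_path) as fh:
            for lineno, ln in enumerate(fh, start=1):
                ln = ln.rstrip("\n")
                if not ln.strip():
                    continue
                parts = ln.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{edges_path}:{lineno}: expected pathway_id, geneA, geneB")
                pid, a, b = parts
                if pid not in pathways:
                    raise ValueError(f"{edges_path}:{lineno}: unknown pathway {pid!r}")
                members = pathways[pid].nodes
                for gene in (a, b):
                    if gene not in members:
                        raise ValueError(
                            f"edge in pathway {pid!r} references non-member gene {gene!r}"
                        )
                if a != b:
                    pathways[pid].graph.add_edge(a, b)
    n_edgeless = sum(1 for p in pathways.values() if p.graph.number_of_edges() == 0)
    if n_edgeless:
        logger.info("%d of %d pathways have no edges", n_edgeless, len(pathways))
    return list(pathways.values())


# ---------------------------------------------------------------------------
# network writers

_FORMATS = ("graphml", "sif", "tsv")


def write_network(net, path, fmt: str = "graphml") -> None:
    """Write a network (PpiNetwork or nx.Graph) as GraphML, SIF or 2-column TSV.

    GraphML preserves edge attributes (e.g. cross-talk score, p, fdr);
    SIF/TSV keep node and edge sets only.
    """
    g = net.graph if isinstance(net, PpiNetwork) else net
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose one of {_FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(nx.isolates(g)):
                fh.write(f"{n}\n")
    else:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"{u}\t{v}\n")
            for n in sorted(nx.isolates(g)):
                fh.write(f"{n}\n")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    """Counterpart of :func:`write_network`; round-trips node/edge/attribute sets."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose one of {_FORMATS}")
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif fmt == "sif" and len(parts) == 3:
                g.add_edge(parts[0], parts[2])
            elif fmt == "tsv" and len(parts) == 2:
                g.add_edge(parts[0], parts[1])
            elif any(parts):
                raise ValueError(f"malformed {fmt} line: {ln!r}")
    return g
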