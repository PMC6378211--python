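"""Readers, writers and validated in-memory containers for every file the pipeline touches.

All tabular files are tab-separated UTF-8 with a header row. Gene identifiers
are matched by exact, case-sensitive string comparison; no alias resolution is
attempted because expression tables routinely mix gene symbols (``GTF2H4``)
with transcript-locus names (``RP11-203J24.9``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("cerna_ti")

BIOTYPES = ("mRNA", "lncRNA", "miRNA")

#: the three typed regulatory edge classes of a ceRNA analysis
EDGE_LNC_MRNA = "lncRNA-mRNA"
EDGE_LNC_MIRNA = "lncRNA-miRNA"
EDGE_MIRNA_MRNA = "miRNA-mRNA"
EDGE_TYPES = (EDGE_LNC_MRNA, EDGE_LNC_MIRNA, EDGE_MIRNA_MRNA)

#: expected endpoint biotypes (source, target) per edge type
_EDGE_ENDPOINTS = {
    EDGE_LNC_MRNA: ("lncRNA", "mRNA"),
    EDGE_LNC_MIRNA: ("lncRNA", "miRNA"),
    EDGE_MIRNA_MRNA: ("miRNA", "mRNA"),
}


class ValidationError(ValueError):
    """A file or container violated a structural contract; message names the offender."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with per-sample (patient, time) metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample names. Entries are
        non-negative finite abundances (FPKM-like; units treated as opaque).
    biotype
        Per-gene label in ``{"mRNA", "lncRNA", "miRNA"}``, aligned to ``values.index``.
    sample_meta
        DataFrame indexed by sample name with columns ``patient`` and
        ``time_hours``; every sample column of ``values`` must appear here.
    """

    values: pd.DataFrame
    biotype: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample name: {dup!r}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = vals.columns[[not np.issubdtype(d, np.number) for d in vals.dtypes]][0]
            raise ValidationError(f"non-numeric expression column: {bad!r}")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {vals.index[g]!r}, sample {vals.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {vals.index[g]!r}, sample {vals.columns[s]!r}"
            )
        if not self.biotype.index.equals(vals.index):
            raise ValidationError("biotype index does not match gene ids")
        unknown = set(self.biotype.unique()) - set(BIOTYPES)
        if unknown:
            raise ValidationError(f"unknown biotype label(s): {sorted(unknown)}")
        missing = [s for s in vals.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        for col in ("patient", "time_hours"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        meta = self.sample_meta.loc[list(vals.columns)]
        keys = list(zip(meta["patient"], meta["time_hours"]))
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValidationError(f"duplicate (patient, time) sample key: {dup}")

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patients(self) -> list[str]:
        meta = self.sample_meta.loc[self.samples]
        return list(dict.fromkeys(meta["patient"]))

    @property
    def time_points(self) -> list[float]:
        meta = self.sample_meta.loc[self.samples]
        return sorted(set(meta["time_hours"]))

    def samples_of_patient(self, patient: str) -> list[str]:
        """Sample names of one patient, ordered by time."""
        meta = self.sample_meta.loc[self.samples]
        sub = meta[meta["patient"] == patient].sort_values("time_hours")
        if sub.empty:
            raise ValidationError(f"unknown patient: {patient!r}")
        return list(sub.index)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids]
        missing = [g for g in ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[ids],
            biotype=self.biotype.loc[ids],
            sample_meta=self.sample_meta,
        )

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return list(self.biotype.index[self.biotype == biotype])


def read_expression(
    path: str | Path,
    meta_path: str | Path,
    biotype_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (+ sample metadata, + biotypes) into a validated matrix.

    The expression TSV has gene ids in the first column and either a
    ``biotype`` column or a two-column sidecar TSV (``gene``, ``biotype``)
    given as ``biotype_path``. Row and column order are preserved.
    """
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if "biotype" in tab.columns:
        biotype = tab["biotype"].astype(str)
        tab = tab.drop(columns=["biotype"])
    elif biotype_path is not None:
        bt = pd.read_csv(biotype_path, sep="\t", index_col=0)
        if "biotype" not in bt.columns:
            raise ValidationError(f"{biotype_path}: expected a 'biotype' column")
        try:
            biotype = bt["biotype"].astype(str).loc[tab.index]
        except KeyError as exc:
            raise ValidationError(f"biotype sidecar missing gene(s): {exc}") from exc
    else:
        raise ValidationError(
            f"{path}: no 'biotype' column and no biotype sidecar supplied"
        )
    for col in tab.columns:
        if not np.issubdtype(tab[col].dtype, np.number):
            bad = tab[col][pd.to_numeric(tab[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}"
            )
    tab = tab.astype(float)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample", "patient", "time_hours"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"{meta_path}: metadata needs columns {sorted(required)}"
        )
    meta = meta.set_index("sample")
    unknown = [s for s in meta.index if s not in tab.columns]
    if unknown:
        raise ValidationError(f"metadata names unknown sample(s): {unknown}")
    return ExpressionMatrix(values=tab, biotype=biotype, sample_meta=meta)


def write_expression(expr: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix (with an inline ``biotype`` column) and its sample metadata."""
    out = expr.values.copy()
    out.insert(0, "biotype", expr.biotype)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
    meta = expr.sample_meta.loc[expr.samples].copy()
    meta.index.name = "sample"
    meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# TargetPairSet
# ---------------------------------------------------------------------------

@dataclass
class TargetPairSet:
    """Typed candidate regulatory pairs: (source, target, edge_type) triples, deduplicated."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["source", "target", "type"])
    )

    def __post_init__(self) -> None:
        e = self.edges
        unknown = set(e["type"]) - set(EDGE_TYPES)
        if unknown:
            raise ValidationError(f"unknown edge type token(s): {sorted(unknown)}")
        n_before = len(e)
        self.edges = e.drop_duplicates().reset_index(drop=True)
        if len(self.edges) < n_before:
            logger.warning(
                "dropped %d duplicate pair(s)", n_before - len(self.edges)
            )

    def __len__(self) -> int:
        return len(self.edges)

    def of_type(self, edge_type: str) -> pd.DataFrame:
        if edge_type not in EDGE_TYPES:
            raise ValidationError(f"unknown edge type token: {edge_type!r}")
        return self.edges[self.edges["type"] == edge_type]

    def as_tuples(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.edges.to_numpy()))

    def validate_biotypes(self, expr: ExpressionMatrix) -> None:
        """Check that measured endpoints carry the biotype their edge type declares."""
        bt = expr.biotype
        for _, (src, tgt, etype) in self.edges.iterrows():
            want_src, want_tgt = _EDGE_ENDPOINTS[etype]
            if src in bt.index and bt[src] != want_src:
                raise ValidationError(
                    f"pair ({src}, {tgt}, {etype}): source biotype {bt[src]} != {want_src}"
                )
            if tgt in bt.index and bt[tgt] != want_tgt:
                raise ValidationError(
                    f"pair ({src}, {tgt}, {etype}): target biotype {bt[tgt]} != {want_tgt}"
                )


def read_pairs(path: str | Path) -> TargetPairSet:
    """Read a pair TSV with columns ``source``, ``target``, ``type``."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "type"}
    if not required.issubset(tab.columns):
        raise ValidationError(f"{path}: pair file needs columns {sorted(required)}")
    return TargetPairSet(edges=tab[["source", "target", "type"]])


def write_pairs(pairs: TargetPairSet, path: str | Path) -> None:
    pairs.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AnnotationMap
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """Functional term -> gene-set map with an explicit test universe.

    ``terms`` maps term id to ``(term_name, frozenset of gene ids)``; every
    annotated gene must belong to ``universe``.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValidationError(
                    f"term {term_id}: annotated gene(s) outside universe: {sorted(stray)[:5]}"
                )

    def restrict_universe(self, genes: Iterable[str]) -> "AnnotationMap":
        """Intersect the universe (and every term) with ``genes``."""
        uni = self.universe & frozenset(genes)
        terms = {
            tid: (name, members & uni)
            for tid, (name, members) in self.terms.items()
            if members & uni
        }
        return AnnotationMap(terms=terms, universe=uni)


def read_annotations(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationMap:
    """Read a GMT-like TSV: ``term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ...``.

    If ``universe`` is omitted it defaults to the union of all annotated genes.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: need term_id, name and >=1 gene")
        terms[parts[0]] = (parts[1], frozenset(parts[2:]))
    if universe is None:
        uni = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    else:
        uni = frozenset(universe)
        terms = {t: (n, g & uni) for t, (n, g) in terms.items() if g & uni}
    return AnnotationMap(terms=terms, universe=uni)


def write_annotations(annot: AnnotationMap, path: str | Path) -> None:
    lines = [
        "\t".join([tid, name, *sorted(genes)])
        for tid, (name, genes) in annot.terms.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Network export (CeRNANetwork lives in cerna_network; export here so every
# on-disk format sits in one module)
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path, format: str = "SIF") -> None:
    """Export a ceRNA network for Cytoscape.

    SIF uses the edge type as the interaction token (one data line per edge);
    GraphML carries node ``biotype`` and edge ``type`` attributes; TSV is the
    same edge-list dialect ``read_pairs`` accepts, so a TSV round trip
    reproduces the edge set exactly.
    """
    fmt = format.upper()
    path = Path(path)
    edges = sorted(net.edges)  # (source, target, type) triples
    if fmt == "SIF":
        lines = [f"{s}\t{et}\t{t}" for s, t, et in edges]
        # isolated nodes: bare node-name lines, per the SIF convention
        touched = {s for s, _, _ in edges} | {t for _, t, _ in edges}
        lines += [n for n in sorted(net.nodes) if n not in touched]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GRAPHML":
        g = nx.Graph()
        for node, biotype in sorted(net.nodes.items()):
            g.add_node(node, biotype=biotype)
        for s, t, et in edges:
            g.add_edge(s, t, type=et)
        nx.write_graphml(g, path)
    elif fmt == "TSV":
        rows = [{"source": s, "target": t, "type": et} for s, t, et in edges]
        pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValidationError(f"unknown network format: {format!r}")
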