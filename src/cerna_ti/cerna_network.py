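"""Stage 4: ceRNA (lncRNA-miRNA-mRNA) network assembly.

A candidate lncRNA-mRNA pair survives when the two RNAs are strongly
co-expressed (|Pearson r| at or above a cutoff, both signs admitted). A
ceRNA triplet (L, mi, M) requires the surviving co-expressed pair (L, M)
plus database edges (L, mi) and (mi, M): the lncRNA and mRNA compete for
the shared miRNA. The network is the union of the three typed edge sets
restricted to triplet members; gene-centred functional submodules are the
closure of all triplets through a focus mRNA set. miRNA expression is not
required — miRNA edges come from databases, not measurement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import TraitVector
from .io_formats import (
    EDGE_LNC_MIRNA,
    EDGE_LNC_MRNA,
    EDGE_MIRNA_MRNA,
    ExpressionMatrix,
    TargetPairSet,
    ValidationError,
)
from .timecourse_profiles import gene_time_series

logger = logging.getLogger("cerna_ti")

DEFAULT_MIN_ABS_R = 0.9


@dataclass(frozen=True)
class CoexpressedPair:
    lncrna: str
    mrna: str
    r: float
    direction: str  # "positive" | "negative"


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna: str
    mirna: str
    mrna: str


@dataclass
class CeRNANetwork:
    """Typed nodes and edges plus the triplet list that justifies each link."""

    nodes: dict[str, str] = field(default_factory=dict)       # id -> biotype
    edges: set[tuple[str, str, str]] = field(default_factory=set)  # (src, tgt, type)
    triplets: list[CeRNATriplet] = field(default_factory=list)

    def validate(self) -> None:
        for s, t, _ in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise ValidationError(f"edge ({s}, {t}) has an endpoint without a node")
        for tr in self.triplets:
            for e in [
                (tr.lncrna, tr.mrna, EDGE_LNC_MRNA),
                (tr.lncrna, tr.mirna, EDGE_LNC_MIRNA),
                (tr.mirna, tr.mrna, EDGE_MIRNA_MRNA),
            ]:
                if e not in self.edges:
                    raise ValidationError(f"triplet {tr} lacks its edge {e}")

    def node_counts(self) -> dict[str, int]:
        counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
        for biotype in self.nodes.values():
            counts[biotype] += 1
        return counts

    def edge_counts(self) -> dict[str, int]:
        counts = {EDGE_LNC_MRNA: 0, EDGE_LNC_MIRNA: 0, EDGE_MIRNA_MRNA: 0}
        for _, _, etype in self.edges:
            counts[etype] += 1
        return counts

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Co-expression screening of candidate pairs
# ---------------------------------------------------------------------------

def coexpressed_pairs(
    expr: ExpressionMatrix,
    candidate_pairs: TargetPairSet,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
) -> list[CoexpressedPair]:
    """Retain candidate lncRNA-mRNA pairs with |Pearson r| >= cutoff on log(x+1).

    Pairs with an endpoint absent from the matrix, or with a constant profile
    (undefined correlation), are skipped with a logged count.
    """
    cand = candidate_pairs.of_type(EDGE_LNC_MRNA)
    logged = np.log1p(expr.values.astype(float))
    kept: list[CoexpressedPair] = []
    n_missing = n_undefined = 0
    for src, tgt in zip(cand["source"], cand["target"]):
        if src not in logged.index or tgt not in logged.index:
            n_missing += 1
            continue
        x = logged.loc[src].to_numpy()
        y = logged.loc[tgt].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_undefined += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= min_abs_r:
            kept.append(CoexpressedPair(
                lncrna=src, mrna=tgt, r=r,
                direction="positive" if r >= 0 else "negative",
            ))
    if n_missing or n_undefined:
        logger.info("co-expression screen skipped %d pair(s) with missing endpoints "
                    "and %d with constant profiles", n_missing, n_undefined)
    logger.info("co-expression screen: %d/%d candidate pairs at |r| >= %g",
                len(kept), len(cand), min_abs_r)
    return kept


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_cerna(
    coexpressed: list[CoexpressedPair],
    pairs: TargetPairSet,
) -> CeRNANetwork:
    """Build the ceRNA network from co-expressed pairs and database edges.

    Triplets are every (L, mi, M) with (L, M) co-expressed, (L, mi) in the
    lncRNA-miRNA set and (mi, M) in the miRNA-mRNA set; nodes and edges are
    the deduplicated union over triplets.
    """
    lnc_mi = pairs.of_type(EDGE_LNC_MIRNA)
    mi_m = pairs.of_type(EDGE_MIRNA_MRNA)
    mirnas_of_lnc: dict[str, set[str]] = {}
    for l, mi in zip(lnc_mi["source"], lnc_mi["target"]):
        mirnas_of_lnc.setdefault(l, set()).add(mi)
    mirnas_of_mrna: dict[str, set[str]] = {}
    for mi, m in zip(mi_m["source"], mi_m["target"]):
        mirnas_of_mrna.setdefault(m, set()).add(mi)

    net = CeRNANetwork()
    for pair in coexpressed:
        shared = mirnas_of_lnc.get(pair.lncrna, set()) & mirnas_of_mrna.get(pair.mrna, set())
        for mi in sorted(shared):
            net.triplets.append(CeRNATriplet(pair.lncrna, mi, pair.mrna))
            net.nodes[pair.lncrna] = "lncRNA"
            net.nodes[mi] = "miRNA"
            net.nodes[pair.mrna] = "mRNA"
            net.edges.add((pair.lncrna, pair.mrna, EDGE_LNC_MRNA))
            net.edges.add((pair.lncrna, mi, EDGE_LNC_MIRNA))
            net.edges.add((mi, pair.mrna, EDGE_MIRNA_MRNA))
    logger.info("ceRNA network: %d triplets, %d nodes, %d edges",
                len(net.triplets), net.n_nodes, net.n_edges)
    return net


def extract_gene_module(net: CeRNANetwork, focus_mrnas: set[str]) -> CeRNANetwork:
    """Subnetwork induced by every triplet containing a focus mRNA."""
    missing = sorted(g for g in focus_mrnas if g not in net.nodes)
    if missing:
        raise ValidationError(f"focus gene(s) absent from network: {missing}")
    not_mrna = sorted(g for g in focus_mrnas if net.nodes[g] != "mRNA")
    if not_mrna:
        raise ValidationError(f"focus gene(s) are not mRNA nodes: {not_mrna}")
    sub = CeRNANetwork()
    for g in sorted(focus_mrnas):
        sub.nodes[g] = "mRNA"
    for tr in net.triplets:
        if tr.mrna in focus_mrnas:
            sub.triplets.append(tr)
            sub.nodes[tr.lncrna] = "lncRNA"
            sub.nodes[tr.mirna] = "miRNA"
            sub.nodes[tr.mrna] = "mRNA"
            sub.edges.add((tr.lncrna, tr.mrna, EDGE_LNC_MRNA))
            sub.edges.add((tr.lncrna, tr.mirna, EDGE_LNC_MIRNA))
            sub.edges.add((tr.mirna, tr.mrna, EDGE_MIRNA_MRNA))
    return sub


# ---------------------------------------------------------------------------
# Per-node trait summary (the figure-2D style view)
# ---------------------------------------------------------------------------

def node_trait_profile(
    expr: ExpressionMatrix,
    net: CeRNANetwork,
    trait: TraitVector,
) -> pd.DataFrame:
    """Per measured node: mean time course, trait-correlation sign, peak time.

    Unmeasured nodes (typically miRNAs, whose edges are database-derived) are
    skipped. The sign is that of the Pearson correlation between the node's
    log(x+1) profile across samples and the trait.
    """
    measured = [g for g in sorted(net.nodes) if g in expr.values.index]
    if not measured:
        return pd.DataFrame(columns=["biotype", "trait_sign", "peak_time"])
    sub = expr.subset_genes(measured)
    meta = sub.sample_meta.loc[sub.samples]
    times = sorted(set(meta["time_hours"]))
    vals = sub.values.to_numpy(dtype=float)
    mean_tc = np.column_stack([
        vals[:, (meta["time_hours"] == t).to_numpy()].mean(axis=1) for t in times
    ])
    logged = np.log1p(vals)
    t = trait.values.loc[sub.samples].to_numpy(dtype=float)
    tc = t - t.mean()
    rows = []
    for i, g in enumerate(measured):
        x = logged[i] - logged[i].mean()
        denom = np.linalg.norm(x) * np.linalg.norm(tc)
        r = float(x @ tc / denom) if denom > 0 else 0.0
        rows.append({
            "node": g,
            "biotype": net.nodes[g],
            "trait_sign": "positive" if r >= 0 else "negative",
            "trait_r": r,
            "peak_time": float(times[int(np.argmax(mean_tc[i]))]),
            **{f"t{c:g}h": float(v) for c, v in zip(times, mean_tc[i])},
        })
    return pd.DataFrame(rows).set_index("node")
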