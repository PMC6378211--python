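import numpy as np
import pandas as pd
import pytest

from cerna_ti.cerna_network import (
    CoexpressedPair,
    assemble_cerna,
    coexpressed_pairs,
    extract_gene_module,
    node_trait_profile,
)
from cerna_ti.coexpression import make_trait
from cerna_ti.io_formats import (
    EDGE_LNC_MIRNA,
    EDGE_LNC_MRNA,
    EDGE_MIRNA_MRNA,
    TargetPairSet,
    ValidationError,
)

from conftest import make_expression


def pairset(rows):
    return TargetPairSet(edges=pd.DataFrame(rows, columns=["source", "target", "type"]))


def brute_force_triplets(coexpressed, pairs):
    """Triple loop over every (L, mi, M) candidate — the reference enumeration."""
    lnc_mi = set(map(tuple, pairs.of_type(EDGE_LNC_MIRNA)[["source", "target"]].to_numpy()))
    mi_m = set(map(tuple, pairs.of_type(EDGE_MIRNA_MRNA)[["source", "target"]].to_numpy()))
    mirnas = {mi for _, mi in lnc_mi} | {mi for mi, _ in mi_m}
    out = set()
    for p in coexpressed:
        for mi in mirnas:
            if (p.lncrna, mi) in lnc_mi and (mi, p.mrna) in mi_m:
                out.add((p.lncrna, mi, p.mrna))
    return out


def test_minimal_triplet():
    co = [CoexpressedPair("L1", "M1", 1.0, "positive")]
    pairs = pairset([("L1", "mi1", EDGE_LNC_MIRNA), ("mi1", "M1", EDGE_MIRNA_MRNA)])
    net = assemble_cerna(co, pairs)
    assert [(t.lncrna, t.mirna, t.mrna) for t in net.triplets] == [("L1", "mi1", "M1")]
    assert net.n_nodes == 3 and net.n_edges == 3
    net.validate()


def test_no_shared_mirna_gives_empty_network():
    co = [CoexpressedPair("L1", "M1", 1.0, "positive")]
    pairs = pairset([("L1", "mi1", EDGE_LNC_MIRNA), ("mi2", "M1", EDGE_MIRNA_MRNA)])
    net = assemble_cerna(co, pairs)
    assert net.triplets == [] and net.n_nodes == 0 and net.n_edges == 0


def test_assembly_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(10):
        lncs = [f"L{i}" for i in range(30)]
        mis = [f"mi{i}" for i in range(15)]
        mrnas = [f"M{i}" for i in range(50)]
        rows = []
        for L in lncs:
            for mi in mis:
                if rng.random() < 0.1:
                    rows.append((L, mi, EDGE_LNC_MIRNA))
        for mi in mis:
            for M in mrnas:
                if rng.random() < 0.1:
                    rows.append((mi, M, EDGE_MIRNA_MRNA))
        pairs = pairset(rows)
        co = [CoexpressedPair(L, M, 1.0, "positive")
              for L in lncs for M in mrnas if rng.random() < 0.05]
        net = assemble_cerna(co, pairs)
        got = {(t.lncrna, t.mirna, t.mrna) for t in net.triplets}
        assert got == brute_force_triplets(co, pairs)
        net.validate()


def test_triplet_count_monotone_in_edges():
    """Adding pairs never removes triplets."""
    rng = np.random.default_rng(23)
    rows = [("L1", "mi1", EDGE_LNC_MIRNA), ("mi1", "M1", EDGE_MIRNA_MRNA)]
    co = [CoexpressedPair("L1", "M1", 0.95, "positive"),
          CoexpressedPair("L2", "M2", -0.95, "negative")]
    base = assemble_cerna(co, pairset(rows))
    more = rows + [("L2", "mi2", EDGE_LNC_MIRNA), ("mi2", "M2", EDGE_MIRNA_MRNA),
                   ("L1", "mi3", EDGE_LNC_MIRNA), ("mi3", "M1", EDGE_MIRNA_MRNA)]
    bigger = assemble_cerna(co, pairset(more))
    base_set = {(t.lncrna, t.mirna, t.mrna) for t in base.triplets}
    bigger_set = {(t.lncrna, t.mirna, t.mrna) for t in bigger.triplets}
    assert base_set <= bigger_set and len(bigger_set) > len(base_set)


def test_coexpression_screen_on_toy(toy):
    """The toy's two planted pairs have identical profiles (r = 1) and survive
    any cutoff; assembly returns exactly the two planted triplets."""
    expr, pairs, *_ = toy
    kept = coexpressed_pairs(expr, pairs, min_abs_r=0.99)
    assert {(p.lncrna, p.mrna) for p in kept} == {("LNC_T1", "MRNA_T1"),
                                                  ("LNC_T2", "MRNA_T2")}
    assert all(p.r == pytest.approx(1.0) for p in kept)
    net = assemble_cerna(kept, pairs)
    got = {(t.lncrna, t.mirna, t.mrna) for t in net.triplets}
    assert got == {("LNC_T1", "MIR_T1", "MRNA_T1"), ("LNC_T2", "MIR_T2", "MRNA_T2")}


def test_coexpression_screen_zero_cutoff_keeps_all_defined(toy):
    expr, pairs, *_ = toy
    kept = coexpressed_pairs(expr, pairs, min_abs_r=0.0)
    assert len(kept) == len(pairs.of_type(EDGE_LNC_MRNA))


def test_coexpression_null_tail():
    """With random expression the retained fraction matches the null tail
    P(|r| >= cut) estimated by direct simulation."""
    rng = np.random.default_rng(31)
    n_genes, n_samp, cut = 300, 10, 0.8
    expr = make_expression(rng.lognormal(2, 1, size=(n_genes, n_samp)))
    genes = list(expr.gene_ids)
    rows = []
    for _ in range(1000):
        i, j = rng.choice(n_genes, size=2, replace=False)
        rows.append((genes[i], genes[j], EDGE_LNC_MRNA))
    kept = coexpressed_pairs(expr, pairset(rows), min_abs_r=cut)
    # independent Monte-Carlo oracle for P(|r| >= cut) at this sample size
    sims = np.array([
        abs(np.corrcoef(rng.normal(size=n_samp), rng.normal(size=n_samp))[0, 1])
        for _ in range(4000)
    ])
    p_null = (sims >= cut).mean()
    frac = len(kept) / len(rows)
    se = np.sqrt(p_null * (1 - p_null) / 1000) + np.sqrt(p_null * (1 - p_null) / 4000)
    assert abs(frac - p_null) < 4 * se + 1e-3


def test_extract_gene_module_closure_and_idempotence():
    co = [CoexpressedPair("L1", "M1", 1.0, "positive"),
          CoexpressedPair("L2", "M2", 1.0, "positive")]
    pairs = pairset([
        ("L1", "mi1", EDGE_LNC_MIRNA), ("mi1", "M1", EDGE_MIRNA_MRNA),
        ("L1", "mi2", EDGE_LNC_MIRNA), ("mi2", "M1", EDGE_MIRNA_MRNA),
        ("L2", "mi3", EDGE_LNC_MIRNA), ("mi3", "M2", EDGE_MIRNA_MRNA),
    ])
    net = assemble_cerna(co, pairs)
    full = extract_gene_module(net, {"M1", "M2"})
    assert full.nodes == net.nodes and full.edges == net.edges
    sub = extract_gene_module(net, {"M1"})
    assert set(sub.nodes) == {"L1", "mi1", "mi2", "M1"}
    assert sub.edge_counts()[EDGE_MIRNA_MRNA] == 2
    again = extract_gene_module(sub, {"M1"})
    assert again.nodes == sub.nodes and again.edges == sub.edges


def test_extract_missing_focus_rejected():
    net = assemble_cerna(
        [CoexpressedPair("L1", "M1", 1.0, "positive")],
        pairset([("L1", "mi1", EDGE_LNC_MIRNA), ("mi1", "M1", EDGE_MIRNA_MRNA)]),
    )
    with pytest.raises(ValidationError, match="GHOST"):
        extract_gene_module(net, {"GHOST"})


def test_edge_count_bookkeeping(default_dataset):
    expr, pairs, *_ = default_dataset
    kept = coexpressed_pairs(expr, pairs, min_abs_r=0.9)
    net = assemble_cerna(kept, pairs)
    assert net.n_edges == sum(net.edge_counts().values())
    assert net.n_nodes == sum(net.node_counts().values())


def test_node_trait_profile_signs(toy):
    expr, pairs, *_ = toy
    kept = coexpressed_pairs(expr, pairs, 0.99)
    net = assemble_cerna(kept, pairs)
    trait = make_trait(expr.sample_meta.loc[expr.samples], "binary")
    tab = node_trait_profile(expr, net, trait)
    # T2 partners fall monotonically after time 0 -> negative trait correlation
    assert tab.loc["MRNA_T2", "trait_sign"] == "negative"
    assert tab.loc["MRNA_T1", "trait_sign"] == "positive"
    assert tab.loc["MRNA_T1", "peak_time"] == 12.0  # peak at 12 h
    assert "MIR_T1" not in tab.index  # unmeasured miRNAs are skipped
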