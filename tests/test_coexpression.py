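import numpy as np
import networkx as nx
import pandas as pd
import pytest

from cerna_ti.coexpression import (
    CoexpressionModule,
    adjacency_matrix,
    detect_modules,
    make_trait,
    module_eigengene,
    module_trait_association,
    scale_free_fit,
    select_power,
    topological_overlap,
    TraitVector,
)
from cerna_ti.io_formats import ValidationError

from conftest import make_expression


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop implementation of the unsigned TOM."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n=20):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def test_tom_complete_graph():
    """All-ones adjacency on 3 nodes: TOM = (1+1)/(2+1-1) = 1 everywhere."""
    a = np.ones((3, 3)) - np.eye(3)
    assert np.allclose(topological_overlap(a), np.ones((3, 3)))


def test_tom_empty_graph():
    tom = topological_overlap(np.zeros((4, 4)))
    assert np.allclose(tom, np.eye(4))


def test_tom_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a = random_adjacency(rng, 30)
        assert np.max(np.abs(topological_overlap(a) - tom_brute_force(a))) < 1e-10


def test_tom_range_and_symmetry():
    rng = np.random.default_rng(9)
    a = random_adjacency(rng, 40)
    tom = topological_overlap(a)
    assert np.allclose(tom, tom.T)
    assert tom.min() >= 0 and tom.max() <= 1


def test_tom_rejects_asymmetric():
    a = np.zeros((3, 3))
    a[0, 1] = 0.5
    with pytest.raises(ValidationError, match="symmetric"):
        topological_overlap(a)


# ---------------------------------------------------------------------------
# Power selection
# ---------------------------------------------------------------------------

def test_adjacency_monotone_in_power(default_dataset):
    """|r| <= 1, so raising beta never increases any off-diagonal entry."""
    expr, *_ = default_dataset
    sub = expr.subset_genes(expr.gene_ids[:40])
    a2 = adjacency_matrix(sub, 2).to_numpy()
    a6 = adjacency_matrix(sub, 6).to_numpy()
    assert (a6 <= a2 + 1e-12).all()


def test_scale_free_fit_exact_power_law():
    """Connectivity counts following an exact power law give R-squared 1."""
    k = np.repeat([1.0, 2.0, 4.0, 8.0], [8, 4, 2, 1])  # freq ~ k^-1
    assert scale_free_fit(k) == pytest.approx(1.0, abs=1e-12)


def test_select_power_on_scale_free_structure():
    """Expression whose correlation structure mirrors a preferential-attachment
    graph reaches the 0.9 scale-free fit at a small power."""
    rng = np.random.default_rng(0)
    g = nx.barabasi_albert_graph(400, 2, seed=1)
    n_samp = 60
    f = rng.normal(size=(400, n_samp))
    x = np.zeros((400, n_samp))
    for i in range(400):
        x[i] = f[list(g.neighbors(i))].sum(axis=0) + 0.3 * rng.normal(size=n_samp)
    expr = make_expression(np.expm1(x - x.min()))
    scan = select_power(expr)
    assert not scan.flagged
    assert scan.selected <= 8
    assert scan.fit_r2[scan.powers.index(scan.selected)] >= 0.9


def test_select_power_fallback_flag():
    """When no power reaches the target, the scan flags and picks argmax R2."""
    rng = np.random.default_rng(1)
    expr = make_expression(rng.lognormal(1, 0.5, size=(30, 10)))
    scan = select_power(expr, target_r2=1.0)
    assert scan.flagged
    assert scan.fit_r2[scan.powers.index(scan.selected)] == max(scan.fit_r2)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def test_two_planted_blocks_detected_exactly():
    """Block-diagonal adjacency (within-block 1, between 0) yields exactly the
    two planted modules."""
    n = 30
    a = np.zeros((2 * n, 2 * n))
    a[:n, :n] = 1.0
    a[n:, n:] = 1.0
    np.fill_diagonal(a, 0.0)
    genes = [f"G{i:03d}" for i in range(2 * n)]
    tom = topological_overlap(pd.DataFrame(a, index=genes, columns=genes))
    modules, unassigned = detect_modules(tom, min_size=20, cut_height=0.95)
    assert sorted(len(m.members) for m in modules) == [n, n]
    assert unassigned == []
    assert set(modules[0].members) in ({*genes[:n]}, {*genes[n:]})


def test_uncorrelated_genes_all_unassigned():
    tom = topological_overlap(np.zeros((25, 25)))
    genes = [f"G{i}" for i in range(25)]
    modules, unassigned = detect_modules(
        pd.DataFrame(tom, index=genes, columns=genes), min_size=20
    )
    assert modules == [] and len(unassigned) == 25


def test_min_size_larger_than_gene_count():
    tom = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
    modules, unassigned = detect_modules(tom, min_size=10)
    assert modules == []


def test_module_partition(default_dataset):
    """No gene belongs to two modules; modules + unassigned cover the input."""
    expr, *_ = default_dataset
    sub = expr.subset_genes(expr.gene_ids[:120])
    tom = topological_overlap(adjacency_matrix(sub, 6))
    modules, unassigned = detect_modules(tom, min_size=10)
    seen = [g for m in modules for g in m.members] + unassigned
    assert sorted(seen) == sorted(tom.index)


# ---------------------------------------------------------------------------
# Eigengene
# ---------------------------------------------------------------------------

def test_eigengene_identical_profiles():
    base = np.array([1.0, 4.0, 16.0, 4.0, 1.0] * 2)
    vals = np.vstack([base, base, base])
    expr = make_expression(vals)
    mod = CoexpressionModule(label="M1", members=["G0000", "G0001", "G0002"])
    eig = module_eigengene(expr, mod)
    assert mod.explained_variance == pytest.approx(1.0)
    z = np.log1p(base)
    z = (z - z.mean()) / z.std(ddof=1)
    assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
    assert np.corrcoef(eig, z)[0, 1] > 0  # orientation follows the mean profile


def test_eigengene_anticorrelated_pair_sign_convention():
    x = np.linspace(1, 5, 10)
    vals = np.vstack([np.expm1(x), np.expm1(6 - x)])
    expr = make_expression(vals)
    mod = CoexpressionModule(label="M1", members=["G0000", "G0001"])
    eig = module_eigengene(expr, mod)
    assert mod.explained_variance == pytest.approx(1.0)
    assert np.linalg.norm(eig) == pytest.approx(1.0)


def test_eigengene_matches_dense_eigendecomposition():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(2, 0.8, size=(15, 10))
    expr = make_expression(vals)
    mod = CoexpressionModule(label="M1", members=[f"G{i:04d}" for i in range(15)])
    eig = module_eigengene(expr, mod).to_numpy()
    z = np.log1p(vals)
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    w, v = np.linalg.eigh(z.T @ z)
    lead = v[:, -1]
    assert min(np.abs(eig - lead).max(), np.abs(eig + lead).max()) < 1e-8


# ---------------------------------------------------------------------------
# Module-trait association
# ---------------------------------------------------------------------------

def _module_with_eigengene(vec, samples):
    m = CoexpressionModule(label="M1", members=["g"])
    m.eigengene = pd.Series(vec, index=samples)
    return m


def test_trait_association_perfect_and_orthogonal():
    samples = [f"S{i}" for i in range(10)]
    t = pd.Series([0.0] * 5 + [1.0] * 5, index=samples)
    trait = TraitVector(values=t, encoding_name="binary")
    m = _module_with_eigengene((t - t.mean()) / np.linalg.norm(t - t.mean()), samples)
    module_trait_association([m], trait)
    assert m.trait_correlation == pytest.approx(1.0)
    assert m.trait_p < 1e-10
    # sum-zero within each trait level -> orthogonal to the trait
    orth = np.array([1, -1, 1, -1, 0, 1, -1, 1, -1, 0], dtype=float)
    m2 = _module_with_eigengene(orth / np.linalg.norm(orth), samples)
    module_trait_association([m2], trait)
    assert m2.trait_correlation == pytest.approx(0.0, abs=1e-12)
    assert m2.trait_p == pytest.approx(1.0)


def test_trait_encodings():
    meta = pd.DataFrame(
        {"patient": ["P1"] * 5, "time_hours": [0.0, 2.0, 12.0, 24.0, 72.0]},
        index=[f"P1_t{t:g}" for t in (0, 2, 12, 24, 72)],
    )
    assert list(make_trait(meta, "binary").values) == [0, 1, 1, 1, 1]
    assert list(make_trait(meta, "hours").values) == [0, 2, 12, 24, 72]
    with pytest.raises(ValidationError):
        make_trait(meta, "exotic")
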