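"""Nei distance, Weir-Cockerham Fst and neighbor joining."""

import numpy as np
import pytest

from condiv import (
    DistanceMatrix,
    GenotypePanel,
    SampleRecord,
    VariantRecord,
    expected_identity,
    neighbor_joining,
    nei_distance_matrix,
    nei_minimum_distance,
    simple_fst,
    simulate_panel,
    wc_fst_global,
    wc_fst_pair,
)
from condiv.synthetic_data import SimulationConfig


def two_breed_panel(cols_x, cols_y):
    """Two breeds from genotype columns (lists over samples per variant)."""
    variants = [VariantRecord(f"v{j}", "1", 100 * (j + 1), "A", "G") for j in range(len(cols_x))]
    samples = [SampleRecord(f"x{i}", "X") for i in range(len(cols_x[0]))] + [
        SampleRecord(f"y{i}", "Y") for i in range(len(cols_y[0]))
    ]
    calls = np.vstack(
        [np.array(cols_x, dtype=np.int8).T, np.array(cols_y, dtype=np.int8).T]
    )
    return GenotypePanel(samples, variants, calls)


# ----------------------------------------------------------------------
# identity and Nei distance
# ----------------------------------------------------------------------

def test_expected_identity_limits(toy_panel):
    mono = two_breed_panel([[0, 0, 0]], [[2, 2, 2]])
    assert expected_identity(mono, "X") == 1.0
    balanced = two_breed_panel([[0, 1, 1, 2]], [[0, 0, 1, 1]])
    assert expected_identity(balanced, "X") == 0.5  # p = 0.5


def test_nei_distance_worked_examples():
    # same breed -> exactly 0
    panel = two_breed_panel([[0, 1, 2]], [[0, 1, 2]])
    assert nei_minimum_distance(panel, "X", "X") == 0.0
    # opposite fixation at one locus -> (1 + 1)/2 - 0 = 1
    fixed = two_breed_panel([[2, 2]], [[0, 0]])
    assert nei_minimum_distance(fixed, "X", "Y") == 1.0
    # p_X = 0.8 vs p_Y = 0.2 -> (0.68 + 0.68)/2 - 0.32 = 0.36
    skew = two_breed_panel([[2, 2, 2, 1, 1]], [[0, 0, 0, 1, 1]])
    assert nei_minimum_distance(skew, "X", "Y") == pytest.approx(0.36, abs=1e-12)


def test_nei_distance_toy_values(toy_panel):
    # frozen from brute-force enumeration of the toy panel frequencies
    assert nei_minimum_distance(toy_panel, "RED", "BLU") == pytest.approx(23 / 96, abs=1e-12)
    assert nei_minimum_distance(toy_panel, "BLU", "GRN") == pytest.approx(0.13020833333333334, abs=1e-12)
    assert nei_minimum_distance(toy_panel, "RED", "GRN") == pytest.approx(0.057291666666666664, abs=1e-12)


def test_nei_matrix_symmetry_and_flip_invariance(toy_panel):
    dm = nei_distance_matrix(toy_panel)
    assert np.array_equal(dm.values, dm.values.T)
    assert np.all(np.diag(dm.values) == 0)
    dm_flipped = nei_distance_matrix(toy_panel.flipped())
    np.testing.assert_allclose(dm.values, dm_flipped.values, atol=1e-12)


def test_nei_distance_no_shared_loci_raises():
    panel = two_breed_panel([[0, 1], [-1, -1]], [[-1, -1], [0, 1]])
    with pytest.raises(ValueError, match="share no called loci"):
        nei_minimum_distance(panel, "X", "Y")


# ----------------------------------------------------------------------
# Fst
# ----------------------------------------------------------------------

def test_identical_breeds_give_zero_differentiation():
    col = [0, 1, 1, 2] * 50  # 200 samples per breed
    panel = two_breed_panel([col, col[::-1]], [col, col[::-1]])
    theta, simple = wc_fst_pair(panel, "X", "Y")
    assert simple == 0.0
    # theta's sampling correction leaves a small negative bias of order 1/n
    assert abs(theta) < 0.01


def test_simple_fst_closed_form():
    """p = 0.2 vs 0.8: sigma^2 / (p_bar q_bar) = 0.09 / 0.25 = 0.36."""
    panel = two_breed_panel([[1, 1, 0, 0, 0]], [[1, 1, 2, 2, 2]])
    assert simple_fst(panel, ["X", "Y"]) == pytest.approx(0.36, abs=1e-12)


def test_theta_recovers_drift_parameter():
    cfg = SimulationConfig(n_breeds=4, samples_per_breed=50, n_snps=2000,
                           breed_fst=0.10, seed=42, missing_rate=0.01)
    panel, _ = simulate_panel(cfg)
    assert wc_fst_global(panel) == pytest.approx(0.10, abs=0.02)


def test_theta_and_simple_fst_converge_at_large_equal_n():
    """The variance-ratio Fst uses the population variance across the r
    observed breeds; rescaled by r/(r-1) it approaches theta as n grows."""
    base = dict(n_breeds=4, n_snps=1500, breed_fst=0.15, seed=8, missing_rate=0.0)
    gaps = []
    for n in (10, 500):
        panel, _ = simulate_panel(SimulationConfig(samples_per_breed=n, **base))
        gaps.append(abs(wc_fst_global(panel) - simple_fst(panel) * 4 / 3))
    assert gaps[1] < gaps[0]
    assert gaps[1] < 0.01


def test_fst_flip_invariance(toy_panel):
    t1, s1 = wc_fst_pair(toy_panel, "RED", "BLU")
    t2, s2 = wc_fst_pair(toy_panel.flipped(), "RED", "BLU")
    assert t1 == pytest.approx(t2, abs=1e-12)
    assert s1 == pytest.approx(s2, abs=1e-12)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def branch_lengths(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    return {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
    newick = neighbor_joining(d, ["A", "B", "C"])
    lengths = branch_lengths(newick)
    assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):3,(C:4,D:5)) -> path-length matrix
    d = np.array(
        [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
    )
    newick = neighbor_joining(d, ["A", "B", "C", "D"])
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate("ABCD"):
        for j, b in enumerate("ABCD"):
            if i < j:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j], abs=1e-9)


def test_nj_equidistant_matrix_has_zero_internal_branches():
    d = np.full((4, 4), 2.0)
    np.fill_diagonal(d, 0.0)
    newick = neighbor_joining(d, ["A", "B", "C", "D"])
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    internal = [
        e.length for e in tree.preorder_edge_iter()
        if e.head_node is not None and not e.head_node.is_leaf() and e.length is not None
    ]
    assert all(abs(x) < 1e-12 for x in internal)
    assert all(x == pytest.approx(1.0) for x in branch_lengths(newick).values())


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])


def test_nj_cross_checked_against_reference_implementation():
    """Independent oracle: scikit-bio's NJ on an additive five-taxon matrix
    (additivity avoids implementation-specific negative-branch handling)."""
    from io import StringIO

    import dendropy
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    # caterpillar tree: A-u=1, B-u=2, u-v=2, C-v=3, v-w=1, D-w=4, E-w=5
    d = np.array(
        [
            [0, 3, 6, 8, 9],
            [3, 0, 7, 9, 10],
            [6, 7, 0, 8, 9],
            [8, 9, 8, 0, 9],
            [9, 10, 9, 9, 0],
        ],
        dtype=float,
    )
    labels = list("ABCDE")
    ours = neighbor_joining(d, labels)
    buf = StringIO()
    skbio_nj(SkbioDM(d, ids=labels)).write(buf, format="newick")
    tns = dendropy.TaxonNamespace(labels)
    t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=buf.getvalue(), schema="newick", taxon_namespace=tns)
    p1 = t1.phylogenetic_distance_matrix()
    p2 = t2.phylogenetic_distance_matrix()
    for i, a in enumerate(tns):
        for b in list(tns)[i + 1 :]:
            assert p1.distance(a, b) == pytest.approx(p2.distance(a, b), abs=1e-9)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]), "bad")
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0.5, 1.0], [1.0, 0.0]]), "bad")
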