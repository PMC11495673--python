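import numpy as np
import pytest

from pairsite.errors import DegenerateGeometryError, GraphError
from pairsite.graph_features import (
    EdgeFeatureStats,
    build_knn_graph,
    interface_labels,
    label_interactions,
    mean_residue_distance,
    read_graph_tsv,
    relative_orientation,
    residue_plane_normal,
    standardize_edge_features,
    write_graph_tsv,
    PairLabels,
)
from pairsite.structure_io import AtomRecord, ProteinStructure, ResidueRecord

from conftest import line_structure, make_backbone_residue, make_residue


# -- mean residue distance --------------------------------------------------

@pytest.mark.parametrize(
    "c1, c2, expected",
    [
        ([[0, 0, 0]], [[3, 0, 0]], 3.0),
        # 2×2 atom cross product: (4 + √20 + √20 + 4) / 4
        ([[0, 0, 0], [0, 0, 2]], [[4, 0, 0], [4, 0, 2]],
         (4 + np.sqrt(20) + np.sqrt(20) + 4) / 4),
    ],
)
def test_mean_distance_examples(c1, c2, expected):
    r1, r2 = make_residue(c1, 0), make_residue(c2, 1)
    assert mean_residue_distance(r1, r2) == pytest.approx(expected, abs=1e-12)
    assert mean_residue_distance(r2, r1) == pytest.approx(expected, abs=1e-12)


def test_mean_distance_self_is_zero():
    r = make_residue([[1, 2, 3]], 0)
    assert mean_residue_distance(r, r) == 0.0


def test_mean_distance_excludes_hydrogens():
    r1 = make_residue([[0, 0, 0]], 0)
    r2 = ResidueRecord(aa_code="G", chain_id="A", seq_index=1, atoms=[
        AtomRecord(name="C", element="C", coords=[5, 0, 0]),
        AtomRecord(name="H", element="H", coords=[1, 0, 0]),
    ])
    assert mean_residue_distance(r1, r2) == pytest.approx(5.0)


# -- plane normals and orientation -----------------------------------------

def test_plane_normal_of_right_angle_backbone():
    r = make_backbone_residue([0, 0, 0], [1, 0, 0], [1, 1, 0])
    normal = residue_plane_normal(r)
    assert np.allclose(np.abs(normal), [0, 0, 1])
    assert np.linalg.norm(normal) == pytest.approx(1.0)


def test_collinear_backbone_is_degenerate():
    r = make_backbone_residue([0, 0, 0], [1, 0, 0], [2, 0, 0])
    with pytest.raises(DegenerateGeometryError):
        residue_plane_normal(r)
    missing = make_residue([[0, 0, 0]], 0)  # no N/CA/C triple
    with pytest.raises(DegenerateGeometryError):
        residue_plane_normal(missing)


def test_relative_orientation_conventions():
    flat = make_backbone_residue([0, 0, 0], [1, 0, 0], [1, 1, 0], 0)
    flat_shifted = make_backbone_residue([5, 0, 0], [6, 0, 0], [6, 1, 0], 1)
    upright = make_backbone_residue([0, 0, 5], [1, 0, 5], [1, 0, 6], 2)
    # anti-parallel: traverse the same plane in the opposite winding
    reversed_winding = make_backbone_residue([0, 1, 0], [1, 1, 0], [1, 0, 0], 3)

    assert relative_orientation(flat, flat_shifted) == pytest.approx(0.0, abs=1e-12)
    assert relative_orientation(flat, upright) == pytest.approx(np.pi / 2, abs=1e-12)
    # |dot| convention maps anti-parallel normals to angle 0
    assert relative_orientation(flat, reversed_winding) == pytest.approx(0.0, abs=1e-12)
    assert relative_orientation(upright, flat) == pytest.approx(
        relative_orientation(flat, upright)
    )


# -- k-NN graph -------------------------------------------------------------

def test_knn_on_a_line():
    s = line_structure([0.0, 1.0, 2.0, 3.0])
    g = build_knn_graph(s, k=2)
    into_0 = sorted(g.edges[g.edges[:, 1] == 0][:, 0])
    assert into_0 == [1, 2]
    assert (g.in_degree() == 2).all()
    assert not (g.edges[:, 0] == g.edges[:, 1]).any()


def test_knn_matches_brute_force_on_fixture(fixture_complex):
    """Neighbor sets agree with an O(N²) enumeration via the same metric."""
    ligand = fixture_complex[0]
    k = 4
    g = build_knn_graph(ligand, k=k)
    n = len(ligand)
    for i in range(n):
        dists = [
            (mean_residue_distance(ligand.residues[i], ligand.residues[j]), j)
            for j in range(n) if j != i
        ]
        expected = {j for _, j in sorted(dists)[:k]}
        got = set(g.edges[g.edges[:, 1] == i][:, 0])
        assert got == expected


def test_knn_tie_broken_by_lower_index():
    # isoceles: residues 1 and 2 equidistant from residue 0
    s = ProteinStructure(
        residues=[
            make_residue([[0, 0, 0]], 0),
            make_residue([[1, 0, 0]], 1),
            make_residue([[-1, 0, 0]], 2),
        ],
        source_id="tie",
    )
    g = build_knn_graph(s, k=1)
    assert g.edges[g.edges[:, 1] == 0][:, 0].tolist() == [1]


def test_knn_complete_when_k_large():
    s = line_structure([0.0, 1.0, 2.5, 4.0])
    g = build_knn_graph(s, k=10)
    assert g.n_edges == 4 * 3


def test_knn_requires_two_residues():
    with pytest.raises(GraphError):
        build_knn_graph(line_structure([0.0]), k=1)


def test_edge_feature_ranges(fixture_complex):
    for structure in fixture_complex[:2]:
        g = build_knn_graph(structure, k=5)
        d, theta = g.edge_features[:, 0], g.edge_features[:, 1]
        assert (d > 0).all()
        assert ((theta >= 0) & (theta <= np.pi / 2 + 1e-12)).all()
        assert np.isfinite(g.edge_features).all()


# -- interaction labels -----------------------------------------------------

def _two_residue_structures(distance, element="C"):
    lig = ProteinStructure([make_residue([[0, 0, 0]], 0)], source_id="l")
    rec = ProteinStructure(
        [ResidueRecord(aa_code="G", chain_id="B", seq_index=0, atoms=[
            AtomRecord(name="C", element=element, coords=[distance, 0, 0])])],
        source_id="r",
    )
    return lig, rec


@pytest.mark.parametrize("distance, expected", [(5.9, 1), (6.0, 1), (6.1, 0)])
def test_label_flips_at_cutoff(distance, expected):
    lig, rec = _two_residue_structures(distance)
    assert label_interactions(lig, rec, 6.0).matrix[0, 0] == expected


def test_hydrogens_do_not_create_contacts():
    lig = ProteinStructure([make_residue([[0, 0, 0]], 0)], source_id="l")
    rec = ProteinStructure(
        [ResidueRecord(aa_code="G", chain_id="B", seq_index=0, atoms=[
            AtomRecord(name="H", element="H", coords=[2, 0, 0]),
            AtomRecord(name="C", element="C", coords=[8, 0, 0])])],
        source_id="r",
    )
    assert label_interactions(lig, rec, 6.0).matrix[0, 0] == 0


def test_hydrogen_only_residue_warned_and_zero():
    lig = ProteinStructure([make_residue([[0, 0, 0]], 0)], source_id="l")
    rec = ProteinStructure(
        [ResidueRecord(aa_code="G", chain_id="B", seq_index=0, atoms=[
            AtomRecord(name="H", element="H", coords=[1, 0, 0])])],
        source_id="r",
    )
    with pytest.warns(UserWarning):
        labels = label_interactions(lig, rec, 6.0)
    assert labels.matrix[0, 0] == 0


def test_labels_match_brute_force(fixture_complex):
    """Vectorized labeling agrees with an explicit atom-pair double loop."""
    ligand, receptor, _ = fixture_complex
    labels = label_interactions(ligand, receptor, 6.0)
    for i, rl in enumerate(ligand.residues):
        for j, rr in enumerate(receptor.residues):
            dmin = min(
                float(np.linalg.norm(a.coords - b.coords))
                for a in rl.heavy_atoms() for b in rr.heavy_atoms()
            )
            assert labels.matrix[i, j] == (1 if dmin <= 6.0 else 0)


def test_interface_labels():
    m = np.zeros((4, 6), dtype=int)
    assert all(v.sum() == 0 for v in interface_labels(PairLabels(m, 6.0)))
    m[2, 5] = 1
    lig, rec = interface_labels(PairLabels(m, 6.0))
    assert lig.tolist() == [0, 0, 1, 0]
    assert rec.tolist() == [0, 0, 0, 0, 0, 1]
    assert lig.sum() <= (m.any(axis=1)).sum()


# -- standardization and tabular export ------------------------------------

def test_standardize_edge_features(fixture_complex):
    graphs = [build_knn_graph(s, k=4) for s in fixture_complex[:2]]
    std, stats = standardize_edge_features(graphs)
    pooled = np.concatenate([g.edge_features for g in std])
    assert np.abs(pooled.mean(axis=0)).max() < 1e-10
    # reusing stored stats reproduces the same transform
    again, _ = standardize_edge_features(graphs, stats)
    assert np.array_equal(again[0].edge_features, std[0].edge_features)


def test_standardize_zero_variance_channel():
    s = line_structure([0.0, 1.0])
    g = build_knn_graph(s, k=1)  # two edges, identical (D, θ)
    with pytest.warns(UserWarning):
        std, stats = standardize_edge_features([g])
    assert np.allclose(std[0].edge_features, 0.0)
    assert (stats.scale == 1.0).all()


def test_graph_tsv_round_trip(fixture_complex, tmp_path):
    ligand = fixture_complex[0]
    g = build_knn_graph(ligand, k=3)
    write_graph_tsv(g, ligand, tmp_path)
    back = read_graph_tsv(tmp_path, k=3)
    assert back.n_nodes == g.n_nodes
    assert np.array_equal(back.edges, g.edges)
    assert np.allclose(back.edge_features, g.edge_features, atol=1e-6)
    assert back.degenerate_nodes == g.degenerate_nodes
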