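import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from muse.graph_io import (
    DEFAULT_RESIDUE_TABLE,
    MolecularGraph,
    build_contact_graph,
    build_knn_graph,
    featurize_residues,
    molecular_graph_from_line_notation,
    parse_structure_chain,
    read_graph_interchange,
    read_interaction_table,
    write_graph_interchange,
)


def write_table(tmp_path, rows, name="net.tsv"):
    path = tmp_path / name
    path.write_text("".join("\t".join(r) + "\n" for r in rows))
    return path


class TestInteractionTable:
    def test_direct_construction(self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", "P2", "1"),
            ("P2", "P3", "1"),
            ("P3", "P4", "0"),
        ])
        net = read_interaction_table(path)
        assert net.n_entities == 4
        assert len(net.links) == 3
        assert all(l.status == "observed" for l in net.links)
        assert net.entity_ids == ["P1", "P2", "P3", "P4"]

    def test_self_pair_rejected(self, tmp_path):
        path = write_table(tmp_path, [("P1", "P1", "1")])
        with pytest.raises(ValueError, match="self-interaction"):
            read_interaction_table(path)

    def test_duplicate_pair_deduplicated(self, tmp_path):
        rows = [
            ("P1", "P2", "1"),
            ("P2", "P3", "1"),
            ("P2", "P1", "1"),  # same pair, reversed order
        ]
        path = write_table(tmp_path, rows)
        net = read_interaction_table(path)
        # oracle: set of canonical pairs from the raw row list
        ids = {}
        for a, b, _ in rows:
            for x in (a, b):
                ids.setdefault(x, len(ids))
        oracle = {tuple(sorted((ids[a], ids[b]))) for a, b, _ in rows}
        assert {l.pair for l in net.links} == oracle
        assert len(net.links) == 2

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = write_table(tmp_path, [("P1", "P2", "1"), ("P2", "P1", "0")])
        with pytest.raises(ValueError, match="conflicting"):
            read_interaction_table(path)

    def test_unknown_label_reports_row(self, tmp_path):
        path = write_table(tmp_path, [("P1", "P2", "maybe")])
        with pytest.raises(ValueError, match=":1:"):
            read_interaction_table(path)

    def test_status_column(self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", "P2", "1", "observed"),
            ("P1", "P3", "1", "unobserved"),
        ])
        net = read_interaction_table(path)
        assert [l.status for l in net.links] == ["observed", "unobserved"]

    def test_multilabel(self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", "P2", "binding,activation"),
            ("P1", "P3", "binding"),
        ])
        net = read_interaction_table(path, label_space="multilabel")
        assert net.n_classes == 2
        np.testing.assert_array_equal(net.links[0].label, [1.0, 1.0])
        np.testing.assert_array_equal(net.links[1].label, [1.0, 0.0])

    def test_adjacency_symmetric_zero_diagonal(self, tmp_path):
        path = write_table(tmp_path, [
            ("A", "B", "1"), ("B", "C", "1"), ("A", "C", "1"),
        ])
        net = read_interaction_table(path)
        a = net.adjacency()
        np.testing.assert_array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)


class TestStructureChain:
    def test_roundtrip(self, tiny_pdb):
        seq, coords = parse_structure_chain(tiny_pdb, "A")
        assert seq == "AGS"
        assert coords.shape == (3, 3)
        np.testing.assert_allclose(coords[0], [1.0, 0.0, 0.0])

    def test_missing_ca_dropped(self, tmp_path, caplog):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  N   GLY A   2       3.000   0.000   0.000  1.00  0.00           N",
            "ATOM      3  CA  SER A   3       7.000   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "gap.pdb"
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            seq, coords = parse_structure_chain(path, "A")
        assert seq == "AS"
        assert coords.shape == (2, 3)
        assert any("no CA" in r.message for r in caplog.records)

    def test_missing_chain_lists_available(self, tiny_pdb):
        with pytest.raises(ValueError, match="available.*A"):
            parse_structure_chain(tiny_pdb, "Z")


class TestContactGraph:
    def test_threshold_semantics(self):
        near = np.array([[0, 0, 0], [9.5, 0, 0]], dtype=float)
        far = np.array([[0, 0, 0], [10.5, 0, 0]], dtype=float)
        assert build_contact_graph("AG", near).n_edges == 1
        assert build_contact_graph("AG", far).n_edges == 0
        # boundary: exactly 10 is excluded (strict <)
        boundary = np.array([[0, 0, 0], [10.0, 0, 0]], dtype=float)
        assert build_contact_graph("AG", boundary).n_edges == 0

    def test_single_residue(self):
        g = build_contact_graph("A", np.zeros((1, 3)))
        assert g.n_edges == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_contact_graph("", np.zeros((0, 3)))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 51))
            coords = rng.uniform(0, 30, size=(L, 3))
            g = build_contact_graph("A" * L, coords)
            dist = squareform(pdist(coords))
            oracle = {
                (i, j)
                for i in range(L) for j in range(i + 1, L)
                if dist[i, j] < 10.0
            }
            assert {tuple(e) for e in g.edges.tolist()} == oracle


class TestKnnGraph:
    def test_collinear_geometry(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        edges = build_knn_graph(coords, k=1)
        nbrs = {i: set() for i in range(3)}
        for src, dst in edges.tolist():
            nbrs[dst].add(src)
        assert nbrs[0] == {1}
        assert nbrs[2] == {1}
        # middle point ties between the two endpoints: lower index wins
        assert nbrs[1] == {0}

    def test_complete_graph(self, rng):
        coords = rng.normal(size=(6, 3))
        edges = build_knn_graph(coords, k=5)
        assert edges.shape == (30, 2)

    def test_k_validation(self, rng):
        coords = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            build_knn_graph(coords, k=0)
        with pytest.raises(ValueError):
            build_knn_graph(coords, k=5)

    def test_matches_bruteforce_sort_oracle(self, rng):
        coords = rng.uniform(0, 10, size=(30, 3))
        k = 5
        edges = build_knn_graph(coords, k)
        dist = cdist(coords, coords)
        for i in range(30):
            got = {src for src, dst in edges.tolist() if dst == i}
            row = [(dist[i, j], j) for j in range(30) if j != i]
            row.sort()
            expected = {j for _, j in row[:k]}
            assert got == expected


class TestResidueFeatures:
    def test_identical_rows(self):
        feats = featurize_residues("AAA")
        assert feats.shape == (3, 7)
        np.testing.assert_array_equal(feats[0], feats[1])
        np.testing.assert_array_equal(feats[1], feats[2])

    def test_nonstandard_zero_row(self):
        with pytest.warns(UserWarning, match="non-standard"):
            feats = featurize_residues("AXA")
        np.testing.assert_array_equal(feats[1], np.zeros(7))
        assert not np.all(feats[0] == 0)

    def test_shape(self, rng):
        seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=25))
        assert featurize_residues(seq).shape == (25, 7)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            featurize_residues("")

    def test_all_twenty_present(self):
        for aa in "ARNDCQEGHILKMFPSTWYV":
            assert aa in DEFAULT_RESIDUE_TABLE


class TestSmiles:
    def test_methane(self):
        g = molecular_graph_from_line_notation("C")
        assert g.n_nodes == 1
        assert g.n_edges == 0

    def test_ethanol(self):
        g = molecular_graph_from_line_notation("CCO")
        assert g.n_nodes == 3
        assert g.n_edges == 2

    def test_benzene_aromatic(self):
        g = molecular_graph_from_line_notation("c1ccccc1")
        assert g.n_nodes == 6
        assert g.n_edges == 6
        # aromaticity flag is the last node-feature column
        assert np.all(g.node_features[:, -1] == 1.0)
        # all bonds aromatic
        assert np.all(g.edge_features[:, -1] == 1.0)

    def test_unparseable(self):
        with pytest.raises(ValueError, match="not-a-smiles"):
            molecular_graph_from_line_notation("not-a-smiles")


class TestGraphInterchange:
    def make_graph(self, rng, with_coords=True):
        n = int(rng.integers(2, 12))
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.4
        ]
        return MolecularGraph(
            entity_id="G1",
            entity_kind="generic",
            node_features=rng.normal(size=(n, 5)),
            edges=np.array(edges).reshape(-1, 2),
            coords=rng.normal(size=(n, 3)) if with_coords else None,
        )

    def test_roundtrip(self, tmp_path, rng):
        for _ in range(10):
            g = self.make_graph(rng)
            path = tmp_path / "g.json"
            write_graph_interchange(g, path)
            g2 = read_graph_interchange(path)
            assert g2.entity_id == g.entity_id
            assert g2.entity_kind == g.entity_kind
            np.testing.assert_array_equal(g2.node_features, g.node_features)
            np.testing.assert_array_equal(g2.edges, g.edges)
            np.testing.assert_array_equal(g2.coords, g.coords)

    def test_reserialization_identical(self, tmp_path, rng):
        g = self.make_graph(rng)
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        write_graph_interchange(g, p1)
        write_graph_interchange(read_graph_interchange(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_edges_key(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"schema": "muse-graph/1", "entity_id": "x", '
            '"entity_kind": "generic", "node_features": [[0.0]]}'
        )
        with pytest.raises(ValueError, match="edges"):
            read_graph_interchange(path)

    def test_schema_mismatch(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "muse-graph/99"}')
        with pytest.raises(ValueError, match="schema version"):
            read_graph_interchange(path)

    def test_coords_full_precision(self, tmp_path, rng):
        g = self.make_graph(rng, with_coords=True)
        path = tmp_path / "g.json"
        write_graph_interchange(g, path)
        g2 = read_graph_interchange(path)
        assert np.all(g2.coords == g.coords)


class TestMolecularGraphInvariants:
    def test_edge_canonicalization(self):
        g = MolecularGraph(
            entity_id="g", entity_kind="generic",
            node_features=np.zeros((3, 2)),
            edges=[(2, 0), (0, 2), (1, 0)],
        )
        np.testing.assert_array_equal(g.edges, [[0, 1], [0, 2]])

    def test_out_of_range_edge(self):
        with pytest.raises(ValueError, match="out of range"):
            MolecularGraph(
                entity_id="g", entity_kind="generic",
                node_features=np.zeros((2, 2)), edges=[(0, 5)],
            )

    def test_coords_shape_checked(self):
        with pytest.raises(ValueError, match="coords"):
            MolecularGraph(
                entity_id="g", entity_kind="generic",
                node_features=np.zeros((3, 2)), edges=[],
                coords=np.zeros((2, 3)),
            )
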