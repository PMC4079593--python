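"""Haplotype collapsing and median-joining network construction."""

import numpy as np
import pytest

from mthapnet.errors import InputError
from mthapnet.mjnet import (
    HaplotypeCluster,
    _feasible_links,
    build_mj_network,
    collapse_haplotypes,
    weighted_distance,
)
from mthapnet.oracle import steiner_minimal_length
from mthapnet.refcoords import HaplotypeAlignment, RefPosition
from mthapnet.synthdata import random_haplotype_vectors


def clusters_of(vectors):
    return [
        HaplotypeCluster(f"H{i}", [f"H{i}"], tuple(v))
        for i, v in enumerate(vectors)
    ]


class TestCollapse:
    def make_aln(self, rows, labels=None):
        labels = labels or [f"s{i}" for i in range(len(rows))]
        colmap = [RefPosition(i + 1) for i in range(len(rows[0]))]
        return HaplotypeAlignment(labels=labels, rows=rows, colmap=colmap)

    def test_identical_sequences_merge(self):
        aln = self.make_aln(["ACGT", "ACGT", "ACTT"])
        clusters, _ = collapse_haplotypes(aln)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 2]

    def test_all_distinct(self):
        aln = self.make_aln(["ACGT", "ACGA", "ACTT"])
        clusters, _ = collapse_haplotypes(aln)
        assert len(clusters) == 3

    def test_partition_covers_input(self):
        aln = self.make_aln(["ACGT", "ACGT", "ACTT", "GCGT", "ACTT"])
        clusters, _ = collapse_haplotypes(aln)
        members = sorted(m for c in clusters for m in c.members)
        assert members == sorted(aln.labels)

    def test_permissive_missing_merges(self):
        aln = self.make_aln(["ACGT", "ACNT", "ACTT"])
        clusters, _ = collapse_haplotypes(aln, missing="permissive")
        # the N sequence is compatible with the first haplotype
        assert len(clusters) == 2
        strict, _ = collapse_haplotypes(aln, missing="strict")
        assert len(strict) == 3

    def test_variable_positions_reported(self):
        aln = self.make_aln(["ACGT", "ACGA", "TCGA"])
        _, positions = collapse_haplotypes(aln)
        assert positions == [RefPosition(1), RefPosition(4)]

    def test_empty_alignment_rejected(self):
        with pytest.raises(InputError):
            collapse_haplotypes(
                HaplotypeAlignment(labels=[], rows=[], colmap=[])
            )


class TestWeightedDistance:
    def test_identity(self):
        assert weighted_distance("ACGT", "ACGT", [1, 2, 3, 4]) == 0

    def test_weighted(self):
        assert weighted_distance("AA", "GG", [2, 1]) == 3

    def test_missing_contributes_zero(self):
        assert weighted_distance("AN", "GA", [5, 5]) == 5

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            weighted_distance("AC", "A", [1, 1])


class TestBuildNetwork:
    def test_two_clusters_single_edge(self):
        cl = clusters_of(["ACA", "GCG"])
        net = build_mj_network(cl, [1, 1, 1])
        assert net.graph.number_of_edges() == 1
        assert net.edge_labels("H0", "H1") == (RefPosition(1), RefPosition(3))
        assert net.median_nodes == []

    def test_three_haplotype_star(self):
        """GAA/AGA/AAG resolves to one central median and three unit
        branches of total length 3."""
        cl = clusters_of(["GAA", "AGA", "AAG"])
        net = build_mj_network(cl, [1, 1, 1])
        assert len(net.median_nodes) == 1
        (mv,) = net.median_nodes
        assert net.node_vector(mv) == ("A", "A", "A")
        assert net.spanning_length() == 3
        assert steiner_minimal_length(["GAA", "AGA", "AAG"]) == 3

    def test_single_cluster_rejected(self):
        with pytest.raises(InputError):
            build_mj_network(clusters_of(["ACGT"]), [1] * 4)

    def test_edge_labels_equal_vector_differences(self):
        vecs = random_haplotype_vectors(seed=5)
        net = build_mj_network(clusters_of(vecs), [1] * len(vecs[0]))
        for u, v, d in net.graph.edges(data=True):
            diff = tuple(
                p for p, a, b in zip(
                    net.positions, net.node_vector(u), net.node_vector(v)
                ) if a != b
            )
            assert d["labels"] == diff
            assert d["length"] == len(diff)

    def test_connected_and_observed_present(self):
        import networkx as nx

        vecs = random_haplotype_vectors(seed=6)
        net = build_mj_network(clusters_of(vecs), [1] * len(vecs[0]))
        assert nx.is_connected(net.graph)
        assert set(net.observed_nodes) == {f"H{i}" for i in range(len(vecs))}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_steiner(self, seed):
        """The network's tree length equals the exact minimal Steiner
        length on small random instances."""
        vecs = random_haplotype_vectors(seed=seed)
        if len(vecs) < 2:
            pytest.skip("degenerate draw")
        net = build_mj_network(clusters_of(vecs), [1] * len(vecs[0]))
        assert net.spanning_length() == steiner_minimal_length(vecs)

    def test_medians_only_help(self):
        """Re-linking observed clusters by plain MST never beats the
        network's tree length."""
        from scipy.sparse.csgraph import minimum_spanning_tree

        vecs = random_haplotype_vectors(seed=17)
        w = [1] * len(vecs[0])
        net = build_mj_network(clusters_of(vecs), w)
        n = len(vecs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = weighted_distance(vecs[i], vecs[j], w)
        mst_len = int(round(minimum_spanning_tree(D).sum()))
        assert net.spanning_length() <= mst_len

    def test_determinism(self):
        vecs = random_haplotype_vectors(seed=23)
        cl = clusters_of(vecs)
        w = [1] * len(vecs[0])
        a = build_mj_network(cl, w)
        b = build_mj_network(cl, w)
        assert a.to_node_table().equals(b.to_node_table())
        assert a.to_edge_table().equals(b.to_edge_table())

    @pytest.mark.parametrize("seed", [2, 9, 31])
    def test_epsilon_monotonicity_of_links(self, seed):
        """Raising epsilon never removes a feasible link."""
        from mthapnet.mjnet import _distance_matrix

        vecs = random_haplotype_vectors(seed=seed)
        D = _distance_matrix([tuple(v) for v in vecs], [1] * len(vecs[0]))
        f0 = _feasible_links(D, 0)
        f1 = _feasible_links(D, 1)
        f2 = _feasible_links(D, 2)
        assert (f1 | f0 == f1).all()
        assert (f2 | f1 == f2).all()

    def test_weighted_network_downweights_hotspot(self):
        """A recurrent column with weight 0 is excluded from distances but
        a positive-weight column still separates haplotypes."""
        cl = clusters_of(["AC", "GC", "AT"])
        net = build_mj_network(cl, [0, 1])
        assert weighted_distance("AC", "GC", [0, 1]) == 0
        # zero-weight difference still labels the edge
        assert net.graph.has_edge("H0", "H1")

    def test_multistate_indel_character(self):
        """An indel column with states {absent, T, G} behaves as one
        multistate character: two insertion events label two branches."""
        cl = clusters_of(["-AA", "TAA", "-CC", "GCC"])
        net = build_mj_network(cl, [1, 1, 1], positions=[
            RefPosition(15581, 1), RefPosition(15600), RefPosition(15601),
        ])
        from mthapnet.netstats import mutation_frequencies

        ft = mutation_frequencies(net)
        assert ft.get(RefPosition(15581, 1)) == 2

    def test_graphml_export(self, tmp_path):
        import networkx as nx

        cl = clusters_of(["GAA", "AGA", "AAG"])
        net = build_mj_network(cl, [1, 1, 1])
        p = tmp_path / "net.graphml"
        net.to_graphml(p)
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == 4
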