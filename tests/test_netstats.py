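"""Mutation frequencies, inverse-frequency weights, motifs and placement."""

import pytest

from mthapnet.errors import InputError, TopologyError
from mthapnet.mjnet import HaplotypeCluster, build_mj_network, collapse_haplotypes
from mthapnet.netstats import (
    cluster_distance_report,
    infer_motif,
    inverse_frequency_weights,
    mutation_frequencies,
    FrequencyTable,
)
from mthapnet.refcoords import RefPosition, apply_gap_policy
from mthapnet.synthdata import HaploSimConfig, simulate_haplotypes


def clusters_of(vectors):
    return [
        HaplotypeCluster(f"H{i}", [f"H{i}"], tuple(v))
        for i, v in enumerate(vectors)
    ]


@pytest.fixture(scope="module")
def planted_network():
    """Three star haplogroups joined to a sampled ancestor, one triple
    hotspot, one whitelisted indel column."""
    cfg = HaploSimConfig(
        n_haplogroups=3, star_size=4, stem_length=3, n_hotspots=1,
        hotspot_recurrence=3, indel_column=True, seed=7,
    )
    aln, truth = simulate_haplotypes(cfg)
    aln, _ = apply_gap_policy(aln, [truth["indel_position"]])
    clusters, positions = collapse_haplotypes(aln)
    net = build_mj_network(clusters, [1] * len(positions), 0, positions)
    return net, clusters, truth


class TestFrequencies:
    def test_single_edge(self):
        net = build_mj_network(
            clusters_of(["AC", "GT"]), [1, 1],
            positions=[RefPosition(5), RefPosition(9)],
        )
        ft = mutation_frequencies(net)
        assert ft.counts == {RefPosition(5): 1, RefPosition(9): 1}
        assert sorted(map(str, ft.hotspots)) == ["5", "9"]

    def test_conservation(self, planted_network):
        net, _, _ = planted_network
        ft = mutation_frequencies(net)
        total_labels = sum(
            len(d["labels"]) for _, _, d in net.graph.edges(data=True)
        )
        assert ft.total == total_labels
        assert all(c >= 1 for c in ft.counts.values())

    def test_planted_hotspot_recovered(self, planted_network):
        net, _, truth = planted_network
        ft = mutation_frequencies(net)
        (pos, recurrence), = [tuple(h) for h in truth["hotspots"]]
        assert ft.get(RefPosition.parse(pos)) == recurrence
        assert [str(p) for p in ft.hotspots] == [pos]

    def test_relabeling_invariance(self, planted_network):
        """Hotspot detection does not depend on node names."""
        import networkx as nx

        net, _, _ = planted_network
        mapping = {n: f"x{i}" for i, n in enumerate(sorted(net.graph.nodes))}
        relabeled = net.graph.__class__(nx.relabel_nodes(net.graph, mapping))
        counts = {}
        for _, _, d in relabeled.edges(data=True):
            for p in d["labels"]:
                counts[p] = counts.get(p, 0) + 1
        assert counts == mutation_frequencies(net).counts


class TestInverseFrequencyWeights:
    @pytest.mark.parametrize("f,expected", [(1, 10), (2, 5), (3, 3), (10, 1), (100, 1)])
    def test_mapping(self, f, expected):
        ft = FrequencyTable({RefPosition(7): f})
        assert inverse_frequency_weights(ft, 10)[RefPosition(7)] == expected

    def test_uniform_frequencies_uniform_weights(self):
        ft = FrequencyTable({RefPosition(p): 2 for p in (1, 2, 3)})
        w = inverse_frequency_weights(ft, 10)
        assert set(w.values()) == {5}

    def test_unobserved_positions_get_full_scale(self):
        ft = FrequencyTable({RefPosition(1): 5})
        w = inverse_frequency_weights(ft, 10, positions=[RefPosition(1), RefPosition(2)])
        assert w[RefPosition(2)] == 10

    def test_invalid_scale(self):
        with pytest.raises(InputError):
            inverse_frequency_weights(FrequencyTable({}), 0)

    def test_two_pass_downweights_hotspots(self, planted_network):
        net, _, truth = planted_network
        ft = mutation_frequencies(net)
        w = inverse_frequency_weights(ft, 10)
        hotspot = RefPosition.parse(truth["hotspots"][0][0])
        stem = RefPosition.parse(truth["stems"]["HG0"][0])
        assert w[hotspot] < w[stem]
        assert w[stem] == 10


class TestInferMotif:
    def test_planted_stems_recovered(self, planted_network):
        net, clusters, truth = planted_network
        ft = mutation_frequencies(net)
        for hg, stem in truth["stems"].items():
            nodes = {
                c.cluster_id for c in clusters
                if any(m.startswith(hg) for m in c.members)
            }
            rep = infer_motif(net, ft, nodes, haplogroup=hg)
            assert [str(p) for p in rep.motif] == stem
            assert rep.ancestor_candidate == "ANC"

    def test_recurrent_position_excluded_from_motif(self, planted_network):
        net, clusters, truth = planted_network
        ft = mutation_frequencies(net)
        hotspot = RefPosition.parse(truth["hotspots"][0][0])
        for hg in truth["stems"]:
            nodes = {
                c.cluster_id for c in clusters
                if any(m.startswith(hg) for m in c.members)
            }
            rep = infer_motif(net, ft, nodes, haplogroup=hg)
            assert hotspot not in rep.motif
            assert all(ft.get(p) == 1 for p in rep.motif)

    def test_non_separable_set_refused(self, planted_network):
        """Members scattered across two haplogroups cannot be separated by
        one stem cut."""
        net, clusters, _ = planted_network
        ft = mutation_frequencies(net)
        nodes = {
            c.cluster_id for c in clusters
            if c.cluster_id in ("HG0_F", "HG2_F")
        }
        with pytest.raises(TopologyError):
            infer_motif(net, ft, nodes)

    def test_unknown_node(self, planted_network):
        net, _, _ = planted_network
        with pytest.raises(InputError):
            infer_motif(net, mutation_frequencies(net), {"nope"})


class TestClusterDistance:
    def test_adjacent_nodes(self):
        net = build_mj_network(
            clusters_of(["AC", "GT"]), [1, 1],
            positions=[RefPosition(5), RefPosition(9)],
        )
        rep = cluster_distance_report(net, "H0", "H1")
        assert rep["total_label_count"] == 2
        assert rep["branches"][0]["labels"] == ["5", "9"]

    def test_chain_of_unit_edges(self):
        net = build_mj_network(
            clusters_of(["AAA", "GAA", "GCA", "GCT"]), [1, 1, 1]
        )
        rep = cluster_distance_report(net, "H0", "H3")
        assert rep["total_weighted_length"] == 3
        assert rep["total_label_count"] == 3
        assert rep["path"][0] == "H0" and rep["path"][-1] == "H3"

    def test_unknown_node(self):
        net = build_mj_network(clusters_of(["AC", "GT"]), [1, 1])
        with pytest.raises(InputError):
            cluster_distance_report(net, "H0", "missing")
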