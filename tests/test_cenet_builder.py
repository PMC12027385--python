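"""Network expansion, polarity filtering and Cytoscape export."""

import random

import pytest

from cenet import (
    CeNET,
    Edge,
    InteractionRecord,
    SeedSet,
    UsageError,
    apply_cerna_filter,
    build_whole_genome_net,
    export_network,
    read_graphml_network,
)

from conftest import make_de


def _random_interactions(rng, n, n_mirna=15, n_target=40):
    # each target carries one RNA class, derived from its index
    classes = ("mRNA", "lncRNA", "circRNA")
    seen = set()
    records = []
    while len(records) < n:
        t = rng.randrange(n_target)
        pair = (f"miR-{rng.randrange(n_mirna)}", f"T{t}")
        if pair in seen:
            continue
        seen.add(pair)
        records.append(InteractionRecord(
            pair[0], pair[1], classes[t % 3], rng.randrange(1, 11)))
    return records


class TestBuildWholeGenomeNet:
    def test_edge_count_matches_linear_scan(self):
        rng = random.Random(11)
        interactions = _random_interactions(rng, 2000, n_mirna=40, n_target=200)
        seeds = SeedSet("6m", "up", tuple(f"miR-{i}" for i in range(0, 40, 3)))
        net = build_whole_genome_net(seeds, interactions)
        expected = [r for r in interactions if r.mirna_id in seeds.members]
        assert len(net.edges) == len(expected)
        assert {(e.mirna_id, e.target_id) for e in net.edges} == \
            {(r.mirna_id, r.target_id) for r in expected}
        assert net.polarity == "DOWN"

    def test_seed_without_interactions_lands_in_missing(self):
        seeds = SeedSet("6m", "up", ("miR-0", "miR-ghost"))
        interactions = [InteractionRecord("miR-0", "T0", "mRNA", 1)]
        net = build_whole_genome_net(seeds, interactions)
        assert net.missing_seeds == ("miR-ghost",)

    def test_empty_interaction_table(self):
        seeds = SeedSet("6m", "down", ("miR-0", "miR-1"))
        net = build_whole_genome_net(seeds, [])
        assert net.edges == () and net.missing_seeds == ("miR-0", "miR-1")

    def test_empty_seed_set_warns_not_raises(self, caplog):
        net = build_whole_genome_net(
            SeedSet("6m", "up", ()), [InteractionRecord("m", "t", "mRNA", 1)])
        assert net.edges == ()

    def test_clip_support_threshold(self):
        seeds = SeedSet("6m", "up", ("miR-0",))
        interactions = [InteractionRecord("miR-0", "T0", "mRNA", 1),
                        InteractionRecord("miR-0", "T1", "mRNA", 5)]
        net = build_whole_genome_net(seeds, interactions, clip_support_min=3)
        assert [e.target_id for e in net.edges] == ["T1"]


class TestApplyCernaFilter:
    def _net(self, polarity="UP", targets=("A", "B", "C")):
        edges = tuple(Edge("miR-X", t, "mRNA", 2) for t in targets)
        return CeNET(stage="6m", polarity=polarity,
                     seed_members=("miR-X",), edges=edges)

    def test_polarity_rule_on_three_target_fixture(self):
        """A down-miRNA seed (UP network) with targets A up, B down,
        C absent keeps only the edge to A."""
        net = self._net("UP")
        cerna = [make_de("A", "up", rna_class="mRNA"),
                 make_de("B", "down", rna_class="mRNA")]
        filtered = apply_cerna_filter(net, cerna)
        assert [(e.mirna_id, e.target_id) for e in filtered.edges] == \
            [("miR-X", "A")]
        assert filtered.edges[0].target_direction == "up"

    def test_no_matching_de_record_empties_network(self):
        filtered = apply_cerna_filter(self._net(), [])
        assert filtered.edges == ()
        assert filtered.filtered_out_seeds == ("miR-X",)

    def test_matches_bruteforce_filter_on_random_networks(self):
        """Random nets (100 targets): retained edges equal a brute
        force scan over edges x DE directions."""
        rng = random.Random(17)
        for _ in range(20):
            interactions = _random_interactions(rng, 300, n_mirna=10,
                                                n_target=100)
            direction = rng.choice(["up", "down"])
            seeds = SeedSet("6m", direction,
                            tuple(sorted({r.mirna_id for r in
                                          interactions})[:5]))
            net = build_whole_genome_net(seeds, interactions)
            class_of = {}
            for r in interactions:
                class_of.setdefault(r.target_id, r.target_class)
            de = [make_de(t, rng.choice(["up", "down", "ns"]),
                          rna_class=class_of[t])
                  for t in sorted(class_of) if rng.random() < 0.8]
            filtered = apply_cerna_filter(net, de)
            want_dir = "down" if direction == "up" else "up"
            de_dir = {(r.feature_id, r.rna_class): r.direction for r in de}
            expected = {(e.mirna_id, e.target_id) for e in net.edges
                        if de_dir.get((e.target_id, e.target_class))
                        == want_dir}
            assert {(e.mirna_id, e.target_id)
                    for e in filtered.edges} == expected

    def test_filtering_is_anti_monotone(self):
        rng = random.Random(23)
        interactions = _random_interactions(rng, 200)
        seeds = SeedSet("6m", "up", tuple(f"miR-{i}" for i in range(15)))
        net = build_whole_genome_net(seeds, interactions)
        de = [make_de(f"T{i}", rng.choice(["up", "down"]), rna_class="mRNA")
              for i in range(40)]
        filtered = apply_cerna_filter(net, de)
        assert set(e.key for e in filtered.edges) <= \
            set(e.key for e in net.edges)
        assert set(filtered.nodes) <= set(net.nodes)

    def test_seed_partition_after_filter(self):
        """missing ∪ degree-0-after-filter ∪ retained partitions the
        seed set."""
        seeds = SeedSet("6m", "up", ("miR-0", "miR-1", "miR-2"))
        interactions = [InteractionRecord("miR-0", "A", "mRNA", 1),
                        InteractionRecord("miR-1", "B", "mRNA", 1)]
        de = [make_de("A", "down", rna_class="mRNA"),
              make_de("B", "up", rna_class="mRNA")]
        net = apply_cerna_filter(build_whole_genome_net(seeds, interactions),
                                 de)
        retained = set(net.mirna_nodes)
        parts = [set(net.missing_seeds), set(net.filtered_out_seeds), retained]
        assert set().union(*parts) == set(seeds.members)
        assert sum(len(p) for p in parts) == len(seeds.members)
        assert net.missing_seeds == ("miR-2",)
        assert net.filtered_out_seeds == ("miR-1",)

    def test_target_matched_by_id_and_class(self):
        """A symbol present in two class tables matches the record of
        the interaction's class."""
        net = CeNET(stage="6m", polarity="UP", seed_members=("miR-X",),
                    edges=(Edge("miR-X", "Dual", "lncRNA", 1),))
        de = [make_de("Dual", "down", rna_class="mRNA"),
              make_de("Dual", "up", rna_class="lncRNA")]
        filtered = apply_cerna_filter(net, de)
        assert len(filtered.edges) == 1  # lncRNA record (up) wins

    def test_class_conflict_logged_interaction_class_wins(self, caplog):
        net = CeNET(stage="6m", polarity="UP", seed_members=("miR-X",),
                    edges=(Edge("miR-X", "A", "circRNA", 1),))
        de = [make_de("A", "up", rna_class="mRNA")]
        with caplog.at_level("WARNING", logger="cenet.cenet_builder"):
            filtered = apply_cerna_filter(net, de)
        assert len(filtered.edges) == 1
        assert filtered.edges[0].target_class == "circRNA"
        assert any("conflicts" in m for m in caplog.messages)


class TestExport:
    def _fixture_net(self):
        return CeNET(
            stage="6m", polarity="UP", seed_members=("miR-1", "miR-2"),
            edges=(Edge("miR-2", "GeneB", "lncRNA", 3, "up"),
                   Edge("miR-1", "GeneA", "mRNA", 5, "up")),
            filtered=True)

    def test_sif_lines_sorted_with_relation_label(self, tmp_path):
        p = export_network(self._fixture_net(), "SIF", tmp_path / "n.sif")
        assert p.read_text().splitlines() == [
            "miR-1\tcerna_of\tGeneA",
            "miR-2\tcerna_of\tGeneB",
        ]

    def test_unknown_format_is_usage_error(self, tmp_path):
        with pytest.raises(UsageError, match="format"):
            export_network(self._fixture_net(), "XGMML", tmp_path / "x")

    def test_empty_network_exports_valid_empty_file(self, tmp_path):
        empty = CeNET(stage="6m", polarity="UP", seed_members=(), edges=())
        p = export_network(empty, "SIF", tmp_path / "e.sif")
        assert p.read_text() == ""
        p2 = export_network(empty, "TSV", tmp_path / "e.tsv")
        assert len(p2.read_text().splitlines()) == 1  # header only

    def test_graphml_round_trip_preserves_nodes_and_edges(self, tmp_path):
        net = self._fixture_net()
        p = export_network(net, "GraphML", tmp_path / "n.graphml")
        back = read_graphml_network(p)
        assert set(back.nodes) == set(net.nodes)
        assert {(e.mirna_id, e.target_id, e.clip_support)
                for e in back.edges} == \
            {(e.mirna_id, e.target_id, e.clip_support) for e in net.edges}
        assert (back.stage, back.polarity) == (net.stage, net.polarity)

    def test_tsv_carries_attributes(self, tmp_path):
        p = export_network(self._fixture_net(), "TSV", tmp_path / "n.tsv")
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == ["mirna_id", "target_id",
                                        "target_class", "target_direction",
                                        "clip_support"]
        assert lines[1].split("\t") == ["miR-1", "GeneA", "mRNA", "up", "5"]

    def test_repeated_export_is_byte_identical(self, tmp_path):
        net = self._fixture_net()
        for fmt, name in (("SIF", "a.sif"), ("GraphML", "a.graphml"),
                          ("TSV", "a.tsv")):
            p1 = export_network(net, fmt, tmp_path / ("1" + name))
            p2 = export_network(net, fmt, tmp_path / ("2" + name))
            assert p1.read_bytes() == p2.read_bytes()
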