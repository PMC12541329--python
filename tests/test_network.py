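"""Score combination, graph construction, subnetworks, MC enrichment."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sfpage.network import (
    CHANNELS,
    PPINetwork,
    build_network,
    combine_scores,
    degree_partition,
    export_network,
    extract_subnetworks,
    mc_age_enrichment,
    read_edge_table,
    reproductive_association,
)
from sfpage.simulate import gen_network


def _edge_row(a, b, **scores):
    row = {"protein1": a, "protein2": b, **dict.fromkeys(CHANNELS, 0.0)}
    row.update(scores)
    return row


class TestCombineScores:
    def test_single_channel_identity(self):
        assert combine_scores({"experiments": 0.9}) == pytest.approx(0.9)

    def test_all_zero_reports_zero_not_prior(self):
        assert combine_scores(dict.fromkeys(CHANNELS, 0.0)) == 0.0

    def test_two_channels_match_stepwise_oracle(self):
        # independent step-by-step evaluation of the prior-removal rule
        prior, s = 0.041, 0.6
        s_nop = (s - prior) / (1 - prior)
        total_nop = 1 - (1 - s_nop) ** 2
        expected = total_nop + prior * (1 - total_nop)
        got = combine_scores({"experiments": s, "database": s}, prior=prior)
        assert got == pytest.approx(expected)
        assert got > s  # independent evidence accumulates

    def test_excluded_channel_ignored(self):
        scores = {"experiments": 0.8, "textmining": 0.99}
        with_tm = combine_scores(scores, excluded=())
        without_tm = combine_scores(scores)  # textmining excluded by default
        assert without_tm == pytest.approx(0.8)
        assert with_tm > without_tm

    def test_score_validation(self):
        with pytest.raises(ValueError):
            combine_scores({"experiments": 1.2})
        with pytest.raises(ValueError):
            combine_scores({"not_a_channel": 0.5})

    def test_subprior_evidence_drops_out(self):
        assert combine_scores({"experiments": 0.02}, prior=0.041) == 0.0


class TestBuildNetwork:
    def test_below_threshold_edges_dropped_nodes_kept(self):
        edges = pd.DataFrame([_edge_row("g1", "g2", experiments=0.5)])
        net = build_network(edges, {"g1", "g2", "g3"})
        assert net.n_edges == 0
        assert net.nodes >= {"g1", "g2", "g3"}

    def test_duplicate_orientations_merge(self):
        edges = pd.DataFrame(
            [
                _edge_row("g1", "g2", experiments=0.8),
                _edge_row("g2", "g1", experiments=0.9),
            ]
        )
        net = build_network(edges, {"g1", "g2"})
        assert net.n_edges == 1
        assert net.graph.edges["g1", "g2"]["score"] == pytest.approx(0.9)

    def test_self_loops_dropped_with_warning(self, caplog):
        edges = pd.DataFrame([_edge_row("g1", "g1", experiments=0.9)])
        with caplog.at_level("WARNING"):
            net = build_network(edges, {"g1"})
        assert net.n_edges == 0
        assert any("self-loop" in r.message for r in caplog.records)

    def test_textmining_only_edges_excluded_by_default(self):
        edges = pd.DataFrame([_edge_row("g1", "g2", textmining=0.95)])
        assert build_network(edges, {"g1", "g2"}).n_edges == 0
        assert build_network(edges, {"g1", "g2"}, excluded=()).n_edges == 1

    def test_planted_edge_count_recovered(self):
        bundle = gen_network(
            block_sizes=(6, 5), p_in=0.5, n_nonsfp=10, n_weak=15,
            n_textmining_decoys=10, seed=2,
        )
        net = build_network(bundle.edges, bundle.sfp_ids)
        assert net.n_edges == bundle.truth["n_high_edges"]

    def test_integer_score_dialect_autodetected(self, tmp_path):
        edges = pd.DataFrame(
            [
                {"protein1": "g1", "protein2": "g2",
                 **{c: 0 for c in CHANNELS}, "experiments": 900},
            ]
        )
        p = tmp_path / "edges.tsv"
        edges.to_csv(p, sep="\t", index=False)
        parsed = read_edge_table(p)
        assert parsed["experiments"].iloc[0] == pytest.approx(0.9)


class TestDegreePartition:
    def test_pure_sfp_clique_has_no_outside_degree(self):
        edges = pd.DataFrame(
            [_edge_row(a, b, experiments=0.9) for a, b in [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]]
        )
        deg = degree_partition(build_network(edges, {"g1", "g2", "g3"}))
        assert (deg["k_outside"] == 0).all()
        assert (deg["k_total"] == 2).all()

    def test_isolated_node_all_zero(self):
        net = build_network(pd.DataFrame([_edge_row("g1", "g2", experiments=0.9)]),
                            {"g1", "g2", "g3"})
        assert tuple(degree_partition(net).loc["g3"]) == (0, 0, 0)

    def test_matches_brute_force_recount_on_random_graph(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        sfp = frozenset(n for n in g.nodes if rng.random() < 0.5)
        nx.set_edge_attributes(g, 1.0, "score")
        net = PPINetwork(graph=g, sfp_ids=sfp, threshold=0.7)
        deg = degree_partition(net)
        for gene in sfp:
            nbrs = set(g.neighbors(gene))
            assert deg.loc[gene, "k_total"] == len(nbrs)
            assert deg.loc[gene, "k_within"] == len(nbrs & sfp)
        # conservation: sum k_within = 2 * (# sfp-sfp edges)
        n_within = sum(1 for a, b in g.edges if a in sfp and b in sfp)
        assert deg["k_within"].sum() == 2 * n_within
        assert (deg["k_total"] == deg["k_within"] + deg["k_outside"]).all()


class TestExtractSubnetworks:
    @staticmethod
    def _net_from_components(*comps):
        g = nx.Graph()
        for comp in comps:
            nx.add_path(g, comp)
        nx.set_edge_attributes(g, 1.0, "score")
        sfp = frozenset(g.nodes)
        return PPINetwork(graph=g, sfp_ids=sfp, threshold=0.7)

    def test_small_components_filtered(self):
        net = self._net_from_components(["a", "b", "c"], ["d", "e", "f"])
        assert extract_subnetworks(net, min_size=4) == []

    def test_largest_component_is_core(self):
        net = self._net_from_components(list("abcde"), list("fghi"))
        subs = extract_subnetworks(net, min_size=4)
        assert [s.size for s in subs] == [5, 4]
        assert subs[0].is_core and not subs[1].is_core
        assert sum(s.is_core for s in subs) == 1

    def test_size_tie_broken_lexicographically(self):
        net = self._net_from_components(list("wxyz"), list("abcd"))
        subs = extract_subnetworks(net, min_size=4)
        assert subs[0].members == frozenset("abcd")

    def test_non_sfp_bridges_do_not_merge_components(self):
        g = nx.Graph()
        nx.add_path(g, ["a", "b", "c", "d"])
        nx.add_path(g, ["e", "f", "g", "h"])
        g.add_edges_from([("d", "bridge"), ("bridge", "e")])
        nx.set_edge_attributes(g, 1.0, "score")
        net = PPINetwork(graph=g, sfp_ids=frozenset("abcdefgh"), threshold=0.7)
        assert len(extract_subnetworks(net, min_size=4)) == 2

    def test_planted_blocks_recovered(self):
        bundle = gen_network(block_sizes=(64, 13, 6, 5, 5, 5), p_in=0.2, p_out=0.0,
                             n_nonsfp=30, p_cross=0.02, seed=4)
        net = build_network(bundle.edges, bundle.sfp_ids)
        subs = extract_subnetworks(net, min_size=4)
        assert sorted((s.size for s in subs), reverse=True) == [64, 13, 6, 5, 5, 5]
        assert {frozenset(b) for b in bundle.blocks} == {s.members for s in subs}

    def test_subnetworks_are_disjoint(self, paper_bundle, aged_catalog):
        bundle = paper_bundle["network"]
        net = build_network(bundle.edges, aged_catalog.ids)
        subs = extract_subnetworks(net)
        seen = set()
        for s in subs:
            assert not (s.members & seen)
            seen |= s.members


class TestMCEnrichment:
    def test_subnetwork_equal_to_universe_is_degenerate(self):
        from sfpage.network import Subnetwork

        members = frozenset(f"g{i}" for i in range(8))
        subs = [Subnetwork("S1", members, is_core=True)]
        ages = {g: ("A" if i < 4 else "E") for i, g in enumerate(sorted(members))}
        res = mc_age_enrichment(subs, ages, n_resamples=500, seed=0)
        assert (res["p_enrichment"] == 1.0).all()

    def test_matches_exact_hypergeometric_tail(self):
        from sfpage.network import Subnetwork

        # universe of 10 with 5 class-A genes; subnetwork of 4, all class A
        universe = [f"g{i}" for i in range(10)]
        ages = {g: ("A" if i < 5 else "B") for i, g in enumerate(universe)}
        subs = [Subnetwork("S1", frozenset(universe[:4]), is_core=True)]
        n = 40_000
        res = mc_age_enrichment(subs, ages, universe=universe, n_resamples=n, seed=3)
        p_mc = float(res[(res.age_class == "A")]["p_enrichment"].iloc[0])
        p_exact = 5 / 210  # C(5,4) C(5,0) / C(10,4)
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(p_mc - p_exact) < 3 * se + 1 / (n + 1)

    def test_expected_counts_and_directions(self):
        from sfpage.network import Subnetwork

        universe = [f"g{i}" for i in range(20)]
        ages = {g: ("A" if i < 10 else "E") for i, g in enumerate(universe)}
        subs = [Subnetwork("S1", frozenset(universe[:8]), is_core=True)]
        res = mc_age_enrichment(subs, ages, universe=universe, n_resamples=200, seed=0)
        row_a = res[res.age_class == "A"].iloc[0]
        assert row_a["expected"] == pytest.approx(4.0)
        assert row_a["direction"] == "over"
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()
        assert (res["p_raw"] >= 1 / 201).all()

    def test_bit_reproducible_and_order_invariant(self):
        from sfpage.network import Subnetwork

        universe = [f"g{i}" for i in range(30)]
        ages = {g: "ABC"[i % 3] for i, g in enumerate(universe)}
        s1 = Subnetwork("S1", frozenset(universe[:10]), is_core=True)
        s2 = Subnetwork("S2", frozenset(universe[10:16]))
        r1 = mc_age_enrichment([s1, s2], ages, universe=universe, n_resamples=300, seed=7)
        r2 = mc_age_enrichment([s2, s1], ages, universe=universe, n_resamples=300, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_member_outside_universe_rejected(self):
        from sfpage.network import Subnetwork

        subs = [Subnetwork("S1", frozenset(["a", "b", "z"]), is_core=True)]
        with pytest.raises(ValueError):
            mc_age_enrichment(subs, {"a": "A", "b": "A", "c": "A", "z": "A"},
                              universe=["a", "b", "c"], n_resamples=10, seed=0)


class TestReproductiveAssociation:
    def test_uniform_flags_degenerate(self):
        from sfpage.network import Subnetwork

        subs = [
            Subnetwork("S1", frozenset(["a", "b", "c", "d"]), is_core=True),
            Subnetwork("S2", frozenset(["e", "f", "g", "h"])),
        ]
        flags = {g: True for g in "abcdefgh"}
        omnibus, posthoc = reproductive_association(subs, flags, n_sim=100, seed=0)
        assert omnibus.statistic == 0.0 and omnibus.p == 1.0
        assert (posthoc["p_adj"] == 1.0).all()

    def test_perfect_separation_detected(self):
        from sfpage.network import Subnetwork

        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        subs = [Subnetwork("S1", frozenset(a), is_core=True), Subnetwork("S2", frozenset(b))]
        flags = {**{g: True for g in a}, **{g: False for g in b}}
        omnibus, posthoc = reproductive_association(subs, flags, n_sim=2000, seed=1)
        assert omnibus.statistic == pytest.approx(20.0)  # 2x2 (10,0;0,10)
        assert omnibus.p <= 0.01
        assert posthoc.loc[posthoc.subnetwork == "S1", "z"].iloc[0] > 0

    def test_missing_flag_rejected(self):
        from sfpage.network import Subnetwork

        subs = [Subnetwork("S1", frozenset(["a", "b"]), is_core=True),
                Subnetwork("S2", frozenset(["c", "d"]))]
        with pytest.raises(ValueError, match="without reproductive flag"):
            reproductive_association(subs, {"a": True, "b": False, "c": True}, n_sim=10)

    def test_null_calibration(self):
        from sfpage.network import Subnetwork
        from sfpage.stats import seeded_rng

        sizes = (20, 15, 10)
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = seeded_rng(55, "assoc_null", rep)
            subs, flags, pos = [], {}, 0
            for si, size in enumerate(sizes):
                members = [f"r{rep}_{pos + i}" for i in range(size)]
                pos += size
                subs.append(Subnetwork(f"S{si + 1}", frozenset(members), is_core=si == 0))
                for m in members:
                    flags[m] = bool(rng.random() < 0.5)
            if all(any(flags[m] == v for m in flags) for v in (True, False)):
                omnibus, _ = reproductive_association(subs, flags, n_sim=199,
                                                      seed=int(rng.integers(2**31)))
                if omnibus.p <= 0.05:
                    rejections += 1
        lo, hi = sps.binom.interval(0.999, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestExportNetwork:
    def test_round_trip_graphml(self, tmp_path):
        bundle = gen_network(block_sizes=(5, 4), p_in=0.5, n_nonsfp=5, p_cross=0.2, seed=1)
        net = build_network(bundle.edges, bundle.sfp_ids)
        subs = extract_subnetworks(net)
        path = export_network(net, subs, tmp_path / "net.graphml",
                              node_attrs={"age_class": {g: "A" for g in bundle.sfp_ids}})
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.graph.edges}
        core = [n for n, d in back.nodes(data=True) if d.get("is_core")]
        assert set(core) == set(subs[0].members)

    def test_empty_edge_set_still_valid(self, tmp_path):
        net = build_network(pd.DataFrame([_edge_row("g1", "g2", experiments=0.1)]),
                            {"g1", "g2"})
        path = export_network(net, [], tmp_path / "empty.graphml")
        back = nx.read_graphml(path)
        assert set(back.nodes) == {"g1", "g2"} and back.number_of_edges() == 0

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network(pd.DataFrame([_edge_row("g1", "g2", experiments=0.9)]),
                            {"g1", "g2"})
        with pytest.raises(ValueError, match="format"):
            export_network(net, [], tmp_path / "x.bin", fmt="binary")
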