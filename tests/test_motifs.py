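import numpy as np
import networkx as nx
import pandas as pd
import pytest

from tmrnet import motifs as mo
from tmrnet.grn import MINetwork
from tmrnet.motifs import (
    MotifError,
    PromoterWindow,
    PWMotif,
    TmrGraph,
    build_tmr_graph,
    call_hubs,
    load_motifs,
    promoter_windows,
    scan_promoter,
)
from tmrnet.synthdata import reverse_complement


def jaspar_file(path, records):
    with open(path, "w") as fh:
        for motif_id, tf, counts in records:
            fh.write(f">{motif_id} {tf}\n")
            for base, row in zip("ACGT", counts):
                fh.write(f"{base} [ {' '.join(str(c) for c in row)} ]\n")
    return path


SHARP = [  # 17/1/1/1 consensus ACGTACGTAC
    [17, 1, 1, 1, 17, 1, 1, 1, 17, 1],
    [1, 17, 1, 1, 1, 17, 1, 1, 1, 17],
    [1, 1, 17, 1, 1, 1, 17, 1, 1, 1],
    [1, 1, 1, 17, 1, 1, 1, 17, 1, 1],
]


def make_window(sequence, gene="gX"):
    return PromoterWindow(
        gene=gene, chrom="chr1", strand="+", start=0, end=mo.WINDOW_WIDTH,
        sequence=sequence,
    )


def random_window(rng, plant=None):
    seq = list(rng.choice(list("ACGT"), size=mo.WINDOW_WIDTH))
    if plant is not None:
        offset, site = plant
        seq[offset : offset + len(site)] = list(site)
    return make_window("".join(seq))


class TestPWM:
    def test_pseudocount_probabilities(self):
        m = PWMotif.from_counts("M1.1", "TFX", np.tile([[10], [0], [0], [0]], (1, 6)))
        prob = 0.25 * 2.0 ** m.pwm
        np.testing.assert_allclose(prob[0], (10 + 0.2) / 10.8, rtol=1e-12)
        np.testing.assert_allclose(prob[1:], 0.2 / 10.8, rtol=1e-12)

    def test_source_priority_then_latest_version(self, tmp_path):
        manual = jaspar_file(tmp_path / "m.jaspar", [("M1.1", "TFA", SHARP)])
        auto = jaspar_file(
            tmp_path / "a.jaspar",
            [("M2.3", "TFA", SHARP), ("M9.1", "TFB", SHARP), ("M9.4", "TFB", SHARP)],
        )
        chosen, missing = load_motifs(
            [(manual, "manual"), (auto, "automatic")], ["TFA", "TFB", "TFC"]
        )
        by_tf = {m.tf: m for m in chosen}
        assert by_tf["TFA"].motif_id == "M1.1"      # manual beats automatic
        assert by_tf["TFB"].motif_id == "M9.4"      # latest version wins
        assert missing == ["TFC"]

    def test_consensus_scores_maximum(self):
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        assert m.consensus == "ACGTACGTAC"
        window = make_window("A" * 100 + m.consensus + "A" * (mo.WINDOW_WIDTH - 110))
        hits = scan_promoter(m, window)
        best = hits.loc[hits["relative"].idxmax()]
        assert best["position"] == 100
        assert best["relative"] == 1.0
        assert best["raw"] == pytest.approx(m.max_score)

    def test_relative_score_invariant_to_affine_pwm_shift(self):
        rng = np.random.default_rng(0)
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        shifted = PWMotif("M1.1s", "TFX", m.pwm + 3.7, m.background)
        w = random_window(rng, plant=(500, m.consensus))
        h1 = scan_promoter(m, w)
        h2 = scan_promoter(shifted, w)
        pd.testing.assert_frame_equal(
            h1[["position", "orientation", "relative"]],
            h2[["position", "orientation", "relative"]],
        )

    def test_malformed_pfm_raises(self, tmp_path):
        bad = tmp_path / "bad.jaspar"
        bad.write_text(">M1.1 TFA\nA [ not numbers ]\n")
        with pytest.raises(MotifError, match="parse"):
            load_motifs(bad, ["TFA"])


class TestScan:
    def test_planted_consensus_hit_at_offset(self):
        rng = np.random.default_rng(1)
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        w = random_window(rng, plant=(137, m.consensus))
        hits = scan_promoter(m, w)
        exact = hits[(hits["position"] == 137) & (hits["orientation"] == "+")]
        assert len(exact) == 1
        assert exact.iloc[0]["relative"] == 1.0

    def test_reverse_complement_reported_on_minus_orientation(self):
        rng = np.random.default_rng(2)
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        w = random_window(rng, plant=(137, reverse_complement(m.consensus)))
        hits = scan_promoter(m, w)
        exact = hits[(hits["position"] == 137) & (hits["orientation"] == "-")]
        assert len(exact) == 1
        assert exact.iloc[0]["relative"] == 1.0

    def test_n_bases_score_background_expectation(self):
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        w = make_window("N" * mo.WINDOW_WIDTH)
        hits = scan_promoter(m, w, min_rel_score=1e-9)
        expected = float((m.background @ m.pwm).sum())
        assert np.allclose(hits["raw"], expected)

    def test_motif_longer_than_window_warns_empty(self):
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        short = PromoterWindow(
            gene="g", chrom="chr1", strand="+", start=0, end=mo.WINDOW_WIDTH,
            sequence="ACGT", clipped=True,
        )
        with pytest.warns(UserWarning, match="longer"):
            assert scan_promoter(m, short).empty

    def test_hit_rate_matches_exact_score_distribution(self):
        """Observed hit count on uniform background matches the expected
        count from the exact per-word score distribution (DP over
        positions), within a factor of two."""
        m = PWMotif.from_counts("M1.1", "TFX", SHARP)
        # DP: distribution of the raw score of a uniform random word
        dist = {0.0: 1.0}
        for j in range(m.length):
            new = {}
            for s, p in dist.items():
                for b in range(4):
                    key = round(s + m.pwm[b, j], 9)
                    new[key] = new.get(key, 0.0) + p * 0.25
            dist = new
        span = m.max_score - m.min_score
        p_hit = sum(
            p for s, p in dist.items() if (s - m.min_score) / span >= 0.85
        )
        rng = np.random.default_rng(3)
        n_windows = 200
        observed = sum(
            len(scan_promoter(m, random_window(rng))) for _ in range(n_windows)
        )
        expected = p_hit * n_windows * 2 * (mo.WINDOW_WIDTH - m.length + 1)
        assert expected / 2 <= observed <= expected * 2


class TestWindows:
    def test_asymmetric_interval_arithmetic(self):
        tss = pd.DataFrame(
            [("gP", "chr1", 10_000, "+"), ("gM", "chr1", 10_000, "-")],
            columns=["gene", "chrom", "tss", "strand"],
        )
        seqs = {"gP": "A" * 2200, "gM": "C" * 2200}
        wins = {w.gene: w for w in promoter_windows(tss, seqs)}
        # 0-based half-open; TSS at 1-based 10000 -> 0-based 9999
        assert (wins["gP"].start, wins["gP"].end) == (9999 - 2000, 9999 + 200)
        assert (wins["gM"].start, wins["gM"].end) == (9999 - 200, 9999 + 2000)
        for w in wins.values():
            assert w.end - w.start == 2200


def two_cohort_networks(pairs_a, pairs_b, regulators):
    def net(pairs):
        df = pd.DataFrame(
            [(r, t, 0.5, 10) for r, t in pairs],
            columns=["regulator", "target", "mi", "support"],
        )
        return MINetwork(edges=df, regulators=regulators, p_cutoff=1e-4)

    return {"a": net(pairs_a), "b": net(pairs_b)}


def hits_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["source_tf", "target_gene", "position", "orientation", "raw",
                 "relative", "motif_id"],
    )


class TestTmrGraph:
    def test_dual_support_rule(self):
        consensus = ["T1", "T2", "T3"]
        hits = hits_frame(
            [
                ("T1", "T2", 10, "+", 5.0, 0.9, "M1"),  # MI in cohort a only
                ("T1", "T3", 20, "-", 5.0, 0.95, "M1"), # no MI anywhere
                ("T2", "T3", 30, "+", 5.0, 0.88, "M2"), # MI in both
            ]
        )
        nets = two_cohort_networks(
            [("T1", "T2"), ("T2", "T3")], [("T2", "T3")], consensus
        )
        g = build_tmr_graph(hits, nets, consensus)
        table = g.edges_table().set_index(["source", "target"])
        assert set(table.index) == {("T1", "T2"), ("T2", "T3")}
        assert bool(table.loc[("T1", "T2"), "mi_support_a"])
        assert not bool(table.loc[("T1", "T2"), "mi_support_b"])
        assert bool(table.loc[("T2", "T3"), "mi_support_b"])

    def test_best_relative_kept_for_duplicate_hits(self):
        consensus = ["T1", "T2"]
        hits = hits_frame(
            [
                ("T1", "T2", 10, "+", 5.0, 0.86, "M1"),
                ("T1", "T2", 500, "-", 6.0, 0.97, "M1"),
            ]
        )
        nets = two_cohort_networks([("T1", "T2")], [], consensus)
        g = build_tmr_graph(hits, nets, consensus)
        assert g.graph["T1"]["T2"]["relative"] == 0.97
        assert g.graph["T1"]["T2"]["position"] == 500

    def test_graph_is_subset_of_both_evidence_layers(self):
        rng = np.random.default_rng(4)
        consensus = [f"T{i}" for i in range(8)]
        hit_pairs = {
            (a, b)
            for a in consensus
            for b in consensus
            if a != b and rng.random() < 0.4
        }
        mi_pairs = {
            (a, b)
            for a in consensus
            for b in consensus
            if a != b and rng.random() < 0.3
        }
        hits = hits_frame(
            [(a, b, 1, "+", 5.0, 0.9, "M") for a, b in hit_pairs]
        )
        nets = two_cohort_networks(sorted(mi_pairs), [], consensus)
        g = build_tmr_graph(hits, nets, consensus)
        undirected_mi = {tuple(sorted(p)) for p in mi_pairs}
        for u, v in g.graph.edges:
            assert (u, v) in hit_pairs
            assert tuple(sorted((u, v))) in undirected_mi


def graph_from_edges(edges, nodes):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, relative=0.9, position=0, orientation="+",
                   support={"a": True})
    return TmrGraph(graph=g, cohorts=["a"])


def brute_force_hubs(edges, nodes):
    """Independent implementation of the degree-quantile rule."""
    out = {n: 0 for n in nodes}
    inn = {n: 0 for n in nodes}
    for u, v in edges:
        out[u] += 1
        inn[v] += 1
    q3 = np.quantile([out[n] for n in nodes], 0.75)
    q1 = np.quantile([inn[n] for n in nodes], 0.25)
    if not edges:
        return set()
    return {n for n in nodes if out[n] >= q3 and inn[n] <= q1}


class TestHubs:
    def test_star_center_is_hub_and_sorts_first(self):
        nodes = [f"n{i}" for i in range(10)]
        edges = [("n0", n) for n in nodes[1:]]
        table = call_hubs(graph_from_edges(edges, nodes))
        assert bool(table.loc["n0", "is_hub"])
        assert table.index[0] == "n0"
        assert set(table.index[table["is_hub"]]) == brute_force_hubs(edges, nodes)

    def test_empty_edge_set_warns_and_calls_no_hubs(self):
        nodes = ["a", "b", "c"]
        with pytest.warns(UserWarning, match="empty edge set"):
            table = call_hubs(graph_from_edges([], nodes))
        assert not table["is_hub"].any()

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(50)]
        for _ in range(100):
            edges = [
                (a, b) for a in nodes for b in nodes
                if a != b and rng.random() < 0.1
            ]
            table = call_hubs(graph_from_edges(edges, nodes))
            assert set(table.index[table["is_hub"]]) == brute_force_hubs(edges, nodes)

    def test_hub_set_equivariant_under_relabeling(self):
        rng = np.random.default_rng(6)
        nodes = [f"n{i}" for i in range(20)]
        edges = [(a, b) for a in nodes for b in nodes if a != b and rng.random() < 0.15]
        mapping = {n: f"x{i}" for i, n in enumerate(rng.permutation(nodes))}
        relabeled = [(mapping[a], mapping[b]) for a, b in edges]
        hubs1 = call_hubs(graph_from_edges(edges, nodes))
        hubs2 = call_hubs(graph_from_edges(relabeled, list(mapping.values())))
        assert {mapping[n] for n in hubs1.index[hubs1["is_hub"]]} == set(
            hubs2.index[hubs2["is_hub"]]
        )

    def test_adjacency_export_matches_edges(self):
        nodes = ["a", "b", "c"]
        g = graph_from_edges([("a", "b"), ("c", "a")], nodes)
        adj = g.adjacency_matrix()
        assert adj.loc["a", "b"] == 1 and adj.loc["c", "a"] == 1
        assert adj.to_numpy().sum() == 2
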