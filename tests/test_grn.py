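import numpy as np
import pandas as pd
import pytest

from tmrnet import grn
from tmrnet.grn import GrnError, MINetwork, apply_dpi, calibrate_threshold, mutual_information
from tmrnet.synthdata import SimulationConfig, simulate_cohorts
from tmrnet import preprocess as pre


def make_network(edges, regulators, p_cutoff=1e-4):
    df = pd.DataFrame(edges, columns=["regulator", "target", "mi", "support"])
    return MINetwork(edges=df, regulators=regulators, p_cutoff=p_cutoff)


class TestEstimator:
    def test_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=100), rng.normal(size=100)
            assert mutual_information(x, y, seed=5) == mutual_information(y, x, seed=5)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        y = 0.7 * x + rng.normal(size=120)
        base = mutual_information(x, y, seed=3)
        assert mutual_information(np.exp(x), y, seed=3) == base
        assert mutual_information(x, y**3, seed=3) == base
        assert mutual_information(2 * x + 5, y, seed=3) == base

    def test_identity_reaches_partition_maximum_and_beats_shuffles(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        mi_xx = mutual_information(x, x, seed=0)
        grid = np.arange(1, 101) / 101.0
        assert mi_xx == float(grn._mi_ap(grid, grid, grn.CHI2_CRIT, grn.MIN_CELL))
        beaten = 0
        for _ in range(200):
            y = rng.permutation(x)
            beaten += mutual_information(x, y, seed=0) < mi_xx
        assert beaten / 200 >= 0.99

    def test_independent_pairs_fall_below_p05_threshold(self):
        thr = calibrate_threshold(1000, 0.05, n_null=10_000, seed=0)
        rng = np.random.default_rng(3)
        below = 0
        for _ in range(50):
            below += (
                mutual_information(rng.uniform(size=1000), rng.uniform(size=1000))
                < thr.mi
            )
        assert below / 50 >= 0.90

    def test_input_validation(self):
        with pytest.raises(GrnError, match="equal length"):
            mutual_information(np.ones(10), np.ones(11))
        with pytest.raises(GrnError, match="at least 8"):
            mutual_information(np.arange(5), np.arange(5))


class TestThreshold:
    def test_half_cutoff_is_the_null_median(self):
        thr = calibrate_threshold(60, 0.5, n_null=10_000, seed=1)
        rng = np.random.default_rng(1)
        null = grn._null_mi(60, 10_000, rng, grn.CHI2_CRIT, grn.MIN_CELL)
        assert thr.mi == float(np.quantile(null, 0.5))

    def test_threshold_monotone_in_cutoff(self):
        thr2 = calibrate_threshold(60, 1e-2, n_null=50_000, seed=2)
        thr4 = calibrate_threshold(60, 1e-4, n_null=50_000, seed=2)
        thr8 = calibrate_threshold(60, 1e-8, n_null=50_000, seed=2)
        assert thr8.mi > thr4.mi > thr2.mi > 0

    def test_small_null_rejected(self):
        with pytest.raises(GrnError, match="n_null"):
            calibrate_threshold(60, 0.01, n_null=1000)


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        net = make_network(
            [("a", "b", 0.9, 1), ("b", "c", 0.8, 1), ("a", "c", 0.3, 1)],
            regulators=["a", "b"],
        )
        for tol in (0.0, grn.DPI_TOLERANCE):
            pruned = apply_dpi(net, tolerance=tol)
            assert pruned.edge_set() == {("a", "b"), ("b", "c")}

    def test_tied_minimum_keeps_all_edges(self):
        net = make_network(
            [("a", "b", 0.9, 1), ("b", "c", 0.3, 1), ("a", "c", 0.3, 1)],
            regulators=["a", "b"],
        )
        assert apply_dpi(net, tolerance=0.0).edge_set() == net.edge_set()

    def test_two_edge_graph_unchanged(self):
        net = make_network(
            [("a", "b", 0.9, 1), ("a", "c", 0.1, 1)], regulators=["a"]
        )
        assert apply_dpi(net).edge_set() == net.edge_set()

    def test_latent_chain_indirect_edge_removed(self):
        """In an X -> Y -> Z latent chain the X-Z dependence is indirect;
        DPI removes it in nearly every seed."""
        rng = np.random.default_rng(4)
        removed = 0
        n_seeds = 10
        for _ in range(n_seeds):
            x = rng.normal(size=500)
            y = 0.8 * x + 0.6 * rng.normal(size=500)
            z = 0.8 * y + 0.6 * rng.normal(size=500)
            pair_mi = {
                ("x", "y"): mutual_information(x, y),
                ("y", "z"): mutual_information(y, z),
                ("x", "z"): mutual_information(x, z),
            }
            removed += grn._dpi_removed(pair_mi, grn.DPI_TOLERANCE) == {("x", "z")}
        assert removed >= 0.95 * n_seeds

    def test_subset_and_idempotent_on_random_graphs(self):
        rng = np.random.default_rng(5)
        regulators = [f"R{i}" for i in range(6)]
        nodes = regulators + [f"t{i}" for i in range(8)]
        for _ in range(100):
            edges = []
            for r in regulators:
                for t in nodes:
                    if t != r and rng.random() < 0.25:
                        edges.append((r, t, float(rng.uniform(0.1, 1.0)), 1))
            if not edges:
                continue
            net = make_network(edges, regulators)
            once = apply_dpi(net)
            assert once.edge_set() <= net.edge_set()
            assert apply_dpi(once).edge_set() == once.edge_set()


class TestConsolidation:
    def test_recovers_planted_regulons(self, threshold_n60):
        """Structural recovery at n=60, strengths >= 0.6, p=1e-4, 50
        bootstraps (no activity shifts, target noise SD 0.3): >= 80% of
        planted pairs recovered, <= 5% of reported edges unplanted,
        averaged over seeds."""
        recalls, unplanted = [], []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                seed=seed, n_active=0, n_tf_edges=0, activity_shift=0.0,
                noise_sd_b=0.3,
            )
            _, mat_b, truth = simulate_cohorts(cfg)
            mat = pre.filter_intensity(mat_b)
            net = grn.consolidate_bootstraps(
                mat, truth.regulators, 1e-4, n_boot=50, seed=11,
                threshold=threshold_n60,
            )
            got = net.edge_set()
            genes = set(mat.genes)
            planted = {
                (r, t) for r, t in truth.planted_pairs()
                if r in genes and t in genes
            }
            tp = len(got & planted)
            recalls.append(tp / len(planted))
            unplanted.append(1 - tp / max(len(got), 1))
        assert np.mean(recalls) >= 0.80
        assert np.mean(unplanted) <= 0.05

    def test_network_shrinks_with_stricter_cutoff(self):
        cfg = SimulationConfig(seed=4, n_active=0, n_tf_edges=0, activity_shift=0.0)
        _, mat_b, truth = simulate_cohorts(cfg)
        mat = pre.filter_intensity(mat_b)
        sizes = []
        for p_cutoff in (1e-2, 1e-4, 1e-6):
            thr = calibrate_threshold(60, p_cutoff, n_null=50_000, seed=6)
            net = grn.consolidate_bootstraps(
                mat, truth.regulators, p_cutoff, n_boot=20, seed=9, threshold=thr
            )
            sizes.append(len(net.edges))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_single_bootstrap_passthrough_warns(self, threshold_n60, default_run):
        _, _, mat_b, truth = default_run
        mat = pre.filter_intensity(mat_b)
        with pytest.warns(UserWarning, match="n_boot=1"):
            net = grn.consolidate_bootstraps(
                mat, truth.regulators, 1e-4, n_boot=1, seed=0,
                threshold=threshold_n60,
            )
        assert (net.edges["support"] == 1).all()

    def test_no_regulator_in_matrix_raises(self, default_run):
        _, _, mat_b, _ = default_run
        with pytest.raises(GrnError, match="no regulator"):
            grn.consolidate_bootstraps(mat_b, ["absent"], 1e-4, n_boot=2)


def test_network_tsv_roundtrip(tmp_path, consolidated_run):
    *_, net_a, _ = consolidated_run
    path = tmp_path / "net.tsv"
    net_a.to_tsv(path)
    back = MINetwork.from_tsv(path, net_a.regulators, net_a.p_cutoff, net_a.n_bootstraps)
    assert back.edge_set() == net_a.edge_set()


def test_network_invariants_enforced():
    with pytest.raises(GrnError, match="self-edges"):
        make_network([("a", "a", 0.5, 1)], regulators=["a"])
    with pytest.raises(GrnError, match="non-negative"):
        make_network([("a", "b", -0.5, 1)], regulators=["a"])
    with pytest.raises(GrnError, match="regulator list"):
        make_network([("z", "b", 0.5, 1)], regulators=["a"])
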