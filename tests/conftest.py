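import numpy as np
import pandas as pd
import pytest

from tmrnet import grn
from tmrnet.preprocess import ExpressionMatrix
from tmrnet.synthdata import SimulationConfig, simulate_cohorts


def bh_bruteforce(p):
    """Independent Benjamini-Hochberg oracle: sort, scale, cummin, restore."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] / (np.arange(1, n + 1) / n)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def intensity_matrix(values: np.ndarray, n_tumor: int, prefix: str = "s") -> ExpressionMatrix:
    """Wrap a plain array as a log2-intensity ExpressionMatrix."""
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{prefix}{j}" for j in range(values.shape[1])]
    groups = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (values.shape[1] - n_tumor), index=samples
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
        platform="intensity",
    )


@pytest.fixture(scope="session")
def threshold_n60():
    """Calibrated MI threshold at p=1e-4 for n=60, shared across heavy tests."""
    return grn.calibrate_threshold(60, 1e-4, n_null=100_000, seed=7)


@pytest.fixture(scope="session")
def default_run():
    """One simulated pair of cohorts under the default study conditions."""
    cfg = SimulationConfig(seed=1)
    mat_a, mat_b, truth = simulate_cohorts(cfg)
    return cfg, mat_a, mat_b, truth


@pytest.fixture(scope="session")
def consolidated_run(default_run, threshold_n60):
    """Normalized matrices plus consolidated networks for the default run."""
    from tmrnet import preprocess as pre

    cfg, mat_a, mat_b, truth = default_run
    norm_a = pre.normalize_counts(pre.filter_counts(mat_a))
    norm_b = pre.filter_intensity(mat_b)
    net_a = grn.consolidate_bootstraps(
        norm_a, truth.regulators, 1e-4, n_boot=50, seed=100, threshold=threshold_n60
    )
    net_b = grn.consolidate_bootstraps(
        norm_b, truth.regulators, 1e-4, n_boot=50, seed=101, threshold=threshold_n60
    )
    return cfg, truth, norm_a, norm_b, net_a, net_b
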