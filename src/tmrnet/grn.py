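"""Mutual-information regulon network inference.

The estimator is the adaptive-partitioning MI used for co-expression
network reconstruction: both vectors are copula-transformed to (0,1) by
rank/(n+1) (ties broken by a seeded random jitter), then the unit square is
recursively split into four quadrants at the midpoint of the current cell
while the chi-square statistic of the quadrant occupancy against uniformity
exceeds 7.815 (df=3, alpha=0.05) and the cell holds at least 8 points.  The
MI (in nats) is the discrete KL divergence of the leaf-cell occupancy
against the uniform measure:

    MI = sum_leaf (n_c/N) * ln( (n_c/N) / area_c )

Significance is calibrated on a permutation null (independent rank pairs of
the same sample size), edges below the calibrated threshold are dropped, the
data processing inequality (DPI) removes the weakest edge of every fully
connected triple, and bootstrap runs are consolidated by a binomial support
test against the mean per-run edge-retention probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

__all__ = [
    "GrnError",
    "MIThreshold",
    "MINetwork",
    "mutual_information",
    "copula_transform",
    "calibrate_threshold",
    "apply_dpi",
    "consolidate_bootstraps",
]

#: chi-square recursion threshold (df=3, alpha=0.05) and minimum cell count
CHI2_CRIT = 7.815
MIN_CELL = 8


class GrnError(ValueError):
    """Invalid input to the network-inference layer."""


# ---------------------------------------------------------------------------
# MI kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mi_ap(u, v, chi2_crit, min_cell, force_depth=1):  # pragma: no cover - numba kernel
    n = u.shape[0]
    idx = np.empty(n, np.int64)
    for i in range(n):
        idx[i] = i
    cap = 64 * n + 256
    sx0 = np.empty(cap)
    sx1 = np.empty(cap)
    sy0 = np.empty(cap)
    sy1 = np.empty(cap)
    slo = np.empty(cap, np.int64)
    shi = np.empty(cap, np.int64)
    sdep = np.empty(cap, np.int64)
    tmp = np.empty(n, np.int64)
    top = 0
    sx0[top] = 0.0
    sx1[top] = 1.0
    sy0[top] = 0.0
    sy1[top] = 1.0
    slo[top] = 0
    shi[top] = n
    sdep[top] = 0
    top += 1
    mi = 0.0
    while top > 0:
        top -= 1
        x0 = sx0[top]
        x1 = sx1[top]
        y0 = sy0[top]
        y1 = sy1[top]
        lo = slo[top]
        hi = shi[top]
        depth = sdep[top]
        m = hi - lo
        if m == 0:
            continue
        split = False
        if m >= min_cell:
            xm = 0.5 * (x0 + x1)
            ym = 0.5 * (y0 + y1)
            c0 = 0
            c1 = 0
            c2 = 0
            c3 = 0
            for i in range(lo, hi):
                j = idx[i]
                q = 0
                if u[j] >= xm:
                    q += 1
                if v[j] >= ym:
                    q += 2
                if q == 0:
                    c0 += 1
                elif q == 1:
                    c1 += 1
                elif q == 2:
                    c2 += 1
                else:
                    c3 += 1
            e = m / 4.0
            chi2 = (
                (c0 - e) ** 2 + (c1 - e) ** 2 + (c2 - e) ** 2 + (c3 - e) ** 2
            ) / e
            # the first level is split unconditionally: the copula margins
            # are fixed, so the root 2x2 table has ~1 df and the chi-square
            # rule would almost never fire under independence, collapsing
            # the null onto an atom at zero
            if depth < force_depth or chi2 > chi2_crit:
                split = True
                # stable four-way partition of idx[lo:hi]
                k = lo
                for quad in range(4):
                    for i in range(lo, hi):
                        j = idx[i]
                        q = 0
                        if u[j] >= xm:
                            q += 1
                        if v[j] >= ym:
                            q += 2
                        if q == quad:
                            tmp[k] = j
                            k += 1
                for i in range(lo, hi):
                    idx[i] = tmp[i]
                b0 = lo + c0
                b1 = b0 + c1
                b2 = b1 + c2
                # push the four child cells
                sx0[top] = x0
                sx1[top] = xm
                sy0[top] = y0
                sy1[top] = ym
                slo[top] = lo
                shi[top] = b0
                sdep[top] = depth + 1
                top += 1
                sx0[top] = xm
                sx1[top] = x1
                sy0[top] = y0
                sy1[top] = ym
                slo[top] = b0
                shi[top] = b1
                sdep[top] = depth + 1
                top += 1
                sx0[top] = x0
                sx1[top] = xm
                sy0[top] = ym
                sy1[top] = y1
                slo[top] = b1
                shi[top] = b2
                sdep[top] = depth + 1
                top += 1
                sx0[top] = xm
                sx1[top] = x1
                sy0[top] = ym
                sy1[top] = y1
                slo[top] = b2
                shi[top] = hi
                sdep[top] = depth + 1
                top += 1
        if not split:
            area = (x1 - x0) * (y1 - y0)
            p = m / n
            mi += p * np.log(p / area)
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def _mi_pairs(U, reg_rows, chi2_crit, min_cell):  # pragma: no cover - numba kernel
    """MI for every (regulator row, gene row) pair; self pairs get -1."""
    n_reg = reg_rows.shape[0]
    n_genes = U.shape[0]
    out = np.empty((n_reg, n_genes))
    for a in range(n_reg):
        ra = reg_rows[a]
        for g in range(n_genes):
            if g == ra:
                out[a, g] = -1.0
            else:
                out[a, g] = _mi_ap(U[ra], U[g], chi2_crit, min_cell)
    return out


@njit(cache=True)
def _mi_rows(U, V, chi2_crit, min_cell):  # pragma: no cover - numba kernel
    m = U.shape[0]
    out = np.empty(m)
    for i in range(m):
        out[i] = _mi_ap(U[i], V[i], chi2_crit, min_cell)
    return out


def copula_transform(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank/(n+1) transform with ties broken by seeded random jitter."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    order = np.lexsort((rng.random(n), x))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return ranks / (n + 1)


def _rank_matrix(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.vstack([copula_transform(row, rng) for row in values])


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    chi2_crit: float = CHI2_CRIT,
    min_cell: int = MIN_CELL,
) -> float:
    """Adaptive-partitioning MI (nats) between two sample vectors.

    Symmetric in its arguments and invariant under strictly monotone
    transforms of either argument (the copula step ranks first).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise GrnError("vectors must have equal length")
    if x.shape[0] < 8:
        raise GrnError("need at least 8 samples")
    rng = np.random.default_rng(seed)
    u = copula_transform(x, rng)
    v = copula_transform(y, rng)
    return float(_mi_ap(u, v, chi2_crit, min_cell))


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIThreshold:
    """Calibrated MI significance threshold for a given sample size."""

    p_cutoff: float
    mi: float
    n_samples: int
    n_null: int
    tail_a: float
    tail_b: float


def _null_mi(
    n_samples: int,
    n_null: int,
    rng: np.random.Generator,
    chi2_crit: float,
    min_cell: int,
    chunk: int = 10_000,
) -> np.ndarray:
    grid = np.arange(1, n_samples + 1, dtype=float) / (n_samples + 1)
    out = np.empty(n_null)
    done = 0
    while done < n_null:
        m = min(chunk, n_null - done)
        U = np.tile(grid, (m, 1))
        V = np.tile(grid, (m, 1))
        U = rng.permuted(U, axis=1)
        V = rng.permuted(V, axis=1)
        out[done : done + m] = _mi_rows(U, V, chi2_crit, min_cell)
        done += m
    return out


def calibrate_threshold(
    n_samples: int,
    p_cutoff: float,
    n_null: int = 100_000,
    seed: int = 0,
    chi2_crit: float = CHI2_CRIT,
    min_cell: int = MIN_CELL,
) -> MIThreshold:
    """MI threshold at ``p_cutoff`` from a permutation null of size ``n_null``.

    Uses the empirical (1 - p) quantile when ``p_cutoff * n_null >= 10``,
    otherwise extrapolates from an exponential fit to the top 1% of the null
    (``ln survival ~ a - b * MI``).
    """
    if not 0 < p_cutoff < 1:
        raise GrnError("p_cutoff must be in (0, 1)")
    if n_null < 10_000:
        raise GrnError("n_null must be at least 1e4 for stable tail fits")
    rng = np.random.default_rng(seed)
    null = _null_mi(n_samples, n_null, rng, chi2_crit, min_cell)
    if null.std() == 0:
        raise GrnError("degenerate null distribution (all values equal)")
    # exponential tail fit on the top 1% for extrapolation below the
    # empirical resolution
    k = max(int(0.01 * n_null), 100)
    top = np.sort(null)[::-1][:k]
    surv = np.arange(1, k + 1) / n_null
    b, a = np.polyfit(top, np.log(surv), 1)
    tail_a, tail_b = float(a), float(-b)
    if p_cutoff * n_null >= 10:
        thr = float(np.quantile(null, 1.0 - p_cutoff))
    else:
        thr = (tail_a - np.log(p_cutoff)) / tail_b
    return MIThreshold(
        p_cutoff=p_cutoff,
        mi=float(thr),
        n_samples=n_samples,
        n_null=n_null,
        tail_a=tail_a,
        tail_b=tail_b,
    )


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass
class MINetwork:
    """Directed regulator->target MI edges with bootstrap support counts."""

    edges: pd.DataFrame  # columns: regulator, target, mi, support
    regulators: list[str]
    p_cutoff: float
    n_bootstraps: int = 1

    def __post_init__(self) -> None:
        need = {"regulator", "target", "mi", "support"}
        if not need.issubset(self.edges.columns):
            raise GrnError(f"edge table must have columns {sorted(need)}")
        if (self.edges["mi"] < 0).any():
            raise GrnError("MI values must be non-negative")
        regs = set(self.regulators)
        if not set(self.edges["regulator"]).issubset(regs):
            raise GrnError("edge regulator not in the regulator list")
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise GrnError("self-edges are not allowed")

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def pair_set(self) -> set[tuple[str, str]]:
        """Undirected (sorted) node pairs carrying at least one edge."""
        return {tuple(sorted(p)) for p in self.edge_set()}

    def has_pair(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.pair_set()

    def to_tsv(self, path: str | Path) -> None:
        self.edges.sort_values(["regulator", "target"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, regulators: list[str], p_cutoff: float, n_bootstraps: int = 1
    ) -> "MINetwork":
        edges = pd.read_csv(path, sep="\t")
        return cls(edges=edges, regulators=regulators, p_cutoff=p_cutoff,
                   n_bootstraps=n_bootstraps)


# ---------------------------------------------------------------------------
# DPI
# ---------------------------------------------------------------------------

def _dpi_removed(
    pair_mi: dict[tuple[str, str], float], tolerance: float = 0.0
) -> set[tuple[str, str]]:
    """Pairs removed by the data processing inequality.

    All triangles are evaluated on the input graph; for each fully connected
    triple the strictly smallest edge is marked when it falls below
    ``(1 - tolerance)`` times the second-smallest edge (ties keep all tied
    edges; ``tolerance = 0`` is the strictest rule).
    """
    adj: dict[str, set[str]] = {}
    for a, b in pair_mi:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    removed: set[tuple[str, str]] = set()
    for a, b in pair_mi:
        x, y = (a, b) if a < b else (b, a)
        for c in adj[x] & adj[y]:
            if c <= y:
                continue
            edges = sorted(
                (
                    (pair_mi[(x, y)], (x, y)),
                    (pair_mi[(x, c) if x < c else (c, x)],
                     tuple(sorted((x, c)))),
                    (pair_mi[(y, c) if y < c else (c, y)],
                     tuple(sorted((y, c)))),
                )
            )
            if edges[0][0] == edges[1][0]:  # tied minimum: keep all
                continue
            if edges[0][0] < (1.0 - tolerance) * edges[1][0]:
                removed.add(edges[0][1])
    return removed


#: default DPI tolerance: near-equilateral triangles (e.g. a TF pair with
#: strongly shared targets) keep their weakest edge unless it trails the
#: second-smallest by more than this relative margin
DPI_TOLERANCE = 0.15


def apply_dpi(network: MINetwork, tolerance: float = DPI_TOLERANCE) -> MINetwork:
    """Prune the weakest edge of every fully connected triple.

    TF-TF pairs present in both directions count as a single undirected pair
    (their MI is identical by symmetry of the estimator); removal drops both
    directed edges of a removed pair.  The output is always a subset of the
    input and the operation is idempotent.
    """
    pair_mi: dict[tuple[str, str], float] = {}
    for row in network.edges.itertuples(index=False):
        pair = tuple(sorted((row.regulator, row.target)))
        pair_mi[pair] = max(pair_mi.get(pair, -np.inf), row.mi)
    removed = _dpi_removed(pair_mi, tolerance)
    if not removed:
        return network
    keep = [
        tuple(sorted((r, t))) not in removed
        for r, t in zip(network.edges["regulator"], network.edges["target"])
    ]
    return replace(network, edges=network.edges[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Bootstrap consolidation
# ---------------------------------------------------------------------------

def _single_run(
    values: np.ndarray,
    reg_rows: np.ndarray,
    threshold: float,
    rng: np.random.Generator,
    chi2_crit: float,
    min_cell: int,
    bootstrap: bool = True,
    tolerance: float = DPI_TOLERANCE,
) -> dict[tuple[int, int], float]:
    """One (optionally resampled) network run; returns post-DPI edge MI."""
    n = values.shape[1]
    if bootstrap:
        cols = rng.integers(0, n, size=n)
        values = values[:, cols]
    U = _rank_matrix(values, rng)
    mi = _mi_pairs(U, reg_rows, chi2_crit, min_cell)
    edge_mi: dict[tuple[int, int], float] = {}
    pair_mi: dict[tuple[int, int], float] = {}
    reg_a, gene_g = np.where(mi > threshold)
    for a, g in zip(reg_a, gene_g):
        r = int(reg_rows[a])
        edge_mi[(r, int(g))] = float(mi[a, g])
        pair_mi[tuple(sorted((r, int(g))))] = float(mi[a, g])
    removed = _dpi_removed(pair_mi, tolerance)
    if removed:
        edge_mi = {
            (r, g): v
            for (r, g), v in edge_mi.items()
            if tuple(sorted((r, g))) not in removed
        }
    return edge_mi


def consolidate_bootstraps(
    mat: ExpressionMatrix,
    regulators: list[str],
    p_cutoff: float,
    n_boot: int = 100,
    seed: int = 0,
    threshold: MIThreshold | None = None,
    n_null: int = 100_000,
    support_fdr: float = 0.05,
    chi2_crit: float = CHI2_CRIT,
    min_cell: int = MIN_CELL,
    dpi_tolerance: float = DPI_TOLERANCE,
) -> MINetwork:
    """Bootstrap-consolidated MI network for one cohort.

    Each run resamples samples with replacement (run ``i`` uses seed
    ``seed + i``), computes all TF-gene MI, thresholds at the calibrated
    cutoff, and applies DPI.  An edge is retained when a binomial test of
    its support count against the mean per-run edge-retention probability
    gives BH FDR < ``support_fdr``; its final MI is the mean over the runs
    that contain it.
    """
    genes = list(mat.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    present = [r for r in regulators if r in gene_pos]
    if not present:
        raise GrnError("no regulator found in the expression matrix")
    reg_rows = np.array([gene_pos[r] for r in present], dtype=np.int64)
    values = mat.values.to_numpy(dtype=float)
    n = values.shape[1]
    if threshold is None:
        threshold = calibrate_threshold(
            n, p_cutoff, n_null=n_null, seed=seed + 10_019,
            chi2_crit=chi2_crit, min_cell=min_cell,
        )
    n_possible = len(present) * (len(genes) - 1)

    if n_boot < 1:
        raise GrnError("n_boot must be >= 1")
    single = n_boot == 1
    if single:
        warnings.warn("n_boot=1: returning a single un-tested run", stacklevel=2)

    support: dict[tuple[int, int], int] = {}
    mi_sum: dict[tuple[int, int], float] = {}
    retention = np.empty(n_boot)
    for b in range(n_boot):
        rng = np.random.default_rng(seed + b)
        run = _single_run(
            values, reg_rows, threshold.mi, rng, chi2_crit, min_cell,
            bootstrap=not single, tolerance=dpi_tolerance,
        )
        retention[b] = len(run) / n_possible
        for key, v in run.items():
            support[key] = support.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + v

    keys = sorted(support)
    if not keys:
        return MINetwork(
            edges=pd.DataFrame(columns=["regulator", "target", "mi", "support"]),
            regulators=present, p_cutoff=p_cutoff, n_bootstraps=n_boot,
        )
    counts = np.array([support[k] for k in keys])
    if single:
        keep = np.ones(len(keys), dtype=bool)
    else:
        p_retain = float(retention.mean())
        pvals = stats.binom.sf(counts - 1, n_boot, p_retain)
        keep = multipletests(pvals, method="fdr_bh")[1] < support_fdr
    rows = [
        (genes[r], genes[g], mi_sum[(r, g)] / support[(r, g)], support[(r, g)])
        for (r, g), ok in zip(keys, keep)
        if ok
    ]
    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi", "support"])
    return MINetwork(
        edges=edges, regulators=present, p_cutoff=p_cutoff, n_bootstraps=n_boot
    )
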