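"""Sensitivity harness over network p-cutoffs and bootstrap depths.

Each grid cell re-runs network inference -> regulon activity -> consensus
meta-analysis for both cohorts with a cell-derived seed, then the harness
quantifies stability: pairwise Jaccard overlap of the consensus TMR sets,
pairwise Spearman correlation of mean-NES vectors over regulators shared
by cell pairs, and a per-regulator persistence fraction (share of grid
cells in which the regulator is consensus).  The desk-scale default grid
is 2 x 2 (p in {1e-2, 1e-4}, bootstrap depths {20, 50}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import activity as _activity
from . import grn as _grn
from . import meta as _meta
from .preprocess import ExpressionMatrix

__all__ = ["SweepResult", "sweep", "jaccard", "DEFAULT_GRID"]

DEFAULT_GRID: list[tuple[float, int]] = [
    (1e-2, 20),
    (1e-2, 50),
    (1e-4, 20),
    (1e-4, 50),
]


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|; two empty sets count as identical (1.0)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class SweepResult:
    """Grid outputs plus pairwise stability matrices."""

    cells: dict[tuple[float, int], pd.DataFrame | None]  # meta table or None (failed)
    jaccard_matrix: pd.DataFrame
    spearman_matrix: pd.DataFrame
    persistence: pd.Series

    def cell_label(self, cell: tuple[float, int]) -> str:
        return f"p{cell[0]:g}_b{cell[1]}"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cell, table in self.cells.items():
            if table is not None:
                table.to_csv(out / f"cell_{self.cell_label(cell)}.tsv", sep="\t")
        self.jaccard_matrix.to_csv(out / "jaccard.tsv", sep="\t")
        self.spearman_matrix.to_csv(out / "spearman.tsv", sep="\t")
        self.persistence.rename("persistence").to_csv(
            out / "persistence.tsv", sep="\t", index_label="regulator"
        )


def _run_cell(
    mats: tuple[ExpressionMatrix, ExpressionMatrix],
    signatures: tuple[pd.DataFrame, pd.DataFrame],
    regulators: list[str],
    p_cutoff: float,
    n_boot: int,
    seed: int,
    min_size: int,
    n_perm: int,
    alpha: float,
    thresholds: dict[tuple[int, float], _grn.MIThreshold],
) -> pd.DataFrame:
    acts = []
    for i, (mat, sig) in enumerate(zip(mats, signatures)):
        key = (mat.values.shape[1], p_cutoff)
        if key not in thresholds:
            thresholds[key] = _grn.calibrate_threshold(
                key[0], p_cutoff, seed=seed + 10_019
            )
        net = _grn.consolidate_bootstraps(
            mat, regulators, p_cutoff, n_boot=n_boot, seed=seed + 100 * i,
            threshold=thresholds[key],
        )
        if net.edges.empty:
            raise _grn.GrnError("empty network")
        regulons = _activity.build_regulons(net, mat, min_size=min_size)
        acts.append(_activity.score_activity(regulons, sig, n_perm=n_perm,
                                             seed=seed + 100 * i + 7, mat=mat))
    return _meta.consensus_tmrs(acts[0], acts[1], alpha=alpha)


def sweep(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    signature_a: pd.DataFrame,
    signature_b: pd.DataFrame,
    regulators: list[str],
    grid: list[tuple[float, int]] | None = None,
    seed: int = 0,
    min_size: int = _activity.MIN_REGULON_SIZE,
    n_perm: int = 1000,
    alpha: float = _meta.CONSENSUS_ALPHA,
) -> SweepResult:
    """Run the full per-cohort analysis at every (p_cutoff, n_boot) cell.

    Matrices must already be on the log2 scale (post-normalization); the
    DE signatures are computed once by the caller and shared across cells.
    Cell i uses seed ``seed + 1000 * (i + 1)``; a cell producing an empty
    network is recorded as failed and the sweep continues.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    if not grid:
        raise ValueError("grid must be non-empty")
    thresholds: dict[tuple[int, float], _grn.MIThreshold] = {}
    cells: dict[tuple[float, int], pd.DataFrame | None] = {}
    for i, (p_cutoff, n_boot) in enumerate(grid):
        try:
            cells[(p_cutoff, n_boot)] = _run_cell(
                (mat_a, mat_b), (signature_a, signature_b), regulators,
                p_cutoff, n_boot, seed + 1000 * (i + 1), min_size, n_perm,
                alpha, thresholds,
            )
        except (_grn.GrnError, _meta.MetaError) as exc:
            warnings.warn(f"grid cell {(p_cutoff, n_boot)} failed: {exc}",
                          stacklevel=2)
            cells[(p_cutoff, n_boot)] = None

    labels = [f"p{p:g}_b{b}" for p, b in cells]
    ok = [c for c, t in cells.items() if t is not None]
    n = len(cells)
    jac = np.full((n, n), np.nan)
    rho = np.full((n, n), np.nan)
    keys = list(cells)
    for i, ci in enumerate(keys):
        for j, cj in enumerate(keys):
            ti, tj = cells[ci], cells[cj]
            if ti is None or tj is None:
                continue
            si = set(ti.index[ti["consensus"]])
            sj = set(tj.index[tj["consensus"]])
            jac[i, j] = jaccard(si, sj)
            shared = ti.index.intersection(tj.index)
            if i == j:
                rho[i, j] = 1.0
            elif len(shared) >= 2:
                r = stats.spearmanr(
                    ti.loc[shared, "mean_nes"], tj.loc[shared, "mean_nes"]
                ).statistic
                rho[i, j] = float(r)
    all_regs: set[str] = set()
    for c in ok:
        all_regs.update(cells[c].index)
    persistence = pd.Series(
        {
            r: np.mean([bool(cells[c].loc[r, "consensus"]) if r in cells[c].index
                        else False for c in ok])
            for r in sorted(all_regs)
        },
        dtype=float,
    )
    return SweepResult(
        cells=cells,
        jaccard_matrix=pd.DataFrame(jac, index=labels, columns=labels),
        spearman_matrix=pd.DataFrame(rho, index=labels, columns=labels),
        persistence=persistence,
    )
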