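"""Cohort-specific filtering, normalization and differential expression.

Two platform kinds are handled:

* ``counts``    — RNA-seq-like non-negative integer counts.  Genes are kept
  when more than 80% of samples show >= 10 reads, library composition is
  corrected with TMM (trimmed mean of M-values) scaling factors, and the
  matrix is transformed to ``log2(CPM + 0.5)`` on effective library sizes.
* ``intensity`` — microarray-like values assumed already normalized and on
  the log2 scale.  Genes with mean log2 <= 4 are dropped, then the bottom
  25% of the remaining genes by variance.

Differential expression for the tumor-vs-normal contrast uses a moderated
two-group t-statistic: per-gene pooled variances are shrunk toward a common
prior ``s0^2`` with prior degrees of freedom ``d0``, both fit by the method
of moments on the observed variances (scaled-inverse-chi-square hierarchy).
The reported standard error satisfies ``se * |t| = |logFC|``, which the
downstream inverse-variance meta-analysis relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "PreprocessError",
    "filter_counts",
    "normalize_counts",
    "tmm_factors",
    "filter_intensity",
    "differential_expression",
    "consolidate_duplicates",
]

#: significance contract for the tumor-vs-normal contrast
FDR_CUTOFF = 0.05
LOGFC_CUTOFF = 1.0
#: offset added to CPM before the log2 transform
CPM_LOG_OFFSET = 0.5


class PreprocessError(ValueError):
    """Raised for invalid expression input or degenerate filter results."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with group labels and a platform kind.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample-id columns.
    groups
        Series mapping sample id -> ``"tumor"`` or ``"normal"``.
    platform
        ``"counts"``, ``"intensity"`` or ``"logcpm"`` (post-normalization).
    norm_factors
        TMM scaling factors, populated by :func:`normalize_counts`.
    """

    values: pd.DataFrame
    groups: pd.Series
    platform: str
    norm_factors: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise PreprocessError("duplicate gene ids; consolidate first")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise PreprocessError(f"samples without group labels: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - {"tumor", "normal"}
        if bad:
            raise PreprocessError(f"unknown group labels: {sorted(bad)}")
        if self.platform == "counts":
            v = self.values.to_numpy()
            if (v < 0).any():
                raise PreprocessError("counts matrix must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]

    # -- I/O (TSV: first column gene id, header sample ids; two-column
    #    sample sheet sample id / group) -----------------------------------
    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.groups.rename("group").to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls,
        values_path: str | Path,
        samples_path: str | Path,
        platform: str,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        values = consolidate_duplicates(values)
        sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values=values, groups=sheet["group"], platform=platform)


def consolidate_duplicates(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene ids to a single row.

    Keeps the duplicate row whose values equal the per-cell statistical mode
    across the duplicates, falling back to the first row when no row matches
    (or on ties).  Deterministic by construction.
    """
    if not values.index.duplicated().any():
        return values
    keep_rows = []
    seen: set = set()
    for gene in values.index:
        if gene in seen:
            continue
        seen.add(gene)
        block = values.loc[[gene]]
        if len(block) == 1:
            keep_rows.append(block.iloc[0])
            continue
        mode = block.apply(lambda col: col.mode().iloc[0], axis=0)
        match = (block == mode).all(axis=1)
        row = block[match].iloc[0] if match.any() else block.iloc[0]
        keep_rows.append(row)
    out = pd.DataFrame(keep_rows)
    out.index.name = values.index.name
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_counts(mat: ExpressionMatrix, min_count: int = 10, min_fraction: float = 0.80) -> ExpressionMatrix:
    """Keep genes with >= ``min_count`` reads in more than ``min_fraction`` of samples.

    The fraction comparison is a strict inequality: a gene observed at the
    threshold in exactly 80% of samples is removed.
    """
    if mat.platform != "counts":
        raise PreprocessError("filter_counts expects a counts matrix")
    frac = (mat.values >= min_count).sum(axis=1) / mat.values.shape[1]
    keep = frac > min_fraction
    if not keep.any():
        raise PreprocessError(
            "no gene passes the expression filter; review the count threshold"
        )
    return replace(mat, values=mat.values.loc[keep])


def filter_intensity(
    mat: ExpressionMatrix, min_mean: float = 4.0, variance_quantile: float = 0.25
) -> ExpressionMatrix:
    """Remove low-expression then low-variability genes from a log2 intensity matrix.

    Genes with mean log2 <= ``min_mean`` are dropped first; of the remainder,
    genes below the ``variance_quantile`` variance quantile (linear
    interpolation) are dropped, retaining ties at the cut.
    """
    if mat.platform != "intensity":
        raise PreprocessError("filter_intensity expects a log2 intensity matrix")
    expressed = mat.values[mat.values.mean(axis=1) > min_mean]
    if expressed.empty:
        raise PreprocessError("no gene passes the mean-expression filter")
    var = expressed.var(axis=1, ddof=1)
    cut = float(np.quantile(var.to_numpy(), variance_quantile))
    keep = var >= cut
    if not keep.any():
        raise PreprocessError("no gene passes the variance filter")
    return replace(mat, values=expressed.loc[keep])


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> float:
    """Scaling factor of ``obs`` against ``ref`` (doubly trimmed, weighted)."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos] / lib_obs, ref[pos] / lib_ref
    logratio = np.log2(o / r)
    abs_expr = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) binomial variance of M, used as inverse weight
    var = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    if logratio.size == 0 or np.max(np.abs(logratio)) < 1e-6:
        return 1.0
    n = logratio.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(logratio)
    rank_s = stats.rankdata(abs_expr)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(logratio[keep] / var[keep]) / np.sum(1.0 / var[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise PreprocessError("sample with zero library size")
    arr = counts.to_numpy(dtype=float)
    f75 = np.quantile(arr, 0.75, axis=0) / lib.to_numpy()
    ref_i = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = arr[:, ref_i]
    lib_ref = float(lib.iloc[ref_i])
    factors = np.array(
        [_tmm_pair(arr[:, j], ref, float(lib.iloc[j]), lib_ref) for j in range(arr.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_counts(mat: ExpressionMatrix) -> ExpressionMatrix:
    """TMM-normalize a filtered counts matrix and return log2(CPM + 0.5).

    CPM uses effective library sizes (library size x TMM factor).  The
    factors are stored on the result for audit.
    """
    if mat.platform != "counts":
        raise PreprocessError("normalize_counts expects a counts matrix")
    factors = tmm_factors(mat.values)
    eff_lib = mat.values.sum(axis=0).astype(float) * factors
    cpm = mat.values / eff_lib * 1e6
    logcpm = np.log2(cpm + CPM_LOG_OFFSET)
    return ExpressionMatrix(
        values=logcpm, groups=mat.groups, platform="logcpm", norm_factors=factors
    )


# ---------------------------------------------------------------------------
# Differential expression (moderated two-group t)
# ---------------------------------------------------------------------------

def _fit_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) for the variance prior.

    Under the scaled-inverse-chi-square hierarchy the observed pooled
    variances satisfy ``E[s2] = s0^2 d0/(d0-2)`` and
    ``Var[s2]/E[s2]^2 = 2 (d + d0 - 2) / (d (d0 - 4))``.  When the observed
    relative spread is no larger than that of the sampling distribution alone
    the prior df is infinite (complete shrinkage).
    """
    m = float(np.mean(s2))
    if m <= 0:
        return np.inf, m
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    r = v / m**2
    if r * d <= 2.0:
        return np.inf, m
    d0 = (4.0 * r * d + 2.0 * d - 4.0) / (r * d - 2.0)
    s02 = m * (d0 - 2.0) / d0
    return float(d0), float(s02)


def moderated_t_stats(
    logfc: np.ndarray,
    s2: np.ndarray,
    n1: int,
    n2: int,
    d0: float | None = None,
    s02: float | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated t, total df, and SE for given per-gene logFC and pooled variances.

    ``d0``/``s02`` override the method-of-moments fit (``d0 = inf`` gives the
    limiting z-like statistic with ``s0`` in place of ``s``).
    """
    d = n1 + n2 - 2
    if d0 is None or s02 is None:
        d0, s02 = _fit_prior(np.asarray(s2, dtype=float), d)
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df = np.inf
    else:
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df = d0 + d
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    return t, df, se


def differential_expression(mat: ExpressionMatrix) -> pd.DataFrame:
    """Tumor-vs-normal moderated-t differential expression table.

    Returns a DataFrame indexed by gene with columns ``logFC`` (log2,
    tumor - normal), ``t``, ``p``, ``fdr``, ``se`` and ``significant``
    (fdr < 0.05 and \\|logFC\\| >= 1).
    """
    if mat.platform == "counts":
        raise PreprocessError("normalize counts to log2 scale before DE")
    tumor = mat.values[mat.group_columns("tumor")].to_numpy(dtype=float)
    normal = mat.values[mat.group_columns("normal")].to_numpy(dtype=float)
    n1, n2 = tumor.shape[1], normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise PreprocessError("each group needs at least 2 samples")
    logfc = tumor.mean(axis=1) - normal.mean(axis=1)
    ss = tumor.var(axis=1, ddof=1) * (n1 - 1) + normal.var(axis=1, ddof=1) * (n2 - 1)
    d = n1 + n2 - 2
    s2 = ss / d
    if np.all(s2 == 0):
        warnings.warn(
            "zero within-group variance everywhere; falling back to ordinary t",
            stacklevel=2,
        )
        t = np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf)
        df = d
        se = np.zeros_like(logfc)
    else:
        t, df, se = moderated_t_stats(logfc, s2, n1, n2)
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "se": se,
            "significant": (fdr < FDR_CUTOFF) & (np.abs(logfc) >= LOGFC_CUTOFF),
        },
        index=mat.genes,
    )
    out.index.name = "gene"
    return out


def write_de(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
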