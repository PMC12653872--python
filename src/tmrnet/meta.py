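"""Cross-cohort meta-analysis: Fisher's method and fixed-effect IVW pooling.

Fisher's method combines k independent p-values into

    chi2 = -2 * sum_i ln(p_i),    chi2 ~ ChiSquare(2k)  under the null.

Consensus regulators are those whose Fisher-combined activity p-value
survives BH FDR < alpha across the regulators tested in both cohorts; the
mean NES and its cross-cohort sign concordance are reported but never used
as exclusion criteria.

Per-gene log fold-changes are pooled by common-effect inverse-variance
weighting:

    beta_meta = sum_i w_i beta_i / sum_i w_i,   w_i = 1 / SE_i^2,
    SE_meta   = 1 / sqrt(sum_i w_i),            Z = beta_meta / SE_meta.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["MetaError", "fisher_combine", "consensus_tmrs", "ivw_meta", "ivw_pool"]

CONSENSUS_ALPHA = 0.05
#: reporting threshold for the |mean NES| flag (plot-style annotation, not a filter)
MEAN_NES_FLAG = 1.0


class MetaError(ValueError):
    pass


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's chi-square statistic and combined p for k p-values.

    Zero p-values are clamped to the smallest positive double with a
    warning (permutation p-values can be exactly 0 at finite n_perm);
    values outside [0, 1] raise.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise MetaError("need at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise MetaError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to the smallest positive double", stacklevel=2)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    combined = float(stats.chi2.sf(chi2, df=2 * p.size))
    # keep the combined p in (0, 1] even when the tail underflows
    return chi2, max(combined, float(np.nextafter(0, 1)))


def consensus_tmrs(
    act_a: pd.DataFrame,
    act_b: pd.DataFrame,
    alpha: float = CONSENSUS_ALPHA,
) -> pd.DataFrame:
    """Fisher-combined consensus table over regulators scored in both cohorts.

    Input frames are :func:`tmrnet.activity.score_activity` outputs (indexed
    by regulator, columns ``nes``/``p``).  Output columns: per-cohort p and
    NES, Fisher ``chi2``, ``p_meta``, BH ``fdr``, ``mean_nes``,
    ``concordant`` (same NES sign), ``high_mean_nes`` (|mean NES| > 1,
    reporting only) and ``consensus`` (fdr < alpha).  Concordance never
    filters.
    """
    shared = act_a.index.intersection(act_b.index)
    if shared.empty:
        raise MetaError("no regulator scored in both cohorts")
    rows = []
    for reg in shared:
        chi2, p_meta = fisher_combine([act_a.loc[reg, "p"], act_b.loc[reg, "p"]])
        rows.append((reg, act_a.loc[reg, "p"], act_b.loc[reg, "p"], chi2, p_meta,
                     act_a.loc[reg, "nes"], act_b.loc[reg, "nes"]))
    out = pd.DataFrame(
        rows, columns=["regulator", "p_a", "p_b", "chi2", "p_meta", "nes_a", "nes_b"]
    ).set_index("regulator")
    out["fdr"] = multipletests(out["p_meta"].to_numpy(), method="fdr_bh")[1]
    out["mean_nes"] = (out["nes_a"] + out["nes_b"]) / 2.0
    out["concordant"] = np.sign(out["nes_a"]) == np.sign(out["nes_b"])
    out["high_mean_nes"] = out["mean_nes"].abs() > MEAN_NES_FLAG
    out["consensus"] = out["fdr"] < alpha
    return out.sort_values("fdr")


def ivw_pool(betas, ses) -> tuple[float, float, float]:
    """Pooled (beta_meta, se_meta, z) for k >= 1 effect estimates.

    With a single study this is the identity: beta_meta = beta_1 and
    z = beta_1 / SE_1.
    """
    betas = np.asarray(list(betas), dtype=float)
    ses = np.asarray(list(ses), dtype=float)
    if betas.size < 1 or betas.size != ses.size:
        raise MetaError("need k >= 1 aligned effect sizes and SEs")
    if np.any(ses <= 0):
        raise MetaError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return beta, se, beta / se


def ivw_meta(de_a: pd.DataFrame, de_b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect IVW pooling of per-gene logFC across two cohorts.

    Genes must be present in both cohorts with positive finite SE; others
    are excluded (count reported via warning).  Output columns: per-cohort
    beta/SE, ``beta_meta``, ``se_meta``, ``z``, ``p``, ``fdr`` and
    ``concordant`` (same logFC sign).
    """
    shared = de_a.index.intersection(de_b.index)
    a = de_a.loc[shared]
    b = de_b.loc[shared]
    ok = (
        (a["se"].to_numpy() > 0)
        & (b["se"].to_numpy() > 0)
        & np.isfinite(a["se"].to_numpy())
        & np.isfinite(b["se"].to_numpy())
    )
    n_excluded = len(de_a.index.union(de_b.index)) - int(ok.sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} genes excluded from IVW meta (missing or SE <= 0)",
            stacklevel=2,
        )
    a, b = a[ok], b[ok]
    if a.empty:
        raise MetaError("no gene eligible for IVW meta-analysis")
    wa = 1.0 / a["se"].to_numpy() ** 2
    wb = 1.0 / b["se"].to_numpy() ** 2
    wsum = wa + wb
    beta = (wa * a["logFC"].to_numpy() + wb * b["logFC"].to_numpy()) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(
        {
            "beta_a": a["logFC"],
            "se_a": a["se"],
            "beta_b": b["logFC"],
            "se_b": b["se"],
            "beta_meta": beta,
            "se_meta": se,
            "z": z,
            "p": p,
            "fdr": multipletests(p, method="fdr_bh")[1],
            "concordant": np.sign(a["logFC"].to_numpy())
            == np.sign(b["logFC"].to_numpy()),
        },
        index=a.index,
    )
    out.index.name = "gene"
    return out
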