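"""Over-representation analysis of the meta-regulon and individual regulons.

The meta-regulon is the union, over both cohorts, of all targets of the
consensus TMRs.  Each gene set is tested per cohort with the upper-tail
hypergeometric probability P(X >= overlap) against that cohort's universe
of expressed genes; per-set p-values are combined across cohorts with
Fisher's method and BH-adjusted.  The strict retention rule for the
meta-regulon report additionally requires per-cohort p < alpha in both
cohorts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import Regulon
from .meta import fisher_combine

__all__ = [
    "EnrichmentError",
    "read_gmt",
    "write_gmt",
    "meta_regulon",
    "ora",
    "combine_ora",
]

ORA_ALPHA = 0.05


class EnrichmentError(ValueError):
    pass


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Standard GMT reader: name, description, then tab-separated genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise EnrichmentError(f"malformed GMT line: {line[:60]!r}")
        name = fields[0]
        if name in sets:
            raise EnrichmentError(f"duplicate gene-set name {name!r}")
        genes = {g for g in fields[2:] if g}
        if not genes:
            raise EnrichmentError(f"empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def meta_regulon(
    regulons_per_cohort: list[list[Regulon]], consensus: list[str]
) -> set[str]:
    """Union over cohorts of all targets of the consensus TMRs.

    The TMRs themselves enter the set only when they appear as targets.
    """
    if not consensus:
        raise EnrichmentError("consensus list is empty")
    cons = set(consensus)
    union: set[str] = set()
    for regulons in regulons_per_cohort:
        for reg in regulons:
            if reg.regulator in cons:
                union.update(reg.targets)
    return union


def ora(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets and the query are intersected with the universe before testing;
    p = P(X >= overlap) with population = universe size, successes =
    set size in universe, draws = query size.  Sets overlapping the query
    below ``min_overlap`` get p = 1 (untested).
    """
    if not universe:
        raise EnrichmentError("empty universe")
    query = set(query) & set(universe)
    if not query:
        raise EnrichmentError("empty query after intersection with the universe")
    M, n = len(universe), len(query)
    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        K = len(members)
        k = len(members & query)
        if K == 0:
            continue
        if k >= min_overlap:
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        else:
            p = 1.0
        fold = (k / n) / (K / M)
        rows.append((name, k, K, n, M, p, fold))
    return pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size", "universe_size",
                 "p", "fold"],
    ).set_index("set_name")


def combine_ora(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    alpha: float = ORA_ALPHA,
    require_both: bool = True,
) -> pd.DataFrame:
    """Fisher-combine per-cohort ORA tables over shared gene sets.

    ``retained`` requires meta-FDR < alpha, plus per-cohort p < alpha in
    both cohorts when ``require_both`` (the strict rule used for the
    meta-regulon report; per-regulon reports set it to False).
    """
    shared = res_a.index.intersection(res_b.index)
    if shared.empty:
        raise EnrichmentError("no shared gene-set names")
    rows = []
    for name in shared:
        chi2, p_meta = fisher_combine([res_a.loc[name, "p"], res_b.loc[name, "p"]])
        rows.append(
            (name, res_a.loc[name, "p"], res_b.loc[name, "p"], chi2, p_meta,
             (res_a.loc[name, "fold"] + res_b.loc[name, "fold"]) / 2.0)
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "p_a", "p_b", "chi2", "p_meta", "mean_fold"]
    ).set_index("set_name")
    out["fdr"] = multipletests(out["p_meta"].to_numpy(), method="fdr_bh")[1]
    retained = out["fdr"] < alpha
    if require_both:
        retained &= (out["p_a"] < alpha) & (out["p_b"] < alpha)
    out["retained"] = retained
    return out.sort_values("fdr")


def bubble_matrix(per_regulon_meta: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """TMR x gene-set matrix of -log10 meta-FDR for external plotting."""
    cols: dict[str, pd.Series] = {}
    for tmr, table in sorted(per_regulon_meta.items()):
        cols[tmr] = -np.log10(table["fdr"])
    out = pd.DataFrame(cols).T
    out.index.name = "regulator"
    return out.fillna(0.0)
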