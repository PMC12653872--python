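"""Promoter motif scanning and the motif+MI-supported TMR hierarchy.

Position frequency matrices (JASPAR text format, parsed with Biopython) are
converted to log2-odds position weight matrices with a total pseudocount of
0.8 per column apportioned by the background frequencies:

    prob_b = (count_b + 0.8 * bg_b) / (colsum + 0.8),   PWM = log2(prob / bg)

One motif is kept per TF by source priority (manual-curated > automatic >
secondary collection), then by latest version.  Promoters are scanned over
both orientations of the transcription-oriented asymmetric TSS window
(width 2200: -2000/+200 on "+", -200/+2000 on "-"); a hit requires a
relative score

    (raw - min attainable) / (max attainable - min attainable) >= 0.85.

A directed TMR->TMR edge is retained only when the motif hit in the target
promoter is backed by a mutual-information edge between the pair in at
least one cohort network (dual support).  Top-of-cascade hubs are nodes
with out-degree >= Q3 of the out-degree distribution and in-degree <= Q1
of the in-degree distribution (linear-interpolation quantiles, degrees
counted over the supported edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .grn import MINetwork

__all__ = [
    "MotifError",
    "PWMotif",
    "PromoterWindow",
    "TmrGraph",
    "load_motifs",
    "scan_promoter",
    "scan_tmr_promoters",
    "promoter_windows",
    "read_fasta",
    "build_tmr_graph",
    "call_hubs",
]

WINDOW_WIDTH = 2200
UPSTREAM, DOWNSTREAM = 2000, 200
PSEUDOCOUNT_TOTAL = 0.8
MIN_REL_SCORE = 0.85
_TIER_RANK = {"manual": 0, "automatic": 1, "secondary": 2}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class MotifError(ValueError):
    pass


@dataclass
class PWMotif:
    """A log2-odds position weight matrix for one TF."""

    motif_id: str
    tf: str
    pwm: np.ndarray  # 4 x L, log2(prob / background)
    background: np.ndarray
    tier: str = "manual"

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape[0] != 4 or self.pwm.shape[1] < 4:
            raise MotifError(f"{self.motif_id}: PWM must be 4 x L with L >= 4")
        if not np.all(np.isfinite(self.pwm)):
            raise MotifError(f"{self.motif_id}: non-finite PWM cell")

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.pwm.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pwm.argmax(axis=0))

    @property
    def version(self) -> int:
        try:
            return int(self.motif_id.rsplit(".", 1)[1])
        except (IndexError, ValueError):
            return 0

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        tf: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        tier: str = "manual",
        pseudocount: float = PSEUDOCOUNT_TOTAL,
    ) -> "PWMotif":
        counts = np.asarray(counts, dtype=float)
        bg = (
            np.full(4, 0.25) if background is None
            else np.asarray(background, dtype=float)
        )
        colsum = counts.sum(axis=0)
        prob = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
        return cls(
            motif_id=motif_id, tf=tf, pwm=np.log2(prob / bg[:, None]),
            background=bg, tier=tier,
        )


def _parse_jaspar(path: str | Path, tier: str) -> list[PWMotif]:
    out = []
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            records = list(records)
        except Exception as exc:  # malformed record
            raise MotifError(f"cannot parse PFM file {path}: {exc}") from exc
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        out.append(
            PWMotif.from_counts(
                motif_id=rec.matrix_id or rec.name, tf=rec.name, counts=counts,
                tier=tier,
            )
        )
    return out


def load_motifs(pfm_files, tf_list) -> tuple[list[PWMotif], list[str]]:
    """Load PFM files and resolve exactly one motif per TF.

    ``pfm_files`` may be a single path (tier "manual"), an iterable of
    ``(path, tier)`` pairs, or a mapping tier -> path.  Selection is by
    source priority (manual > automatic > secondary), then latest version.
    Returns the chosen motifs plus the TFs with no available motif.
    """
    if isinstance(pfm_files, (str, Path)):
        sources = [(pfm_files, "manual")]
    elif isinstance(pfm_files, dict):
        sources = list((path, tier) for tier, path in pfm_files.items())
    else:
        sources = list(pfm_files)
    candidates: dict[str, list[PWMotif]] = {}
    for path, tier in sources:
        if tier not in _TIER_RANK:
            raise MotifError(f"unknown source tier {tier!r}")
        for m in _parse_jaspar(path, tier):
            candidates.setdefault(m.tf, []).append(m)
    chosen, missing = [], []
    for tf in tf_list:
        if tf not in candidates:
            missing.append(tf)
            continue
        best = min(candidates[tf], key=lambda m: (_TIER_RANK[m.tier], -m.version))
        chosen.append(best)
    return chosen, missing


# ---------------------------------------------------------------------------
# Promoter windows and scanning
# ---------------------------------------------------------------------------

@dataclass
class PromoterWindow:
    """Transcription-oriented promoter window around one TSS.

    The genomic interval is 0-based half-open: [TSS-2000, TSS+200) on "+"
    and [TSS-200, TSS+2000) on "-"; width is always 2200.  ``sequence`` is
    given 5'->3' relative to the gene.
    """

    gene: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    clipped: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.end - self.start != WINDOW_WIDTH:
            raise MotifError(f"{self.gene}: window width must be {WINDOW_WIDTH}")
        if len(self.sequence) != WINDOW_WIDTH and not self.clipped:
            raise MotifError(f"{self.gene}: sequence length != window width")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def promoter_windows(
    tss: pd.DataFrame, sequences: dict[str, str]
) -> list[PromoterWindow]:
    """Windows from a 4-column TSS table (gene, chrom, 1-based tss, strand).

    ``sequences`` maps gene id to the transcription-oriented window
    sequence (as emitted by the synthetic generator).
    """
    windows = []
    for row in tss.itertuples(index=False):
        if row.gene not in sequences:
            continue
        tss0 = int(row.tss) - 1
        if row.strand == "+":
            start, end = tss0 - UPSTREAM, tss0 + DOWNSTREAM
        else:
            start, end = tss0 - DOWNSTREAM, tss0 + UPSTREAM
        windows.append(
            PromoterWindow(
                gene=row.gene, chrom=row.chrom, strand=row.strand,
                start=start, end=end, sequence=sequences[row.gene],
            )
        )
    return windows


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.int64)
    except KeyError as exc:
        raise MotifError(f"unexpected base {exc} in promoter sequence") from exc


def _scores(codes: np.ndarray, pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Sliding-window PWM scores; N positions score the background expectation."""
    L = pwm.shape[1]
    expected = background @ pwm  # per-position expectation, used for N
    lookup = np.vstack([pwm, expected[None, :]])  # row 4 = N
    if codes.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lookup[win, np.arange(L)].sum(axis=1)


def scan_promoter(
    motif: PWMotif,
    window: PromoterWindow,
    min_rel_score: float = MIN_REL_SCORE,
) -> pd.DataFrame:
    """All hits of one motif in one promoter window, both orientations.

    Positions are 0-based offsets of the hit start within the
    transcription-oriented window; orientation "-" means the reverse
    complement of the motif matched at that locus.  Relative score is
    (raw - min attainable) / (max - min attainable).
    """
    if not 0 < min_rel_score <= 1:
        raise MotifError("min_rel_score must be in (0, 1]")
    cols = ["position", "orientation", "raw", "relative"]
    if motif.length > len(window.sequence):
        warnings.warn(
            f"motif {motif.motif_id} longer than the promoter window", stacklevel=2
        )
        return pd.DataFrame(columns=cols)
    codes = _encode(window.sequence)
    span = motif.max_score - motif.min_score
    rc_pwm = motif.pwm[::-1, ::-1]
    rows = []
    for orientation, pwm in (("+", motif.pwm), ("-", rc_pwm)):
        raw = _scores(codes, pwm, motif.background)
        rel = (raw - motif.min_score) / span
        for pos in np.nonzero(rel >= min_rel_score)[0]:
            rows.append((int(pos), orientation, float(raw[pos]), float(rel[pos])))
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["position", "orientation"]
    ).reset_index(drop=True)


def scan_tmr_promoters(
    motifs: list[PWMotif],
    windows: list[PromoterWindow],
    min_rel_score: float = MIN_REL_SCORE,
) -> pd.DataFrame:
    """Scan every motif against every promoter window.

    Returns the 7-column hit table (source_tf, target_gene, position,
    orientation, raw, relative, motif_id).
    """
    frames = []
    for m in motifs:
        for w in windows:
            hits = scan_promoter(m, w, min_rel_score)
            if hits.empty:
                continue
            hits = hits.assign(source_tf=m.tf, target_gene=w.gene, motif_id=m.motif_id)
            frames.append(hits)
    cols = ["source_tf", "target_gene", "position", "orientation", "raw",
            "relative", "motif_id"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# Dual-support graph and hubs
# ---------------------------------------------------------------------------

@dataclass
class TmrGraph:
    """Directed motif-hit edges among consensus TMRs, flagged by MI support."""

    graph: nx.DiGraph
    cohorts: list[str]

    def edges_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append(
                (u, v, d["relative"], d["position"], d["orientation"])
                + tuple(bool(d["support"][c]) for c in self.cohorts)
            )
        cols = ["source", "target", "relative", "position", "orientation"] + [
            f"mi_support_{c}" for c in self.cohorts
        ]
        return pd.DataFrame(rows, columns=cols)

    def degrees(self) -> pd.DataFrame:
        nodes = sorted(self.graph.nodes)
        return pd.DataFrame(
            {
                "out_degree": [self.graph.out_degree(n) for n in nodes],
                "in_degree": [self.graph.in_degree(n) for n in nodes],
            },
            index=pd.Index(nodes, name="node"),
        )

    def adjacency_matrix(self) -> pd.DataFrame:
        nodes = sorted(self.graph.nodes)
        mat = pd.DataFrame(0, index=nodes, columns=nodes, dtype=int)
        for u, v in self.graph.edges:
            mat.loc[u, v] = 1
        return mat


def build_tmr_graph(
    hits: pd.DataFrame,
    networks: dict[str, MINetwork],
    consensus: list[str],
) -> TmrGraph:
    """Directed TMR graph from motif hits supported by MI in >= 1 cohort.

    A hit contributes the edge source->target when both nodes are consensus
    TMRs and the (source, target) pair carries an MI edge in at least one
    cohort network; per-cohort support flags are recorded.  Multiple hits
    for one pair collapse to the best relative score.
    """
    cohorts = list(networks)
    cons = set(consensus)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(cons))
    sub = hits[hits["source_tf"].isin(cons) & hits["target_gene"].isin(cons)]
    for row in sub.itertuples(index=False):
        src, tgt = row.source_tf, row.target_gene
        support = {c: networks[c].has_pair(src, tgt) for c in cohorts}
        if not any(support.values()):
            continue
        prev = g.get_edge_data(src, tgt)
        if prev is None or row.relative > prev["relative"]:
            g.add_edge(
                src, tgt, relative=float(row.relative), position=int(row.position),
                orientation=row.orientation, support=support,
            )
    return TmrGraph(graph=g, cohorts=cohorts)


def call_hubs(graph: TmrGraph, include_isolated: bool = True) -> pd.DataFrame:
    """Top-of-cascade hub table by the degree-quantile rule.

    A node is a hub iff out-degree >= Q3 of the out-degree distribution and
    in-degree <= Q1 of the in-degree distribution (linear-interpolation
    quantiles over all nodes, or only connected nodes when
    ``include_isolated`` is False).  Sorted by out-degree descending then
    in-degree ascending.
    """
    deg = graph.degrees()
    if deg.empty:
        raise MotifError("graph has no nodes")
    if not include_isolated:
        deg = deg[(deg["out_degree"] > 0) | (deg["in_degree"] > 0)]
        if deg.empty:
            warnings.warn("no connected node; no hubs called", stacklevel=2)
            return deg.assign(out_q3=[], in_q1=[], is_hub=[])
    out_deg = deg["out_degree"].to_numpy(dtype=float)
    in_deg = deg["in_degree"].to_numpy(dtype=float)
    if graph.graph.number_of_edges() == 0:
        warnings.warn("empty edge set; no hubs called", stacklevel=2)
    q3 = float(np.quantile(out_deg, 0.75))
    q1 = float(np.quantile(in_deg, 0.25))
    if out_deg.size and np.all(out_deg == out_deg[0]) and np.all(in_deg == in_deg[0]):
        warnings.warn(
            "all degrees equal; every node satisfies the hub bounds", stacklevel=2
        )
    table = deg.assign(
        out_q3=q3,
        in_q1=q1,
        is_hub=(deg["out_degree"] >= q3) & (deg["in_degree"] <= q1)
        & (graph.graph.number_of_edges() > 0),
    )
    return table.sort_values(
        ["out_degree", "in_degree"], ascending=[False, True]
    )
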