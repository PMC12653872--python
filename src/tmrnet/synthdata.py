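"""Synthetic two-cohort expression data with planted regulatory ground truth.

The generator emulates the statistical structure the downstream analysis
assumes — without any external download:

* a set of transcription factors (TFs), each with a latent per-sample
  activity ``a ~ Normal(0, 1)``;
* a subset of "active" TFs whose activity is shifted in tumor samples by a
  configurable amount expressed in units of the noise SD;
* planted regulons: each TF drives a disjoint block of target genes with a
  signed strength, target log-expression = sum over regulating TFs of
  ``sign * strength * a`` plus Gaussian noise;
* a TF->TF hierarchy: a few downstream TFs have their latent activity
  coupled to an upstream (active) TF, and the upstream TF's binding-motif
  consensus is planted in the downstream TF's promoter, so both the
  mutual-information edge and the motif hit of a top-of-cascade regulator
  are recoverable;
* two platforms: a counts cohort (negative-binomial counts at a sampled
  sequencing depth) and a log-intensity cohort (Gaussian on the log2 scale);
* promoters: i.i.d. uniform A/C/G/T background over the full asymmetric TSS
  window (width 2200), with planted consensus sites overwriting the
  background (reverse-complemented on the minus strand).

TF mRNA is emitted as a noisy readout of the latent activity (correlation
``tf_readout_corr``), so networks can be inferred from expression alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SynthError",
    "simulate_cohorts",
    "emit_promoters",
    "emit_gene_sets",
    "write_jaspar_pfm",
]

PROMOTER_WIDTH = 2200
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SynthError(ValueError):
    """Configuration or generation error in the synthetic module."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the two synthetic cohorts.

    Defaults are the desk-scale conditions used throughout the test suite:
    200 genes, 10 TFs with 18 targets each, 3 active TFs shifted by 2.0
    noise-SD units in tumors, 30+30 samples per cohort.
    """

    n_genes: int = 200
    n_tfs: int = 10
    targets_per_tf: int = 18
    n_active: int = 3
    activity_shift: float = 2.0
    n_tf_edges: int = 2
    n_tumor_a: int = 30
    n_normal_a: int = 30
    n_tumor_b: int = 30
    n_normal_b: int = 30
    noise_sd_a: float = 0.5
    noise_sd_b: float = 0.5
    platform_a: str = "counts"
    platform_b: str = "intensity"
    depth_mean: float = 1e6
    depth_cv: float = 0.15
    dispersion: float = 0.1
    tf_readout_corr: float = 0.95
    strength_min: float = 0.6
    strength_max: float = 1.0
    positive_sign_prob: float = 0.7
    promoter_length: int = PROMOTER_WIDTH
    motif_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_tfs,
            self.targets_per_tf,
            self.n_tumor_a,
            self.n_normal_a,
            self.n_tumor_b,
            self.n_normal_b,
            self.promoter_length,
            self.motif_length,
        )
        if any(c <= 0 for c in counts):
            raise SynthError("all counts must be positive")
        if self.targets_per_tf * self.n_tfs > self.n_genes:
            raise SynthError(
                f"targets_per_tf * n_tfs = {self.targets_per_tf * self.n_tfs} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.n_active > self.n_tfs:
            raise SynthError("n_active exceeds n_tfs")
        max_edges = self.n_active * (self.n_active - 1) // 2
        if self.n_tf_edges > max_edges:
            raise SynthError(
                "n_tf_edges exceeds the acyclic pairs available among active TFs"
            )
        if not 0 < self.tf_readout_corr <= 1:
            raise SynthError("tf_readout_corr must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted network, activities and motif instances behind both cohorts."""

    regulators: list[str]
    #: TF -> list of (target id, sign in {-1,+1}, strength in (0,1])
    regulons: dict[str, list[tuple[str, int, float]]]
    #: active TF -> tumor activity shift (units of noise SD)
    active_tfs: dict[str, float]
    #: (target gene, motif id, promoter offset, strand)
    planted_sites: list[tuple[str, str, int, str]]
    #: gene -> (chrom, 1-based TSS position, strand)
    tss_table: dict[str, tuple[str, int, str]]
    #: TF -> (motif id, consensus, counts matrix rows A/C/G/T)
    motifs: dict[str, tuple[str, str, list[list[int]]]]
    #: cohort label -> latent TF activity (TF x sample)
    latent_activity: dict[str, pd.DataFrame] = field(default_factory=dict)

    def targets_of(self, tf: str) -> set[str]:
        return {t for t, _, _ in self.regulons[tf]}

    def planted_pairs(self) -> set[tuple[str, str]]:
        """All planted directed regulator->target pairs."""
        return {
            (tf, tgt) for tf, targets in self.regulons.items() for tgt, _, _ in targets
        }

    def tf_edges(self) -> set[tuple[str, str]]:
        """Planted TF->TF (hierarchy) pairs."""
        regs = set(self.regulators)
        return {(a, b) for a, b in self.planted_pairs() if b in regs}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["latent_activity"] = {
            k: {"index": list(df.index), "columns": list(df.columns), "data": df.to_numpy().tolist()}
            for k, df in self.latent_activity.items()
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        latent = {
            k: pd.DataFrame(v["data"], index=v["index"], columns=v["columns"])
            for k, v in payload["latent_activity"].items()
        }
        return cls(
            regulators=payload["regulators"],
            regulons={
                tf: [tuple(t) for t in targets]
                for tf, targets in payload["regulons"].items()
            },
            active_tfs=payload["active_tfs"],
            planted_sites=[tuple(s) for s in payload["planted_sites"]],
            tss_table={g: tuple(v) for g, v in payload["tss_table"].items()},
            motifs={tf: (m[0], m[1], m[2]) for tf, m in payload["motifs"].items()},
            latent_activity=latent,
        )


# ---------------------------------------------------------------------------
# Ground-truth construction
# ---------------------------------------------------------------------------

def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    others = [f"G{i + 1:04d}" for i in range(config.n_tfs, config.n_genes)]
    return tfs, others


def _make_motifs(config: SimulationConfig, rng: np.random.Generator, tfs: list[str]):
    motifs: dict[str, tuple[str, str, list[list[int]]]] = {}
    for i, tf in enumerate(tfs):
        consensus_idx = rng.integers(0, 4, size=config.motif_length)
        counts = np.ones((4, config.motif_length), dtype=int)
        counts[consensus_idx, np.arange(config.motif_length)] = 17
        consensus = "".join(_BASES[b] for b in consensus_idx)
        motifs[tf] = (f"MT{i + 1:04d}.1", consensus, counts.tolist())
    return motifs


def _build_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    tfs, others = _gene_ids(config)
    active = {tf: config.activity_shift for tf in tfs[: config.n_active]}
    non_active = tfs[config.n_active :]

    def draw_edge(target: str) -> tuple[str, int, float]:
        sign = 1 if rng.random() < config.positive_sign_prob else -1
        strength = float(rng.uniform(config.strength_min, config.strength_max))
        return (target, sign, strength)

    regulons: dict[str, list[tuple[str, int, float]]] = {tf: [] for tf in tfs}
    # hierarchy: acyclic TF->TF edges among the active TFs, so the source
    # sits at the top of a cascade of regulators that are themselves
    # consensus-eligible (shifted) — coupling acts on the centered activity
    # component, the tumor shift stays per-TF (see _simulate_cohort)
    del non_active
    active_list = list(active)
    pairs = [
        (active_list[i], active_list[j])
        for i in range(len(active_list))
        for j in range(i + 1, len(active_list))
    ]
    tf_edges: list[tuple[str, str]] = []
    for e in range(config.n_tf_edges):
        src, dst = pairs[e]
        regulons[src].append(draw_edge(dst))
        tf_edges.append((src, dst))
    # fill the remaining quota from a shuffled pool of non-TF genes
    pool = list(others)
    rng.shuffle(pool)
    pos = 0
    for tf in tfs:
        need = config.targets_per_tf - len(regulons[tf])
        if pos + need > len(pool):
            raise SynthError("not enough non-TF genes to fill all regulons")
        for g in pool[pos : pos + need]:
            regulons[tf].append(draw_edge(g))
        pos += need

    # TSS table and planted promoter sites for hierarchy edges
    tss_table = {
        tf: ("chr1", 100_000 + 10_000 * i, "+" if i % 2 == 0 else "-")
        for i, tf in enumerate(tfs)
    }
    motifs = _make_motifs(config, rng, tfs)
    planted_sites = []
    for src, dst in tf_edges:
        motif_id, consensus, _ = motifs[src]
        offset = int(rng.integers(0, config.promoter_length - len(consensus) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        planted_sites.append((dst, motif_id, offset, strand))

    return GroundTruth(
        regulators=tfs,
        regulons=regulons,
        active_tfs=active,
        planted_sites=planted_sites,
        tss_table=tss_table,
        motifs=motifs,
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def _simulate_cohort(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    label: str,
    n_tumor: int,
    n_normal: int,
    noise_sd: float,
    platform: str,
) -> ExpressionMatrix:
    tfs = truth.regulators
    genes = tfs + [g for g in _gene_ids(config)[1]]
    n = n_tumor + n_normal
    samples = [f"{label}_T{i + 1:03d}" for i in range(n_tumor)] + [
        f"{label}_N{i + 1:03d}" for i in range(n_normal)
    ]
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    is_tumor = np.array([1.0] * n_tumor + [0.0] * n_normal)

    # latent activities: base normals, hierarchy coupling on the centered
    # component (variance-preserving, applied in cascade order), then the
    # per-TF tumor shift — coupling carries fluctuations, not the shift
    act = {tf: rng.normal(size=n) for tf in tfs}
    for src, dst in sorted(truth.tf_edges()):
        _, sign, strength = next(e for e in truth.regulons[src] if e[0] == dst)
        resid = np.sqrt(max(1.0 - strength**2, 0.0))
        act[dst] = sign * strength * act[src] + resid * rng.normal(size=n)
    for tf, shift in truth.active_tfs.items():
        act[tf] = act[tf] + shift * is_tumor

    regulators_of: dict[str, list[tuple[str, int, float]]] = {}
    for tf, targets in truth.regulons.items():
        for tgt, sign, strength in targets:
            regulators_of.setdefault(tgt, []).append((tf, sign, strength))

    rho = config.tf_readout_corr
    x = np.zeros((len(genes), n))
    for i, g in enumerate(genes):
        if g in act:
            row = rho * act[g] + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
        else:
            row = np.zeros(n)
            for tf, sign, strength in regulators_of.get(g, []):
                row = row + sign * strength * act[tf]
            if noise_sd > 0:
                row = row + rng.normal(scale=noise_sd, size=n)
        x[i] = row

    truth.latent_activity[label] = pd.DataFrame(
        np.vstack([act[tf] for tf in tfs]), index=tfs, columns=samples
    )

    if platform == "counts":
        baseline = rng.normal(loc=5.0, scale=1.5, size=len(genes))
        rel = np.power(2.0, x + baseline[:, None])
        frac = rel / rel.sum(axis=0, keepdims=True)
        depth = rng.lognormal(
            mean=np.log(config.depth_mean), sigma=config.depth_cv, size=n
        )
        mu = frac * depth[None, :]
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            values = rng.negative_binomial(r, r / (r + mu))
        else:
            values = rng.poisson(mu)
        df = pd.DataFrame(values, index=genes, columns=samples)
    elif platform == "intensity":
        baseline = rng.normal(loc=7.0, scale=1.0, size=len(genes))
        df = pd.DataFrame(x + baseline[:, None], index=genes, columns=samples)
    else:
        raise SynthError(f"unknown platform kind: {platform!r}")
    df.index.name = "gene"
    return ExpressionMatrix(values=df, groups=groups, platform=platform)


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate the two cohorts driven by one shared ground-truth network.

    Cohorts get independent samples (patients) and cohort-specific noise and
    platform; the regulons, signs, strengths and active-TF shifts are shared.
    Fixing ``config.seed`` makes the output bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    truth = _build_truth(config, rng)
    mat_a = _simulate_cohort(
        truth, config, rng, "A", config.n_tumor_a, config.n_normal_a,
        config.noise_sd_a, config.platform_a,
    )
    mat_b = _simulate_cohort(
        truth, config, rng, "B", config.n_tumor_b, config.n_normal_b,
        config.noise_sd_b, config.platform_b,
    )
    return mat_a, mat_b, truth


# ---------------------------------------------------------------------------
# Promoters, motif files, gene sets
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def emit_promoters(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoter sequences (transcription-oriented, full window) and TSS table.

    Background is i.i.d. uniform over A/C/G/T; planted sites overwrite the
    background with the motif consensus (reverse complement on "-" strand).
    """
    if not truth.motifs:
        raise SynthError("motif set is empty")
    rng = np.random.default_rng(config.seed + 101)
    width = config.promoter_length
    seqs: dict[str, list[str]] = {}
    for gene in truth.tss_table:
        seqs[gene] = list("".join(_BASES[b] for b in rng.integers(0, 4, size=width)))
    consensus_by_id = {m_id: cons for m_id, cons, _ in truth.motifs.values()}
    for gene, motif_id, offset, strand in truth.planted_sites:
        cons = consensus_by_id[motif_id]
        if offset < 0 or offset + len(cons) > width:
            raise SynthError(
                f"planted site for {gene} at offset {offset} falls outside the window"
            )
        site = cons if strand == "+" else reverse_complement(cons)
        seqs[gene][offset : offset + len(site)] = list(site)
    tss = pd.DataFrame(
        [(g, c, p, s) for g, (c, p, s) in truth.tss_table.items()],
        columns=["gene", "chrom", "tss", "strand"],
    )
    return {g: "".join(s) for g, s in seqs.items()}, tss


def write_promoters(seqs: dict[str, str], tss: pd.DataFrame, fasta_path, tss_path) -> None:
    with open(fasta_path, "w") as fh:
        for gene, seq in seqs.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    tss.to_csv(tss_path, sep="\t", index=False)


def write_jaspar_pfm(truth: GroundTruth, path: str | Path) -> None:
    """Write the planted motif set in JASPAR text PFM format."""
    with open(path, "w") as fh:
        for tf, (motif_id, _, counts) in truth.motifs.items():
            fh.write(f">{motif_id} {tf}\n")
            for base, row in zip(_BASES, counts):
                cells = " ".join(str(c) for c in row)
                fh.write(f"{base} [ {cells} ]\n")


def emit_gene_sets(
    truth: GroundTruth, config: SimulationConfig, n_decoys: int = 10, decoy_size: int = 25
) -> dict[str, set[str]]:
    """Gene-set collection built from the ground truth plus random decoy sets.

    One set per planted regulon (its target genes) named ``REGULON_<TF>``,
    plus ``n_decoys`` sets of ``decoy_size`` genes drawn uniformly from the
    gene universe — stand-ins for hallmark/pathway collections.
    """
    rng = np.random.default_rng(config.seed + 202)
    tfs, others = _gene_ids(config)
    universe = np.array(tfs + others)
    sets: dict[str, set[str]] = {
        f"REGULON_{tf}": truth.targets_of(tf) for tf in truth.regulators
    }
    for i in range(n_decoys):
        sets[f"DECOY_{i + 1:02d}"] = set(
            rng.choice(universe, size=min(decoy_size, len(universe)), replace=False)
        )
    return sets
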