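"""End-to-end orchestration: simulate -> analyze -> report.

Stages (in dependency order): ``simulate``, ``de``, ``network``,
``activity``, ``meta``, ``motifscan``, ``graph``, ``hubs``, ``ora``,
``sweep``.  Every stage writes its artifacts under its own subdirectory of
the output directory and records an entry (stage, parameters, seed, input
checksums, outputs) in ``manifest.json``.  Re-runs skip stages whose
outputs exist and whose parameter/input fingerprints are unchanged, unless
forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import activity as _activity
from . import enrichment as _enrichment
from . import grn as _grn
from . import meta as _meta
from . import motifs as _motifs
from . import preprocess as _pre
from . import robustness as _robustness
from . import synthdata as _synth

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run", "STAGES"]

log = logging.getLogger("tmrnet")

STAGES = [
    "simulate", "de", "network", "activity", "meta", "motifscan", "graph",
    "hubs", "ora", "sweep",
]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat parameter set for a full synthetic run.

    Network p-cutoffs default to 1e-4 for both cohorts — the lenient
    threshold appropriate for small cohorts; large cohorts would use a
    stricter cutoff (1e-8), configurable per cohort.
    """

    out_dir: str = "tmrnet_run"
    seed: int = 0
    # simulation (see SimulationConfig for the remaining study conditions)
    n_genes: int = 200
    n_tfs: int = 10
    targets_per_tf: int = 18
    n_active: int = 3
    activity_shift: float = 2.0
    # analysis
    p_cutoff_a: float = 1e-4
    p_cutoff_b: float = 1e-4
    n_boot: int = 50
    n_null: int = 100_000
    min_regulon_size: int = 10
    n_perm: int = 1000
    alpha: float = 0.05
    min_rel_score: float = 0.85
    sweep_grid: list = field(
        default_factory=lambda: [list(c) for c in _robustness.DEFAULT_GRID]
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except Exception as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def override(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)

    def simulation_config(self) -> _synth.SimulationConfig:
        try:
            return _synth.SimulationConfig(
                n_genes=self.n_genes, n_tfs=self.n_tfs,
                targets_per_tf=self.targets_per_tf, n_active=self.n_active,
                activity_shift=self.activity_shift, seed=self.seed,
            )
        except _synth.SynthError as exc:
            raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.entries: dict[str, dict] = {}
        if self.path.exists():
            self.entries = json.loads(self.path.read_text())

    def fingerprint(self, params: dict, inputs: list[Path]) -> dict:
        return {
            "params": {k: repr(v) for k, v in sorted(params.items())},
            "inputs": {str(p): _sha256(p) for p in inputs},
        }

    def up_to_date(self, stage: str, fp: dict, outputs: list[Path]) -> bool:
        entry = self.entries.get(stage)
        if entry is None:
            return False
        if entry["params"] != fp["params"] or entry["inputs"] != fp["inputs"]:
            return False
        return all(p.exists() for p in outputs)

    def record(self, stage: str, fp: dict, outputs: list[Path], seed: int) -> None:
        self.entries[stage] = {
            **fp,
            "seed": seed,
            "outputs": [str(p) for p in outputs],
        }
        self.path.write_text(json.dumps(self.entries, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

class _Runner:
    def __init__(self, config: PipelineConfig, force: bool = False):
        self.cfg = config
        self.force = force
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = _Manifest(self.out)

    def _dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _execute(self, stage: str, params: dict, inputs: list[Path],
                 outputs: list[Path], fn) -> None:
        for p in inputs:
            if not p.exists():
                raise StageError(
                    f"stage {stage}: missing input {p}; run the producing stage first"
                )
        fp = self.manifest.fingerprint(params, inputs)
        if not self.force and self.manifest.up_to_date(stage, fp, outputs):
            log.info("stage %s up to date; skipped", stage)
            return
        t0 = time.monotonic()
        fn()
        self.manifest.record(stage, fp, outputs, self.cfg.seed)
        log.info("stage %s done in %.1fs", stage, time.monotonic() - t0)

    # -- artifact paths ---------------------------------------------------
    def paths(self) -> dict[str, Path]:
        sim, de = self._dir("simulate"), self._dir("de")
        net, act = self._dir("network"), self._dir("activity")
        meta, scan = self._dir("meta"), self._dir("motifscan")
        graph, hubs = self._dir("graph"), self._dir("hubs")
        ora = self._dir("ora")
        return {
            "expr_a": sim / "cohortA_counts.tsv",
            "samples_a": sim / "cohortA_samples.tsv",
            "expr_b": sim / "cohortB_intensity.tsv",
            "samples_b": sim / "cohortB_samples.tsv",
            "truth": sim / "ground_truth.json",
            "regulators": sim / "regulators.txt",
            "promoters": sim / "promoters.fa",
            "tss": sim / "tss.tsv",
            "pfm": sim / "motifs.jaspar",
            "gmt": sim / "gene_sets.gmt",
            "norm_a": de / "norm_a.tsv",
            "norm_b": de / "norm_b.tsv",
            "de_a": de / "de_a.tsv",
            "de_b": de / "de_b.tsv",
            "net_a": net / "net_a.tsv",
            "net_b": net / "net_b.tsv",
            "regulons_a": act / "regulons_a.tsv",
            "regulons_b": act / "regulons_b.tsv",
            "act_a": act / "activity_a.tsv",
            "act_b": act / "activity_b.tsv",
            "meta_regulators": meta / "meta_regulators.tsv",
            "consensus": meta / "consensus_tmrs.txt",
            "effect_meta": meta / "effect_meta.tsv",
            "tmr_effect": meta / "tmr_effect_meta.tsv",
            "hits": scan / "hits.tsv",
            "no_motif": scan / "no_motif.txt",
            "tmr_edges": graph / "tmr_edges.tsv",
            "adjacency": graph / "adjacency.tsv",
            "hub_table": hubs / "hubs.tsv",
            "ora_meta": ora / "meta_regulon_ora.tsv",
            "ora_per_regulon": ora / "per_regulon_ora.tsv",
            "bubble": ora / "bubble_matrix.tsv",
            "sweep_dir": self.out / "sweep",
        }

    # -- loaders -----------------------------------------------------------
    def _load_norm(self, p: dict) -> tuple[_pre.ExpressionMatrix, _pre.ExpressionMatrix]:
        a = _pre.ExpressionMatrix.from_tsv(p["norm_a"], p["samples_a"], "logcpm")
        b = _pre.ExpressionMatrix.from_tsv(p["norm_b"], p["samples_b"], "intensity")
        return a, b

    def _load_networks(self, p: dict) -> dict[str, _grn.MINetwork]:
        regs = p["regulators"].read_text().split()
        return {
            "a": _grn.MINetwork.from_tsv(p["net_a"], regs, self.cfg.p_cutoff_a,
                                         self.cfg.n_boot),
            "b": _grn.MINetwork.from_tsv(p["net_b"], regs, self.cfg.p_cutoff_b,
                                         self.cfg.n_boot),
        }

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        p = self.paths()
        cfg = self.cfg.simulation_config()

        def fn():
            mat_a, mat_b, truth = _synth.simulate_cohorts(cfg)
            mat_a.to_tsv(p["expr_a"], p["samples_a"])
            mat_b.to_tsv(p["expr_b"], p["samples_b"])
            truth.to_json(p["truth"])
            p["regulators"].write_text("\n".join(truth.regulators) + "\n")
            seqs, tss = _synth.emit_promoters(truth, cfg)
            _synth.write_promoters(seqs, tss, p["promoters"], p["tss"])
            _synth.write_jaspar_pfm(truth, p["pfm"])
            _enrichment.write_gmt(_synth.emit_gene_sets(truth, cfg), p["gmt"])

        self._execute(
            "simulate", dataclasses.asdict(cfg), [],
            [p["expr_a"], p["expr_b"], p["truth"], p["promoters"], p["pfm"],
             p["gmt"], p["regulators"]],
            fn,
        )

    def de(self) -> None:
        p = self.paths()

        def fn():
            mat_a = _pre.ExpressionMatrix.from_tsv(p["expr_a"], p["samples_a"], "counts")
            mat_a = _pre.normalize_counts(_pre.filter_counts(mat_a))
            mat_a.to_tsv(p["norm_a"], p["samples_a"])
            mat_b = _pre.ExpressionMatrix.from_tsv(p["expr_b"], p["samples_b"], "intensity")
            mat_b = _pre.filter_intensity(mat_b)
            mat_b.to_tsv(p["norm_b"], p["samples_b"])
            _pre.write_de(_pre.differential_expression(mat_a), p["de_a"])
            _pre.write_de(_pre.differential_expression(mat_b), p["de_b"])

        self._execute(
            "de", {}, [p["expr_a"], p["expr_b"]],
            [p["norm_a"], p["norm_b"], p["de_a"], p["de_b"]], fn,
        )

    def network(self) -> None:
        p = self.paths()
        cfg = self.cfg

        def fn():
            mat_a, mat_b = self._load_norm(p)
            regs = p["regulators"].read_text().split()
            for mat, cutoff, out, off in (
                (mat_a, cfg.p_cutoff_a, p["net_a"], 0),
                (mat_b, cfg.p_cutoff_b, p["net_b"], 500),
            ):
                net = _grn.consolidate_bootstraps(
                    mat, regs, cutoff, n_boot=cfg.n_boot, seed=cfg.seed + off,
                    n_null=cfg.n_null,
                )
                net.to_tsv(out)

        self._execute(
            "network",
            {"p_cutoff_a": cfg.p_cutoff_a, "p_cutoff_b": cfg.p_cutoff_b,
             "n_boot": cfg.n_boot, "seed": cfg.seed},
            [p["norm_a"], p["norm_b"], p["regulators"]],
            [p["net_a"], p["net_b"]], fn,
        )

    def activity(self) -> None:
        p = self.paths()
        cfg = self.cfg

        def fn():
            mat_a, mat_b = self._load_norm(p)
            nets = self._load_networks(p)
            for mat, net, reg_out, act_out, off in (
                (mat_a, nets["a"], p["regulons_a"], p["act_a"], 0),
                (mat_b, nets["b"], p["regulons_b"], p["act_b"], 500),
            ):
                regulons = _activity.build_regulons(
                    net, mat, min_size=cfg.min_regulon_size
                )
                _activity.write_regulons(regulons, reg_out)
                sig = _pre.read_de(p["de_a"] if off == 0 else p["de_b"])
                act = _activity.score_activity(
                    regulons, sig, n_perm=cfg.n_perm, seed=cfg.seed + 7 + off,
                    mat=mat,
                )
                act.to_csv(act_out, sep="\t")

        self._execute(
            "activity",
            {"min_regulon_size": cfg.min_regulon_size, "n_perm": cfg.n_perm,
             "seed": cfg.seed},
            [p["net_a"], p["net_b"], p["de_a"], p["de_b"]],
            [p["regulons_a"], p["regulons_b"], p["act_a"], p["act_b"]], fn,
        )

    def meta(self) -> None:
        p = self.paths()
        cfg = self.cfg

        def fn():
            act_a = pd.read_csv(p["act_a"], sep="\t", index_col="regulator")
            act_b = pd.read_csv(p["act_b"], sep="\t", index_col="regulator")
            table = _meta.consensus_tmrs(act_a, act_b, alpha=cfg.alpha)
            table.to_csv(p["meta_regulators"], sep="\t")
            consensus = sorted(table.index[table["consensus"]])
            p["consensus"].write_text("\n".join(consensus) + "\n")
            de_a, de_b = _pre.read_de(p["de_a"]), _pre.read_de(p["de_b"])
            effect = _meta.ivw_meta(de_a, de_b)
            # Fisher combination of the per-cohort DE p-values alongside IVW
            shared = effect.index
            fisher = [
                _meta.fisher_combine([de_a.loc[g, "p"], de_b.loc[g, "p"]])
                for g in shared
            ]
            effect["fisher_chi2"] = [f[0] for f in fisher]
            effect["fisher_p"] = [f[1] for f in fisher]
            effect.to_csv(p["effect_meta"], sep="\t")
            effect.loc[effect.index.intersection(consensus)].to_csv(
                p["tmr_effect"], sep="\t"
            )

        self._execute(
            "meta", {"alpha": cfg.alpha},
            [p["act_a"], p["act_b"], p["de_a"], p["de_b"]],
            [p["meta_regulators"], p["consensus"], p["effect_meta"],
             p["tmr_effect"]], fn,
        )

    def motifscan(self) -> None:
        p = self.paths()
        cfg = self.cfg

        def fn():
            consensus = p["consensus"].read_text().split()
            motifs, missing = _motifs.load_motifs(p["pfm"], consensus)
            p["no_motif"].write_text("\n".join(missing) + ("\n" if missing else ""))
            tss = pd.read_csv(p["tss"], sep="\t")
            seqs = _motifs.read_fasta(p["promoters"])
            windows = _motifs.promoter_windows(
                tss[tss["gene"].isin(consensus)], seqs
            )
            hits = _motifs.scan_tmr_promoters(
                motifs, windows, min_rel_score=cfg.min_rel_score
            )
            hits.to_csv(p["hits"], sep="\t", index=False)

        self._execute(
            "motifscan", {"min_rel_score": cfg.min_rel_score},
            [p["consensus"], p["pfm"], p["promoters"], p["tss"]],
            [p["hits"], p["no_motif"]], fn,
        )

    def graph(self) -> None:
        p = self.paths()

        def fn():
            hits = pd.read_csv(p["hits"], sep="\t")
            nets = self._load_networks(p)
            consensus = p["consensus"].read_text().split()
            g = _motifs.build_tmr_graph(hits, nets, consensus)
            g.edges_table().to_csv(p["tmr_edges"], sep="\t", index=False)
            g.adjacency_matrix().to_csv(p["adjacency"], sep="\t")

        self._execute(
            "graph", {}, [p["hits"], p["net_a"], p["net_b"], p["consensus"]],
            [p["tmr_edges"], p["adjacency"]], fn,
        )

    def hubs(self) -> None:
        p = self.paths()

        def fn():
            hits = pd.read_csv(p["hits"], sep="\t")
            nets = self._load_networks(p)
            consensus = p["consensus"].read_text().split()
            if not consensus:
                pd.DataFrame(
                    columns=["out_degree", "in_degree", "out_q3", "in_q1",
                             "is_hub"]
                ).to_csv(p["hub_table"], sep="\t", index_label="node")
                return
            g = _motifs.build_tmr_graph(hits, nets, consensus)
            _motifs.call_hubs(g).to_csv(p["hub_table"], sep="\t")

        self._execute(
            "hubs", {}, [p["hits"], p["net_a"], p["net_b"], p["consensus"]],
            [p["hub_table"]], fn,
        )

    def ora(self) -> None:
        p = self.paths()
        cfg = self.cfg

        def fn():
            collection = _enrichment.read_gmt(p["gmt"])
            consensus = p["consensus"].read_text().split()
            if not consensus:
                for out in (p["ora_meta"], p["ora_per_regulon"], p["bubble"]):
                    out.write_text("")
                return
            regs_a = _activity.read_regulons(p["regulons_a"])
            regs_b = _activity.read_regulons(p["regulons_b"])
            mat_a, mat_b = self._load_norm(p)
            uni_a, uni_b = set(mat_a.genes), set(mat_b.genes)
            query = _enrichment.meta_regulon([regs_a, regs_b], consensus)
            res_a = _enrichment.ora(query & uni_a, collection, uni_a)
            res_b = _enrichment.ora(query & uni_b, collection, uni_b)
            _enrichment.combine_ora(res_a, res_b, alpha=cfg.alpha).to_csv(
                p["ora_meta"], sep="\t"
            )
            # per-regulon ORA (meta-FDR rule only)
            per_meta: dict[str, pd.DataFrame] = {}
            frames = []
            by_a = {r.regulator: set(r.targets) for r in regs_a}
            by_b = {r.regulator: set(r.targets) for r in regs_b}
            for tmr in consensus:
                qa, qb = by_a.get(tmr, set()) & uni_a, by_b.get(tmr, set()) & uni_b
                if not qa or not qb:
                    continue
                ra = _enrichment.ora(qa, collection, uni_a)
                rb = _enrichment.ora(qb, collection, uni_b)
                combined = _enrichment.combine_ora(
                    ra, rb, alpha=cfg.alpha, require_both=False
                )
                per_meta[tmr] = combined
                frames.append(combined.assign(regulator=tmr))
            if frames:
                pd.concat(frames).to_csv(p["ora_per_regulon"], sep="\t")
                _enrichment.bubble_matrix(per_meta).to_csv(p["bubble"], sep="\t")
            else:
                p["ora_per_regulon"].write_text("")
                p["bubble"].write_text("")

        self._execute(
            "ora", {"alpha": cfg.alpha},
            [p["gmt"], p["consensus"], p["regulons_a"], p["regulons_b"],
             p["norm_a"], p["norm_b"]],
            [p["ora_meta"], p["ora_per_regulon"], p["bubble"]], fn,
        )

    def sweep(self) -> None:
        p = self.paths()
        cfg = self.cfg
        out_dir = p["sweep_dir"]

        def fn():
            mat_a, mat_b = self._load_norm(p)
            sig_a, sig_b = _pre.read_de(p["de_a"]), _pre.read_de(p["de_b"])
            regs = p["regulators"].read_text().split()
            grid = [tuple(c) for c in cfg.sweep_grid]
            result = _robustness.sweep(
                mat_a, mat_b, sig_a, sig_b, regs, grid=grid, seed=cfg.seed,
                min_size=cfg.min_regulon_size, n_perm=cfg.n_perm, alpha=cfg.alpha,
            )
            result.write(out_dir)

        self._execute(
            "sweep", {"grid": cfg.sweep_grid, "seed": cfg.seed},
            [p["norm_a"], p["norm_b"], p["de_a"], p["de_b"], p["regulators"]],
            [out_dir / "jaccard.tsv", out_dir / "spearman.tsv",
             out_dir / "persistence.tsv"], fn,
        )


def run(
    config: PipelineConfig,
    stages: list[str] | None = None,
    force: bool = False,
) -> Path:
    """Execute the requested stages (default: all) in dependency order.

    Returns the output directory.  Raises :class:`ConfigError` for invalid
    configuration and :class:`StageError` when a stage fails or a required
    upstream artifact is missing.
    """
    wanted = list(STAGES) if not stages else list(stages)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    config.simulation_config()  # validate early
    runner = _Runner(config, force=force)
    for stage in STAGES:
        if stage not in wanted:
            continue
        try:
            getattr(runner, stage)()
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
    return runner.out
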