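"""End-to-end orchestration: config validation, staged execution, manifest.

A run is described by a single YAML/dict config; every methods constant
(coverage thresholds, window geometry, significance and delta cutoffs) is a
named parameter with the standard analysis value as default. Stages execute
in order io -> bin -> dmr -> enrich -> integrate, each logging its record
counts into a manifest, and a rerun with identical inputs reproduces
identical outputs (the only randomness lives in the simulator behind an
explicit seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from longmeth import __version__, binning, comparative, dmr, enrichment, integration
from longmeth import io as mio
from longmeth import simulate as sim

log = logging.getLogger("longmeth")

DEFAULTS = {
    "window": 50,
    "step": 25,
    "alpha": 0.05,
    "min_delta": 10.0,
    "min_cov": 3,
    "density_window_bp": 25_000,
    "stringency": 10.0,
    "correction": "BH",
}


@dataclass
class RunConfig:
    outdir: str
    samples: list[dict] = field(default_factory=list)  # {id, group, path}
    contrast: tuple[str, str] | None = None
    simulate: dict | None = None  # SimulationConfig overrides; triggers simulation
    genes: str | None = None
    expression: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)
    window: int = DEFAULTS["window"]
    step: int = DEFAULTS["step"]
    alpha: float = DEFAULTS["alpha"]
    min_delta: float = DEFAULTS["min_delta"]
    min_cov: int = DEFAULTS["min_cov"]
    density_window_bp: int = DEFAULTS["density_window_bp"]
    stringency: float = DEFAULTS["stringency"]
    correction: str = DEFAULTS["correction"]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.contrast is not None:
            cfg.contrast = tuple(cfg.contrast)
        if base is not None:
            for s in cfg.samples:
                s["path"] = str((base / s["path"]).resolve())
            for key in ("genes", "expression"):
                val = getattr(cfg, key)
                if val is not None:
                    setattr(cfg, key, str((base / val).resolve()))
            cfg.tracks = {k: str((base / v).resolve()) for k, v in cfg.tracks.items()}
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_delta < 0 or self.min_cov < 1:
            raise ValueError("min_delta >= 0 and min_cov >= 1 required")
        if not (0 < self.step <= self.window):
            raise ValueError("need 0 < step <= window")
        if self.simulate is None:
            if not self.samples:
                raise ValueError("config needs samples or a simulate block")
            for s in self.samples:
                if not Path(s["path"]).exists():
                    raise FileNotFoundError(f"sample file missing: {s['path']}")
        for key in ("genes", "expression"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key} file missing: {val}")
        for name, path in self.tracks.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"track {name!r} missing: {path}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: getattr(config, k)
            for k in DEFAULTS
        } | {"window": config.window, "seed": config.seed},
        "inputs": {},
        "stages": {},
        "outputs": [],
    }

    # --- stage: input acquisition -----------------------------------------
    genome = None
    truth = None
    if config.simulate is not None:
        sim_cfg = sim.SimulationConfig(seed=config.seed, **config.simulate)
        cohort = sim.simulate_cohort(sim_cfg, outdir / "simulated")
        genome = cohort["genome"]
        truth = cohort["truth"]
        sample_set = cohort["samples"]
        if config.genes is None:
            config.genes = str(outdir / "simulated" / "genes.bed")
        if config.expression is None:
            config.expression = str(outdir / "simulated" / "expression.tsv")
        if not config.tracks:
            config.tracks = {
                "CGI": str(outdir / "simulated" / "cgi.bed"),
                "chromatin": str(outdir / "simulated" / "chromatin.bed"),
            }
        manifest["inputs"]["simulation"] = asdict(sim_cfg) | {
            "groups": list(sim_cfg.groups)
        }
        if config.contrast is None:
            config.contrast = sim_cfg.groups
        manifest["stages"]["simulate"] = {
            "n_samples": len(sample_set.samples),
            "n_planted_blocks": int(len(truth.blocks)),
        }
        log.info("simulate: %d samples", len(sample_set.samples))
    else:
        samples = {}
        grouping = {}
        for s in config.samples:
            samples[s["id"]] = mio.read_bismark_cov(s["path"])
            grouping[s["id"]] = s["group"]
            manifest["inputs"][s["id"]] = _sha256(s["path"])
        sample_set = mio.SampleSet(samples=samples, grouping=grouping)
        if config.contrast is None:
            groups = sample_set.groups
            if len(groups) != 2:
                raise ValueError("contrast required when groups != 2")
            config.contrast = (groups[0], groups[1])

    # --- stage: io (pool + filters) ---------------------------------------
    pooled = mio.pool_replicates(sample_set)
    retained_density, flagged = mio.filter_high_density_regions(
        sample_set, window_bp=config.density_window_bp, stringency=config.stringency
    )
    covered = mio.filter_min_coverage(pooled, min_cov=config.min_cov)
    retained = retained_density.merge(covered, on=["chrom", "pos"])
    manifest["stages"]["io"] = {
        "n_cpgs_after_density": int(len(retained_density)),
        "n_flagged_density_windows": int(len(flagged)),
        "n_cpgs_after_coverage": int(len(covered)),
        "n_cpgs_retained": int(len(retained)),
    }
    log.info("io: %d CpGs retained", len(retained))

    # --- stage: bin --------------------------------------------------------
    ws = binning.build_cpg_windows(retained, window=config.window, step=config.step)
    win = binning.window_methylation(ws, pooled)
    stats = binning.bin_size_stats(ws)
    mio.write_table(win.drop(columns=["first_idx"]), outdir / "windows.tsv")
    manifest["stages"]["bin"] = stats
    manifest["outputs"].append("windows.tsv")
    log.info("bin: %d windows (median %.0f bp)", stats["n_bins"], stats["median_bp"])

    # --- stage: dmr --------------------------------------------------------
    contrast = (config.contrast[1], config.contrast[0])  # delta = treated - control
    dmrs = dmr.call_dmrs(
        win,
        contrast=contrast,
        alpha=config.alpha,
        min_delta=config.min_delta,
        correction=config.correction,
    )
    mio.write_table(dmrs, outdir / "dmrs.tsv")
    mio.write_bed(dmr.dmrs_to_bed(dmrs), outdir / "dmrs.bed")
    n_sig = int(dmrs["is_dmr"].sum())
    manifest["stages"]["dmr"] = {
        "n_tested": int(len(dmrs)),
        "n_dmrs": n_sig,
        "n_hyper": int((dmrs["is_dmr"] & (dmrs["direction"] == "hyper")).sum()),
        "n_hypo": int((dmrs["is_dmr"] & (dmrs["direction"] == "hypo")).sum()),
    }
    manifest["outputs"] += ["dmrs.tsv", "dmrs.bed"]
    log.info("dmr: %d / %d windows significant", n_sig, len(dmrs))

    # --- stage: enrich -----------------------------------------------------
    if config.tracks:
        tracks = {name: mio.read_bed(path) for name, path in config.tracks.items()}
        dmr_ids = frozenset(dmrs.loc[dmrs["is_dmr"], "window_id"])
        enr = enrichment.element_enrichment(dmr_ids, dmrs, tracks)
        mio.write_table(enr, outdir / "enrichment.tsv")
        manifest["stages"]["enrich"] = {"n_tracks": len(tracks)}
        manifest["outputs"].append("enrichment.tsv")
        log.info("enrich: %d tracks", len(tracks))

    # --- stage: integrate --------------------------------------------------
    if config.genes and config.expression:
        genes = mio.read_genes(config.genes)
        expr = mio.read_expression_table(config.expression)
        gene_calls = comparative.genes_with_dmrs(
            dmrs, genes, min_avg_delta=config.min_delta
        )
        quad = integration.methylation_expression_quadrants(
            gene_calls, expr, min_avg_delta=config.min_delta
        )
        mio.write_table(quad["genes"], outdir / "gene_integration.tsv")
        manifest["stages"]["integrate"] = {
            "n_genes": int(len(gene_calls)),
            "n_retained": int(gene_calls["retained"].sum()),
            "quadrants": quad["quadrants"],
            "n_hyper_down": quad["n_hyper_down"],
            "n_hyper_up": quad["n_hyper_up"],
            "binomial_p": None
            if quad["binomial_undefined"]
            else quad["binomial_p"],
        }
        manifest["outputs"].append("gene_integration.tsv")
        log.info("integrate: %d genes retained", manifest["stages"]["integrate"]["n_retained"])

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    manifest["outputs"].append("manifest.json")
    return manifest
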