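"""Synthetic bisulfite cohorts with planted differential methylation.

The generator emulates the statistical structure of replicated liver
methylomes: a CpG landscape with dense, lowly methylated CpG islands on a
70–90% methylated background; 3 replicates per treatment group with
negative-binomial coverage around 10x; beta-binomial methylated counts so
replicates are overdispersed relative to a plain binomial; hypermethylated
blocks of consecutive CpGs planted in the treated group only; and an
expression table whose planted hypermethylated genes trend towards
down-regulation. Every planted effect is recorded as ground truth so
recovery and false-positive rates can be scored exactly.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from longmeth import io as mio


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults describe the desk-scale cohort used throughout the test suite:
    2 chromosomes x 25,000 CpGs, two groups of three replicates, ~10x
    coverage, 80% background methylation, 5% CGI methylation, and 50
    planted hypermethylated blocks of 60 consecutive CpGs at +25
    percentage points.
    """

    seed: int = 0
    n_chroms: int = 2
    cpgs_per_chrom: int = 25_000
    mean_gap_bp: float = 80.0          # geometric inter-CpG gap outside CGIs
    cgi_rate: float = 0.002            # per-CpG chance of starting a CGI cluster
    cgi_cpgs: int = 30                 # CpGs per CGI cluster
    cgi_gap_bp: float = 12.0           # dense spacing inside CGIs
    groups: tuple[str, str] = ("treated", "control")
    replicates: int = 3
    coverage_mean: float = 10.0        # negative-binomial mean per CpG
    coverage_dispersion: float = 5.0   # NB size parameter (smaller = noisier)
    mu_bg: float = 0.80                # background methylation level
    mu_cgi: float = 0.05               # CpG-island methylation level
    bb_concentration: float = 30.0     # beta concentration of locus-level variation
    rep_concentration: float | None = None  # extra between-replicate overdispersion
    n_planted: int = 50                # planted differentially methylated blocks
    planted_span_cpgs: int = 60        # consecutive CpGs per block
    planted_delta_pp: float = 25.0     # effect size, percentage points
    planted_hyper_fraction: float = 1.0
    gene_length_bp: int = 20_000
    gene_gap_bp: int = 10_000
    cgi_promoter_fraction: float = 0.5
    expr_noise_sd: float = 0.5         # log2FC noise of unplanted genes
    expr_effect: float = 1.0           # |log2FC| shift of planted genes
    expr_base_de_rate: float = 0.10
    expr_planted_de_rate: float = 0.90
    p_down_given_hyper: float = 0.8

    def validate(self) -> None:
        if not 0 <= self.mu_bg <= 1 or not 0 <= self.mu_cgi <= 1:
            raise ValueError("methylation means must lie in [0, 1]")
        for p in (
            self.cgi_rate,
            self.planted_hyper_fraction,
            self.cgi_promoter_fraction,
            self.expr_base_de_rate,
            self.expr_planted_de_rate,
            self.p_down_given_hyper,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_span_cpgs < 1 or self.cpgs_per_chrom < 1:
            raise ValueError("spans and counts must be >= 1")
        if self.gene_length_bp <= 0 or self.gene_gap_bp < 0:
            raise ValueError("invalid gene tiling")


@dataclass
class Genome:
    cpg_positions: dict[str, np.ndarray]   # 1-based CpG coordinates
    in_cgi: dict[str, np.ndarray]          # per-CpG CGI membership flags
    genes: pd.DataFrame
    cgi_track: pd.DataFrame
    chromatin_track: pd.DataFrame
    chrom_sizes: dict[str, int]


@dataclass
class SyntheticTruth:
    """Planted effects: DMR blocks and expected expression couplings."""

    blocks: pd.DataFrame        # chrom, start, end, cpg_first, cpg_last, direction, delta_pp
    gene_couplings: pd.DataFrame  # gene_id, expected_sign

    def to_json(self) -> dict:
        return {
            "blocks": self.blocks.to_dict(orient="records"),
            "gene_couplings": self.gene_couplings.to_dict(orient="records"),
        }


_CHROMATIN_STATES = [
    "Promoter", "Enhancer", "Transcribed", "Heterochromatin", "Insulator",
]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def simulate_genome(config: SimulationConfig) -> Genome:
    """CpG layout with CGI clusters, tiled genes, CGI and chromatin tracks."""
    config.validate()
    rng = _rng(config, 1)
    cpg_positions: dict[str, np.ndarray] = {}
    in_cgi: dict[str, np.ndarray] = {}
    cgi_rows = []
    gene_rows = []
    chromatin_rows = []
    chrom_sizes: dict[str, int] = {}
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        pos_list: list[int] = []
        cgi_flags: list[bool] = []
        pos = 0
        while len(pos_list) < config.cpgs_per_chrom:
            if rng.random() < config.cgi_rate:
                # dense CGI cluster
                n = min(config.cgi_cpgs, config.cpgs_per_chrom - len(pos_list))
                gaps = rng.geometric(1.0 / config.cgi_gap_bp, size=n)
                cgi_start = pos + int(gaps[0])
                for gp in gaps:
                    pos += int(gp)
                    pos_list.append(pos + 1)  # 1-based
                    cgi_flags.append(True)
                cgi_rows.append((chrom, cgi_start, pos + 1))
            else:
                pos += int(rng.geometric(1.0 / config.mean_gap_bp))
                pos_list.append(pos + 1)
                cgi_flags.append(False)
        positions = np.asarray(pos_list, dtype=np.int64)
        cpg_positions[chrom] = positions
        in_cgi[chrom] = np.asarray(cgi_flags, dtype=bool)
        size = int(positions[-1]) + int(config.mean_gap_bp)
        chrom_sizes[chrom] = size
        # tile genes, alternating strand
        tile = config.gene_length_bp + config.gene_gap_bp
        g_start = config.gene_gap_bp
        k = 0
        while g_start + config.gene_length_bp <= size:
            strand = "+" if k % 2 == 0 else "-"
            end = g_start + config.gene_length_bp
            if config.gene_length_bp > size:
                raise ValueError("gene longer than chromosome")
            gene_rows.append(
                (
                    f"gene_{chrom}_{k}",
                    chrom,
                    g_start,
                    end,
                    strand,
                    g_start if strand == "+" else end - 1,
                )
            )
            g_start += tile
            k += 1
        # chromatin: random-state segments of ~5 kb
        seg = 0
        while seg < size:
            length = int(rng.integers(2_000, 8_000))
            state = _CHROMATIN_STATES[int(rng.integers(len(_CHROMATIN_STATES)))]
            chromatin_rows.append((chrom, seg, min(seg + length, size), state))
            seg += length
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )
    # move a fraction of CGIs onto promoters so CGI classes are populated
    cgi_track = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    if len(cgi_track) and len(genes):
        relocate = rng.random(len(cgi_track)) < config.cgi_promoter_fraction
        # relocation is annotation-only: island intervals are moved to overlap
        # a promoter, the dense CpG layout stays where it was generated
        for i in np.flatnonzero(relocate):
            chrom = cgi_track.at[i, "chrom"]
            cands = genes[genes["chrom"] == chrom]
            if len(cands) == 0:
                continue
            g = cands.iloc[int(rng.integers(len(cands)))]
            width = cgi_track.at[i, "end"] - cgi_track.at[i, "start"]
            cgi_track.at[i, "start"] = max(int(g["tss"]) - width // 2, 0)
            cgi_track.at[i, "end"] = cgi_track.at[i, "start"] + width
    cgi_track["name"] = [f"CGI_{i}" for i in range(len(cgi_track))]
    chromatin = pd.DataFrame(
        chromatin_rows, columns=["chrom", "start", "end", "name"]
    )
    return Genome(
        cpg_positions=cpg_positions,
        in_cgi=in_cgi,
        genes=genes,
        cgi_track=cgi_track,
        chromatin_track=chromatin,
        chrom_sizes=chrom_sizes,
    )


def _plant_blocks(config: SimulationConfig, genome: Genome, rng) -> pd.DataFrame:
    """Choose non-overlapping runs of consecutive CpGs to carry the effect."""
    rows = []
    if config.n_planted == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "cpg_first", "cpg_last",
                     "direction", "delta_pp", "first_idx"]
        )
    chroms = sorted(genome.cpg_positions)
    per_chrom = np.array_split(np.arange(config.n_planted), len(chroms))
    for chrom, block_ids in zip(chroms, per_chrom):
        n_cpgs = len(genome.cpg_positions[chrom])
        span = config.planted_span_cpgs
        n_here = len(block_ids)
        if n_here == 0:
            continue
        # partition the index space so blocks cannot overlap
        slot = n_cpgs // max(n_here, 1)
        if slot <= span:
            raise ValueError("too many planted blocks for the CpG layout")
        for j, _ in enumerate(block_ids):
            first = j * slot + int(rng.integers(0, slot - span))
            last = first + span - 1
            hyper = rng.random() < config.planted_hyper_fraction
            pos = genome.cpg_positions[chrom]
            rows.append(
                (
                    chrom,
                    int(pos[first]) - 1,
                    int(pos[last]),
                    int(pos[first]),
                    int(pos[last]),
                    "hyper" if hyper else "hypo",
                    config.planted_delta_pp if hyper else -config.planted_delta_pp,
                    first,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "cpg_first", "cpg_last",
                 "direction", "delta_pp", "first_idx"],
    )


def simulate_methylomes(
    config: SimulationConfig, genome: Genome
) -> tuple[mio.SampleSet, SyntheticTruth]:
    """Draw per-replicate methylation calls and record the planted truth.

    Each CpG's true methylation level is drawn once from a beta
    distribution around the regional mean (background or CGI) and shared by
    every sample — locus-to-locus variation is a property of the site, not
    of the animal — so each replicate's methylated count is marginally
    beta-binomial while the group contrast stays exactly null when no
    effect is planted. Planted blocks shift the treated group's level by
    ±delta, clipped to [0, 1].

    Coverage is negative-binomial per CpG and replicate, realised as a
    per-CpG gamma depth propensity (mappability/GC) shared by every sample
    with Poisson draws per replicate, so coverage correlates across samples
    the way alignment depth does in real libraries. Setting
    ``rep_concentration`` adds a replicate-specific beta perturbation
    (between-animal overdispersion), under which the pooled chi-squared
    test is anti-conservative.
    """
    config.validate()
    rng = _rng(config, 2)
    blocks = _plant_blocks(config, genome, rng)
    treated, _ = config.groups
    samples: dict[str, pd.DataFrame] = {
        f"{g}_rep{r + 1}": [] for g in config.groups for r in range(config.replicates)
    }
    grouping = {
        f"{g}_rep{r + 1}": g for g in config.groups for r in range(config.replicates)
    }
    shape = config.coverage_dispersion
    conc = config.bb_concentration
    for chrom in sorted(genome.cpg_positions):
        pos = genome.cpg_positions[chrom]
        mu = np.where(genome.in_cgi[chrom], config.mu_cgi, config.mu_bg)
        p_cpg = rng.beta(
            np.maximum(mu * conc, 1e-9), np.maximum((1 - mu) * conc, 1e-9)
        )
        depth = rng.gamma(shape, config.coverage_mean / shape, size=len(pos))
        p_treated = p_cpg
        if len(blocks):
            p_treated = p_cpg.copy()
            n_clipped = 0
            for _, blk in blocks[blocks["chrom"] == chrom].iterrows():
                i = int(blk["first_idx"])
                j = i + config.planted_span_cpgs
                shifted = p_treated[i:j] + blk["delta_pp"] / 100.0
                n_clipped += int(((shifted < 0) | (shifted > 1)).sum())
                p_treated[i:j] = np.clip(shifted, 0.0, 1.0)
            if n_clipped:
                warnings.warn(
                    f"{chrom}: planted effect saturates methylation at "
                    f"{n_clipped} CpGs (levels clipped to [0, 1])",
                    stacklevel=2,
                )
        for group in config.groups:
            p_group = p_treated if group == treated else p_cpg
            for r in range(config.replicates):
                cov = rng.poisson(depth)
                if config.rep_concentration is not None:
                    rc = config.rep_concentration
                    p_rep = rng.beta(
                        np.maximum(p_group * rc, 1e-9),
                        np.maximum((1 - p_group) * rc, 1e-9),
                    )
                else:
                    p_rep = p_group
                m = rng.binomial(cov, p_rep)
                samples[f"{group}_rep{r + 1}"].append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "n_meth": m.astype(np.int64),
                            "n_unmeth": (cov - m).astype(np.int64),
                        }
                    )
                )
    samples = {sid: pd.concat(frames, ignore_index=True) for sid, frames in samples.items()}
    couplings = _gene_couplings(blocks, genome.genes)
    truth = SyntheticTruth(
        blocks=blocks.drop(columns=["first_idx"]), gene_couplings=couplings
    )
    return mio.SampleSet(samples=samples, grouping=grouping), truth


def _gene_couplings(blocks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, g in genes.iterrows():
        sub = blocks[blocks["chrom"] == g["chrom"]]
        hit = sub[(sub["start"] < g["end"]) & (sub["end"] > g["start"])]
        if len(hit) == 0:
            continue
        sign = 1 if (hit["delta_pp"].mean() > 0) else -1
        rows.append((g["gene_id"], "hyper" if sign > 0 else "hypo"))
    return pd.DataFrame(rows, columns=["gene_id", "planted_direction"])


def simulate_expression(
    config: SimulationConfig,
    truth: SyntheticTruth,
    genes: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential-expression table coupled to the planted methylation.

    Unplanted genes get log2FC ~ Normal(0, sd) and are differentially
    expressed at the base rate. Planted hypermethylated genes are
    down-regulated with probability ``p_down_given_hyper`` and their
    |log2FC| is shifted by ``expr_effect``.
    """
    rng = (
        np.random.default_rng(np.random.SeedSequence((seed, 3)))
        if seed is not None
        else _rng(config, 3)
    )
    planted = dict(
        zip(truth.gene_couplings["gene_id"], truth.gene_couplings["planted_direction"])
    )
    rows = []
    for gid in genes["gene_id"]:
        direction = planted.get(gid)
        if direction is None:
            log2fc = float(rng.normal(0.0, config.expr_noise_sd))
            is_de = bool(rng.random() < config.expr_base_de_rate)
        else:
            down = rng.random() < config.p_down_given_hyper
            sign = -1.0 if down else 1.0
            if direction == "hypo":
                sign = -sign
            log2fc = sign * (
                config.expr_effect + abs(rng.normal(0.0, config.expr_noise_sd))
            )
            is_de = bool(rng.random() < config.expr_planted_de_rate)
        p_adj = float(rng.uniform(0.0, 0.049)) if is_de else float(rng.uniform(0.05, 1.0))
        rows.append((gid, log2fc, p_adj, True, is_de))
    return pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "p_adj", "is_expressed", "is_de"]
    )


def simulate_cohort(
    config: SimulationConfig, outdir: str | Path | None = None
) -> dict:
    """Full cohort: genome, methylomes, expression, truth; optionally on disk.

    When ``outdir`` is given, writes one Bismark coverage file per
    replicate plus genes.bed, cgi.bed, chromatin.bed, expression.tsv and
    truth.json.
    """
    genome = simulate_genome(config)
    sample_set, truth = simulate_methylomes(config, genome)
    expression = simulate_expression(config, truth, genome.genes)
    if outdir is not None:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, calls in sample_set.samples.items():
            mio.write_bismark_cov(calls, outdir / f"{sid}.cov")
        mio.write_genes_bed(genome.genes, outdir / "genes.bed")
        mio.write_bed(genome.cgi_track, outdir / "cgi.bed")
        mio.write_bed(genome.chromatin_track, outdir / "chromatin.bed")
        expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth.to_json(), fh, indent=1)
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample\tgroup\tpath\n")
            for sid, grp in sample_set.grouping.items():
                fh.write(f"{sid}\t{grp}\t{sid}.cov\n")
    return {
        "genome": genome,
        "samples": sample_set,
        "truth": truth,
        "expression": expression,
    }
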