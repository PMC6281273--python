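"""Reading, writing, pooling and filtering of per-CpG methylation calls.

Methylation calls are held in pandas DataFrames with columns
``chrom, pos, n_meth, n_unmeth`` where ``pos`` is the 1-based CpG coordinate
(the Bismark coverage convention). All other genomic intervals in the package
are 0-based half-open; the conversion happens only in the readers/writers in
this module.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]


class MethylationParseError(ValueError):
    """Raised for malformed methylation call files."""


@dataclass
class SampleSet:
    """Per-sample methylation calls plus a sample -> group assignment.

    ``samples`` maps sample id to a calls DataFrame (``CALL_COLUMNS``);
    ``grouping`` maps sample id to a treatment-group label.
    """

    samples: dict[str, pd.DataFrame] = field(default_factory=dict)
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.grouping) - set(self.samples)
        if missing:
            raise ValueError(f"grouping refers to unknown samples: {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.grouping.values()))

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.grouping.items() if g == group]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_cov(path: str | Path, destrand: bool = False) -> pd.DataFrame:
    """Read a Bismark coverage file into a calls DataFrame.

    Expected columns: chrom, start (1-based), end, %methylation, count
    methylated, count unmethylated. The percentage column is ignored; when it
    disagrees with the counts by more than 0.5 percentage points a warning is
    emitted and the counts win.

    With ``destrand=True``, calls at adjacent positions ``p``/``p+1`` (the two
    strands of one CpG dyad) are merged onto the lower coordinate.
    """
    chroms: list[str] = []
    pos: list[int] = []
    n_meth: list[int] = []
    n_unmeth: list[int] = []
    pct_mismatch = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise MethylationParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                start = int(parts[1])
                pct = float(parts[3])
                m = int(parts[4])
                u = int(parts[5])
            except ValueError as exc:
                raise MethylationParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from None
            if m < 0 or u < 0:
                raise MethylationParseError(
                    f"{path}: line {lineno}: negative count"
                )
            cov = m + u
            if cov > 0 and abs(100.0 * m / cov - pct) > 0.5:
                pct_mismatch += 1
            chroms.append(parts[0])
            pos.append(start)
            n_meth.append(m)
            n_unmeth.append(u)
    if pct_mismatch:
        warnings.warn(
            f"{path}: {pct_mismatch} lines had a %methylation column inconsistent "
            "with the counts (>0.5pp); counts were used",
            stacklevel=2,
        )
    calls = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "pos": np.asarray(pos, dtype=np.int64),
            "n_meth": np.asarray(n_meth, dtype=np.int64),
            "n_unmeth": np.asarray(n_unmeth, dtype=np.int64),
        }
    )
    if destrand:
        calls = destrand_calls(calls)
    dup = calls.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = calls.loc[dup, ["chrom", "pos"]].iloc[0]
        raise MethylationParseError(
            f"{path}: duplicate CpG {first.chrom}:{first.pos}"
        )
    return calls.sort_values(["chrom", "pos"], ignore_index=True)


def destrand_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge plus/minus strand calls at ``pos``/``pos+1`` onto ``pos``.

    A position is treated as the minus-strand mate of its predecessor when the
    predecessor on the same chromosome sits exactly 1 bp upstream.
    """
    calls = calls.sort_values(["chrom", "pos"], ignore_index=True)
    same_chrom = calls["chrom"].values[1:] == calls["chrom"].values[:-1]
    gap1 = calls["pos"].values[1:] - calls["pos"].values[:-1] == 1
    is_mate = np.concatenate([[False], same_chrom & gap1])
    # avoid chaining p, p+1, p+2: a mate cannot itself have a mate
    is_mate &= ~np.concatenate([[False], is_mate[:-1]])
    anchor = np.arange(len(calls)) - is_mate.astype(int)
    out = calls.copy()
    out["anchor"] = anchor
    merged = (
        out.groupby("anchor", sort=True)
        .agg(
            chrom=("chrom", "first"),
            pos=("pos", "first"),
            n_meth=("n_meth", "sum"),
            n_unmeth=("n_unmeth", "sum"),
        )
        .reset_index(drop=True)
    )
    return merged


def write_bismark_cov(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls in Bismark coverage format (counts authoritative)."""
    cov = calls["n_meth"] + calls["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * calls["n_meth"] / cov, 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"],
            "end": calls["pos"],
            "pct": [f"{p:.6g}" for p in pct],
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def pool_replicates(samples: SampleSet) -> dict[str, pd.DataFrame]:
    """Sum replicate counts per CpG within each treatment group.

    CpGs absent from a replicate contribute zero counts; the pooled table per
    group contains every CpG seen in any replicate of that group.
    """
    pooled: dict[str, pd.DataFrame] = {}
    for group in samples.groups:
        ids = samples.samples_in_group(group)
        if not ids:
            raise ValueError(f"group {group!r} has no samples")
        frames = [samples.samples[s][CALL_COLUMNS] for s in ids]
        cat = pd.concat(frames, ignore_index=True)
        pooled[group] = (
            cat.groupby(["chrom", "pos"], sort=True, as_index=False)[
                ["n_meth", "n_unmeth"]
            ]
            .sum()
            .astype({"n_meth": np.int64, "n_unmeth": np.int64})
        )
    return pooled


def filter_high_density_regions(
    samples: SampleSet,
    window_bp: int = 25_000,
    stringency: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag 25-kb tiles with outlier observation counts and drop their CpGs.

    The genome is tiled with non-overlapping ``window_bp`` windows; per tile,
    the total read observations (methylated + unmethylated, summed over all
    samples) are counted. Tiles whose count exceeds Q3 + stringency * IQR
    (box-whisker outlier rule; quartiles by linear interpolation) are flagged
    and every CpG inside them is removed.

    Returns ``(retained_cpgs, flagged_windows)`` where ``retained_cpgs`` has
    columns chrom/pos and ``flagged_windows`` has chrom/start/end/count.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not samples.samples:
        empty = pd.DataFrame(columns=["chrom", "pos"])
        flags = pd.DataFrame(columns=["chrom", "start", "end", "count"])
        return empty, flags
    cat = pd.concat(
        [df[CALL_COLUMNS] for df in samples.samples.values()], ignore_index=True
    )
    cat["tile"] = (cat["pos"] - 1) // window_bp
    cat["obs"] = cat["n_meth"] + cat["n_unmeth"]
    tile_counts = (
        cat.groupby(["chrom", "tile"], sort=True)["obs"].sum().reset_index()
    )
    counts = tile_counts["obs"].to_numpy(dtype=float)
    q1, q3 = np.percentile(counts, [25, 75])
    threshold = q3 + stringency * (q3 - q1)
    flagged = tile_counts[tile_counts["obs"] > threshold]
    flagged_windows = pd.DataFrame(
        {
            "chrom": flagged["chrom"].values,
            "start": flagged["tile"].values * window_bp,
            "end": (flagged["tile"].values + 1) * window_bp,
            "count": flagged["obs"].values,
        }
    )
    all_cpgs = cat[["chrom", "pos", "tile"]].drop_duplicates(["chrom", "pos"])
    bad = set(zip(flagged["chrom"], flagged["tile"]))
    if bad:
        mask = [
            (c, t) not in bad
            for c, t in zip(all_cpgs["chrom"].values, all_cpgs["tile"].values)
        ]
        retained = all_cpgs.loc[mask, ["chrom", "pos"]]
    else:
        retained = all_cpgs[["chrom", "pos"]]
    retained = retained.sort_values(["chrom", "pos"], ignore_index=True)
    return retained, flagged_windows


def filter_min_coverage(
    groups: dict[str, pd.DataFrame],
    min_cov: int = 3,
    require: str = "all_groups",
) -> pd.DataFrame:
    """CpGs whose pooled coverage reaches ``min_cov`` in all (or any) group.

    ``require="all_groups"`` keeps a CpG only when every group covers it with
    at least ``min_cov`` observations (the windowed-analysis rule);
    ``require="any_group"`` keeps CpGs reaching the threshold in at least one
    group (the marker-region readout rule). Returns a chrom/pos DataFrame.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if require not in ("all_groups", "any_group"):
        raise ValueError(f"unknown require mode: {require!r}")
    if not groups:
        return pd.DataFrame(columns=["chrom", "pos"])
    per_group = []
    for label, df in groups.items():
        cov = df["n_meth"] + df["n_unmeth"]
        ok = df.loc[cov >= min_cov, ["chrom", "pos"]]
        per_group.append(set(zip(ok["chrom"], ok["pos"])))
    if require == "all_groups":
        keep = set.intersection(*per_group)
    else:
        keep = set.union(*per_group)
    out = pd.DataFrame(sorted(keep), columns=["chrom", "pos"])
    return out


# ---------------------------------------------------------------------------
# annotation I/O


def read_bed(path: str | Path, name: str | None = None) -> pd.DataFrame:
    """Read a BED3+ file into an interval DataFrame (0-based half-open).

    Columns: chrom, start, end, plus name if a 4th column exists.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MethylationParseError(
                    f"{path}: line {lineno}: BED needs >=3 columns"
                )
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise MethylationParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            rows.append(
                (parts[0], start, end, parts[3] if len(parts) > 3 else ".")
            )
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if name is not None:
        track.attrs["name"] = name
    return track.sort_values(["chrom", "start"], ignore_index=True)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene models from BED6/BED12 or minimal GTF.

    Returns columns gene_id, chrom, start, end, strand, tss with the span
    0-based half-open and ``tss = start`` on + and ``end - 1`` on −.
    """
    path = Path(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) >= 9 and parts[2] in {"gene", "transcript"}:
                # minimal GTF: 1-based inclusive coordinates
                chrom, start, end, strand = parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]
                gene_id = _gtf_gene_id(parts[8]) or f"gene_{lineno}"
            elif len(parts) >= 6:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                gene_id, strand = parts[3], parts[5]
            else:
                raise MethylationParseError(
                    f"{path}: line {lineno}: need BED6/BED12 or GTF gene line"
                )
            if start >= end:
                raise MethylationParseError(
                    f"{path}: line {lineno}: start >= end"
                )
            if strand not in "+-":
                raise MethylationParseError(
                    f"{path}: line {lineno}: strand must be + or -"
                )
            tss = start if strand == "+" else end - 1
            rows.append((gene_id, chrom, start, end, strand, tss))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    ).sort_values(["chrom", "start"], ignore_index=True)


def _gtf_gene_id(attributes: str) -> str | None:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    return None


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with a header line."""
    records.to_csv(path, sep="\t", header=True, index=False)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table.

    Expects TSV with header containing at least gene_id, log2fc, p_adj;
    optional is_expressed flag (defaults to True). ``is_de`` is derived as
    p_adj < 0.05 with no fold-change cutoff.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "p_adj"}
    missing = required - set(df.columns)
    if missing:
        raise MethylationParseError(f"{path}: missing columns {sorted(missing)}")
    if "is_expressed" not in df.columns:
        df["is_expressed"] = True
    df["is_de"] = (df["p_adj"] < 0.05) & df["is_expressed"]
    return df
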