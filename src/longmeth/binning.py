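"""Adaptive fixed-CpG-count windows and fixed-width sliding windows.

The primary binning strategy is annotation-blind: windows contain a fixed
number of retained CpGs (default 50) and start every ``step`` CpGs (default
25), so each window carries about the same amount of data and hence similar
technical noise and statistical power, while its genomic span adapts to the
local CpG density. Trailing CpGs that cannot fill a complete window are
dropped.

Window genomic spans are 0-based half-open, ``[first CpG, last CpG + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WindowSet:
    """Fixed-CpG-count windows over a retained-CpG layout.

    ``windows`` columns: window_id, chrom, start, end, first_idx, n_cpgs.
    ``positions`` maps chrom -> sorted 1-based CpG coordinates; ``first_idx``
    indexes into that array. After :func:`window_methylation` the table also
    carries, per group ``g``: ``meth_g`` (unweighted mean percent),
    ``m_g``/``u_g`` (summed methylated/unmethylated counts over member CpGs).
    """

    windows: pd.DataFrame
    positions: dict[str, np.ndarray]
    window: int
    step: int

    def member_positions(self, window_id: int) -> np.ndarray:
        row = self.windows.loc[self.windows["window_id"] == window_id].iloc[0]
        i = int(row["first_idx"])
        return self.positions[row["chrom"]][i : i + int(row["n_cpgs"])]

    def __len__(self) -> int:
        return len(self.windows)


def _positions_by_chrom(retained: pd.DataFrame) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom, sub in retained.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"CpG positions on {chrom} are not sorted")
        if np.any(np.diff(pos) == 0):
            raise ValueError(f"duplicate CpG position on {chrom}")
        out[chrom] = pos
    return out


def build_cpg_windows(
    retained: pd.DataFrame, window: int = 50, step: int = 25
) -> WindowSet:
    """Build windows of ``window`` consecutive retained CpGs every ``step``.

    ``retained`` is a chrom/pos table of CpGs that passed the coverage and
    density filters. Windows never cross chromosomes; a window is emitted only
    when a full ``window`` CpGs remain, so consecutive windows share exactly
    ``window - step`` CpGs.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not (0 < step <= window):
        raise ValueError("step must satisfy 0 < step <= window")
    positions = _positions_by_chrom(retained)
    rows = []
    wid = 0
    for chrom in sorted(positions):
        pos = positions[chrom]
        n = len(pos)
        for first in range(0, n - window + 1, step):
            last = first + window - 1
            rows.append(
                (wid, chrom, int(pos[first]) - 1, int(pos[last]), first, window)
            )
            wid += 1
    windows = pd.DataFrame(
        rows, columns=["window_id", "chrom", "start", "end", "first_idx", "n_cpgs"]
    )
    return WindowSet(windows=windows, positions=positions, window=window, step=step)


def _sliding_sums(values: np.ndarray, window: int, firsts: np.ndarray) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    return csum[firsts + window] - csum[firsts]


def window_methylation(
    ws: WindowSet, group_counts: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-group window methylation: unweighted mean of member-CpG percents.

    Each window's methylation in a group is the plain average of the per-CpG
    methylation percentages — not the pooled-count ratio — so deeply covered
    CpGs do not dominate. Pooled member counts per group are recorded
    alongside (``m_g``/``u_g``) for the count-based chi-squared test.

    Every member CpG must have coverage > 0 in every group (guaranteed when
    the minimum-coverage filter ran upstream); a violation raises ValueError.
    """
    win = ws.windows.copy()
    firsts_by_chrom = {
        chrom: sub["first_idx"].to_numpy()
        for chrom, sub in win.groupby("chrom", sort=True)
    }
    for group, df in group_counts.items():
        meth = np.empty(len(win))
        msum = np.empty(len(win))
        usum = np.empty(len(win))
        for chrom, sub in win.groupby("chrom", sort=True):
            pos = ws.positions[chrom]
            gsub = df[df["chrom"] == chrom].set_index("pos")
            gsub = gsub.reindex(pos)
            m = gsub["n_meth"].to_numpy(dtype=float)
            u = gsub["n_unmeth"].to_numpy(dtype=float)
            cov = m + u
            if np.any(~np.isfinite(cov)) or np.any(cov <= 0):
                bad = pos[np.where(~(cov > 0))[0][:1]]
                raise ValueError(
                    f"group {group!r} has zero coverage at member CpG "
                    f"{chrom}:{bad[0] if len(bad) else '?'}; "
                    "run the coverage filter before binning"
                )
            pct = 100.0 * m / cov
            firsts = firsts_by_chrom[chrom]
            idx = sub.index
            meth[win.index.get_indexer(idx)] = (
                _sliding_sums(pct, ws.window, firsts) / ws.window
            )
            msum[win.index.get_indexer(idx)] = _sliding_sums(m, ws.window, firsts)
            usum[win.index.get_indexer(idx)] = _sliding_sums(u, ws.window, firsts)
        win[f"meth_{group}"] = meth
        win[f"m_{group}"] = msum
        win[f"u_{group}"] = usum
    return win


def build_fixed_width_windows(
    chrom_sizes: dict[str, int], width: int = 500, step: int = 100
) -> pd.DataFrame:
    """Fixed-width overlapping bins ``[k*step, k*step + width)`` per chrom.

    The 500 bp / 100 bp default gives neighbouring bins a 400 bp overlap,
    used to draw high-resolution methylation profiles over single loci.
    """
    if width <= 0 or not (0 < step <= width):
        raise ValueError("need width > 0 and 0 < step <= width")
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        start = 0
        while start < size:
            rows.append((chrom, start, start + width))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def fixed_width_methylation(
    bins: pd.DataFrame, group_counts: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Average per-CpG methylation of covered CpGs inside each fixed bin.

    Bins containing no covered CpG get NaN (missing), never 0%.
    """
    out = bins.copy()
    for group, df in group_counts.items():
        values = np.full(len(bins), np.nan)
        for chrom, sub in bins.groupby("chrom", sort=False):
            g = df[df["chrom"] == chrom]
            cov = (g["n_meth"] + g["n_unmeth"]).to_numpy(dtype=float)
            usable = cov > 0
            pos0 = g["pos"].to_numpy(dtype=np.int64)[usable] - 1  # 0-based
            pct = 100.0 * g["n_meth"].to_numpy(dtype=float)[usable] / cov[usable]
            order = np.argsort(pos0)
            pos0, pct = pos0[order], pct[order]
            csum = np.concatenate([[0.0], np.cumsum(pct)])
            lo = np.searchsorted(pos0, sub["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos0, sub["end"].to_numpy() - 1, side="right")
            n = hi - lo
            with np.errstate(invalid="ignore"):
                vals = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
            values[out.index.get_indexer(sub.index)] = vals
        out[f"meth_{group}"] = values
    return out


def bin_size_stats(ws: WindowSet) -> dict[str, float]:
    """Summary of a window set: bin count, span stats, distinct CpGs covered."""
    win = ws.windows
    if len(win) == 0:
        return {"n_bins": 0, "median_bp": 0.0, "mean_bp": 0.0, "cpgs_covered": 0}
    spans = (win["end"] - win["start"]).to_numpy(dtype=float)
    covered = 0
    for chrom, sub in win.groupby("chrom", sort=True):
        used = np.zeros(len(ws.positions[chrom]), dtype=bool)
        for first, n in zip(sub["first_idx"], sub["n_cpgs"]):
            used[int(first) : int(first) + int(n)] = True
        covered += int(used.sum())
    return {
        "n_bins": int(len(win)),
        "median_bp": float(np.median(spans)),
        "mean_bp": float(np.mean(spans)),
        "cpgs_covered": covered,
    }
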