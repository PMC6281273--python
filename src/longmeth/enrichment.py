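"""Enrichment of DMR sets over genomic and epigenetic element tracks.

Enrichment is measured against the set of background bins (all tested
windows of the cohort), not the nucleotide genome: per element track, the
observed DMR overlap frequency is divided by the background frequency
('observed/expected'), and a one-sided Fisher's exact test with BH
correction across tracks assesses significance. Overlap is binary per
window (>= 1 bp), not bp-weighted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from longmeth.dmr import adjust_pvalues


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [], []
    for s, e in zip(starts, ends):
        if m_ends and s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def annotate_windows(windows: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean flag per window: does its span intersect the track by >= 1 bp?

    ``windows`` needs chrom/start/end; ``track`` is an interval table
    (chrom/start/end, 0-based half-open). Touching half-open boundaries do
    not count as overlap.
    """
    flags = np.zeros(len(windows), dtype=bool)
    track_by_chrom = {
        chrom: _merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        for chrom, sub in track.groupby("chrom", sort=False)
    }
    for chrom, sub in windows.groupby("chrom", sort=False):
        if chrom not in track_by_chrom:
            continue
        t_start, t_end = track_by_chrom[chrom]
        w_start = sub["start"].to_numpy(np.int64)
        w_end = sub["end"].to_numpy(np.int64)
        # a window overlaps some merged interval iff the first interval with
        # end > w_start also has start < w_end
        idx = np.searchsorted(t_end, w_start, side="right")
        ok = idx < len(t_start)
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = t_start[idx[ok]] < w_end[ok]
        flags[windows.index.get_indexer(sub.index)] = hit
    return flags


def element_enrichment(
    dmr_ids: frozenset | set,
    background: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    correction: str = "BH",
) -> pd.DataFrame:
    """Observed/expected enrichment of a DMR set over element tracks.

    ``background`` is the full tested-window table (with window_id and
    spans); ``dmr_ids`` the subset called differentially methylated. Tracks
    with zero background overlap get a missing ratio. p-values are one-sided
    (enrichment) Fisher, BH-adjusted across tracks.
    """
    if not set(dmr_ids) <= set(background["window_id"]):
        raise ValueError("DMR set is not a subset of the background windows")
    is_dmr = background["window_id"].isin(dmr_ids).to_numpy()
    n_dmr = int(is_dmr.sum())
    n_bg = len(background)
    rows = []
    for name in sorted(tracks):
        flags = annotate_windows(background, tracks[name])
        n_bg_overlap = int(flags.sum())
        n_dmr_overlap = int((flags & is_dmr).sum())
        if n_bg_overlap == 0 or n_dmr == 0:
            ratio = np.nan
        else:
            ratio = (n_dmr_overlap / n_dmr) / (n_bg_overlap / n_bg)
        log2_ratio = np.log2(ratio) if ratio and ratio > 0 else np.nan
        # one-sided enrichment: DMR vs non-DMR windows, inside vs outside
        table = [
            [n_dmr_overlap, n_dmr - n_dmr_overlap],
            [n_bg_overlap - n_dmr_overlap, (n_bg - n_dmr) - (n_bg_overlap - n_dmr_overlap)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            (name, n_dmr_overlap, n_dmr, n_bg_overlap, n_bg, ratio, log2_ratio, p)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "element",
            "n_dmr_overlap",
            "n_dmr_total",
            "n_bg_overlap",
            "n_bg_total",
            "ratio",
            "log2_ratio",
            "p_raw",
        ],
    )
    if len(out):
        out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), method=correction)
    else:
        out["p_adj"] = []
    return out
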