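"""Set-level statistics across conditions.

All comparisons here operate on DMR sets defined over one shared binning
(the universe of tested windows): overlap significance with the entire
tested methylome as background, aggregation of DMRs onto genes,
sign-quadrant directionality tests, directional consensus across strains,
and the selection of longevity-marker regions (hypermethylated in every
intervention, not overlapping age-related hypomethylation) with a per-CpG
paired Wilcoxon readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DMRSet:
    """A labelled set of window ids drawn from a shared tested universe."""

    label: str
    universe_size: int
    members: frozenset = field(default_factory=frozenset)
    direction: str = "both"  # hyper / hypo / both

    def __post_init__(self):
        if len(self.members) > self.universe_size:
            raise ValueError("member set exceeds universe")


def dmr_set_from_results(
    dmrs: pd.DataFrame, label: str, direction: str = "both"
) -> DMRSet:
    """Build a DMRSet from a call_dmrs table, optionally direction-filtered."""
    sig = dmrs[dmrs["is_dmr"]]
    if direction in ("hyper", "hypo"):
        sig = sig[sig["direction"] == direction]
    elif direction != "both":
        raise ValueError(f"direction must be hyper/hypo/both, got {direction!r}")
    return DMRSet(
        label=label,
        universe_size=len(dmrs),
        members=frozenset(sig["window_id"].tolist()),
        direction=direction,
    )


def overlap_fisher(a: DMRSet, b: DMRSet) -> tuple[int, float, float]:
    """One-sided Fisher's exact test for DMR-set overlap.

    Background is the entire universe of tested windows. Returns
    (intersection size, odds ratio, one-sided enrichment p).
    """
    if a.universe_size != b.universe_size:
        raise ValueError("DMR sets must share one universe")
    n = a.universe_size
    inter = len(a.members & b.members)
    only_a = len(a.members) - inter
    only_b = len(b.members) - inter
    rest = n - inter - only_a - only_b
    if rest < 0:
        raise ValueError("sets exceed universe")
    odds, p = stats.fisher_exact(
        [[inter, only_a], [only_b, rest]], alternative="greater"
    )
    return inter, float(odds), float(p)


def genes_with_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    min_dmrs: int = 2,
    min_avg_delta: float = 10.0,
) -> pd.DataFrame:
    """Aggregate significant DMRs onto gene transcription spans.

    A DMR overlaps a gene when the window span intersects the gene span
    (TSS..TES including introns) by at least 1 bp. A gene is ``retained``
    when covered by at least ``min_dmrs`` DMRs whose average delta reaches
    ±``min_avg_delta``; requiring an average keeps genes with an equal extent
    of hyper- and hypomethylation out of the call.
    """
    sig = dmrs[dmrs["is_dmr"]]
    rows = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        dsub = sig[sig["chrom"] == chrom]
        if len(dsub) == 0:
            for _, g in gsub.iterrows():
                rows.append((g["gene_id"], 0, np.nan))
            continue
        d_start = dsub["start"].to_numpy()
        d_end = dsub["end"].to_numpy()
        d_delta = dsub["delta_pp"].to_numpy()
        for _, g in gsub.iterrows():
            hit = (d_start < g["end"]) & (d_end > g["start"])
            n = int(hit.sum())
            avg = float(d_delta[hit].mean()) if n else np.nan
            rows.append((g["gene_id"], n, avg))
    out = pd.DataFrame(rows, columns=["gene_id", "n_dmrs", "avg_delta_pp"])
    out["retained"] = (out["n_dmrs"] >= min_dmrs) & (
        out["avg_delta_pp"].abs() >= min_avg_delta
    )
    out["direction"] = np.where(out["avg_delta_pp"] >= 0, "hyper", "hypo")
    out.loc[out["n_dmrs"] == 0, "direction"] = "none"
    return out


def quadrant_association(
    sig_deltas_a: pd.Series | dict, deltas_b: pd.Series | dict
) -> tuple[pd.DataFrame, float]:
    """Directionality of methylation changes across two conditions.

    ``sig_deltas_a`` holds per-window deltas for windows significant in
    condition A; ``deltas_b`` the same windows' (unthresholded) deltas in B.
    Windows with a zero delta on either axis are excluded. Returns the 2x2
    sign-quadrant count table and a one-sided Fisher p for positive
    association (concordant signs enriched).
    """
    a = pd.Series(sig_deltas_a, dtype=float)
    b = pd.Series(deltas_b, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared windows between the two delta maps")
    a, b = a[common], b[common]
    keep = (a != 0) & (b != 0)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no windows left after excluding zero deltas")
    pp = int(((a > 0) & (b > 0)).sum())
    pn = int(((a > 0) & (b < 0)).sum())
    np_ = int(((a < 0) & (b > 0)).sum())
    nn = int(((a < 0) & (b < 0)).sum())
    table = pd.DataFrame(
        [[pp, pn], [np_, nn]],
        index=["a_hyper", "a_hypo"],
        columns=["b_hyper", "b_hypo"],
    )
    _, p = stats.fisher_exact([[pp, pn], [np_, nn]], alternative="greater")
    return table, float(p)


def consensus_dmrs(
    sets: list[DMRSet], min_sets: int = 2, direction: str = "hyper"
) -> DMRSet:
    """Windows carrying a directional DMR in at least ``min_sets`` inputs."""
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be hyper or hypo")
    if min_sets > len(sets):
        raise ValueError("min_sets exceeds the number of input sets")
    sizes = {s.universe_size for s in sets}
    if len(sizes) != 1:
        raise ValueError("input sets must share one universe")
    eligible = [s for s in sets if s.direction in (direction, "both")]
    counts: dict = {}
    for s in eligible:
        for w in s.members:
            counts[w] = counts.get(w, 0) + 1
    members = frozenset(w for w, c in counts.items() if c >= min_sets)
    return DMRSet(
        label=f"consensus_{direction}_ge{min_sets}",
        universe_size=sizes.pop(),
        members=members,
        direction=direction,
    )


def _windows_overlap(ids_a, ids_b, window_spans: pd.DataFrame | None):
    """Ids in ``ids_a`` genomically overlapping any window in ``ids_b``.

    Without a span table, overlap degrades to id identity.
    """
    if window_spans is None:
        return set(ids_a) & set(ids_b)
    spans = window_spans.set_index("window_id")
    hit = set()
    b_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for wid in ids_b:
        row = spans.loc[wid]
        b_by_chrom.setdefault(row["chrom"], []).append(
            (int(row["start"]), int(row["end"]))
        )
    for wid in ids_a:
        row = spans.loc[wid]
        for s, e in b_by_chrom.get(row["chrom"], ()):
            if int(row["start"]) < e and int(row["end"]) > s:
                hit.add(wid)
                break
    return hit


def select_marker_regions(
    intervention_hyper_sets: list[DMRSet],
    age_hypo_consensus: DMRSet | None = None,
    window_spans: pd.DataFrame | None = None,
) -> frozenset:
    """Marker candidates: hypermethylated in every intervention, age-independent.

    Takes the intersection of hypermethylated DMR sets across all
    interventions, then removes every window overlapping the age-related
    hypomethylation consensus (genomic overlap when ``window_spans`` — a
    window_id/chrom/start/end table — is given; id identity otherwise).
    """
    if len(intervention_hyper_sets) < 2:
        raise ValueError("need at least two intervention sets")
    shared = frozenset.intersection(*(s.members for s in intervention_hyper_sets))
    if age_hypo_consensus is None or not shared:
        return shared
    clashing = _windows_overlap(shared, age_hypo_consensus.members, window_spans)
    return frozenset(shared - clashing)


def refine_marker_region(
    chrom: str,
    start: int,
    end: int,
    cpg_positions: np.ndarray,
    cpg_abs_delta: np.ndarray | None = None,
    width: int = 500,
) -> tuple[int, int, bool]:
    """Pick the ``width``-bp subregion of a marker DMR best suited for assays.

    Scans 1-bp candidate starts and keeps the subwindow holding the most
    member CpGs; ties go to the larger mean |delta| across its CpGs, then to
    the leftmost start. Returns (refined_start, refined_end, whole_region):
    when the DMR is shorter than ``width`` the whole span is returned with
    the flag set.
    """
    pos0 = np.asarray(cpg_positions, dtype=np.int64) - 1  # 0-based
    inside = (pos0 >= start) & (pos0 < end)
    pos0 = pos0[inside]
    if cpg_abs_delta is not None:
        delta = np.abs(np.asarray(cpg_abs_delta, dtype=float))[inside]
    else:
        delta = np.zeros(len(pos0))
    if end - start < width:
        return start, end, True
    starts = np.arange(start, end - width + 1)
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, starts + width - 1, side="right")
    n = hi - lo
    dsum = np.concatenate([[0.0], np.cumsum(delta)])
    with np.errstate(invalid="ignore"):
        mean_d = np.where(n > 0, (dsum[hi] - dsum[lo]) / np.maximum(n, 1), -np.inf)
    best = np.lexsort((starts, -mean_d, -n))[0]
    s = int(starts[best])
    return s, s + width, False


def paired_wilcoxon_cpgs(
    treated: np.ndarray, control: np.ndarray
) -> dict[str, float]:
    """Paired Wilcoxon signed-rank test on per-CpG methylation percents.

    Pairs with zero difference are dropped (standard signed-rank
    convention); the direction of change is summarised by the median delta
    rather than folded into the test's sidedness. With fewer than 6
    informative pairs the exact null distribution is used and the result is
    flagged ``small_n``.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated/control must be matched per CpG")
    diff = treated - control
    informative = diff[diff != 0]
    n = int(len(informative))
    if n == 0:
        return {
            "n": 0,
            "statistic": np.nan,
            "p": np.nan,
            "median_delta": 0.0,
            "small_n": True,
        }
    mode = "exact" if n < 26 else "auto"
    res = stats.wilcoxon(informative, alternative="two-sided", method=mode)
    return {
        "n": n,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_delta": float(np.median(diff)),
        "small_n": n < 6,
    }
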