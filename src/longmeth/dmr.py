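"""Differential-methylation tests: windowed DMRs, per-CpG dCpGs, and
replicate-sensitive logistic tests for targeted amplicon data.

A window (or CpG) is called differentially methylated when the chi-squared
test on pooled methylated/unmethylated counts survives FDR control
(adjusted p < 0.05) AND the methylation difference reaches the minimal
cutoff of 10 percentage points. The difference for a window is taken from
the unweighted window means, not from the pooled-count ratio, so the two
definitions (count-based test, mean-based delta) deliberately coexist.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from longmeth.binning import WindowSet


def chi_square_counts(a, b):
    """Pearson chi-squared (df=1, no continuity correction) on 2x2 counts.

    ``a`` and ``b`` are (n_meth, n_unmeth) pairs, scalar or array-valued.
    Degenerate tables — a zero row or column margin — get chi2 = 0, p = 1,
    so downstream FDR input is total.
    """
    ma, ua = np.asarray(a[0], dtype=float), np.asarray(a[1], dtype=float)
    mb, ub = np.asarray(b[0], dtype=float), np.asarray(b[1], dtype=float)
    if np.any(ma < 0) or np.any(ua < 0) or np.any(mb < 0) or np.any(ub < 0):
        raise ValueError("negative counts")
    n = ma + ua + mb + ub
    row_a, row_b = ma + ua, mb + ub
    col_m, col_u = ma + mb, ua + ub
    ok = (row_a > 0) & (row_b > 0) & (col_m > 0) & (col_u > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            ok,
            n * (ma * ub - ua * mb) ** 2
            / np.where(ok, row_a * row_b * col_m * col_u, 1.0),
            0.0,
        )
    p = np.where(ok, stats.chi2.sf(chi2, df=1), 1.0)
    if np.ndim(a[0]) == 0 and np.ndim(b[0]) == 0:
        return float(chi2), float(p)
    return chi2, p


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment; BH step-up by default."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    method_map = {"BH": "fdr_bh", "bonferroni": "bonferroni", "BY": "fdr_by"}
    if method not in method_map:
        raise ValueError(f"unknown correction method: {method!r}")
    return multipletests(p, method=method_map[method])[1]


def call_dmrs(
    windows: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_delta: float = 10.0,
    correction: str = "BH",
) -> pd.DataFrame:
    """Test every window of a contrast for differential methylation.

    ``windows`` is the table from :func:`longmeth.binning.window_methylation`
    with ``meth_g``/``m_g``/``u_g`` columns for both contrast groups.
    ``delta_pp`` is meth(b) − meth(a) in percentage points; ``is_dmr``
    requires adjusted p < ``alpha`` and |delta| ≥ ``min_delta`` (inclusive).
    """
    ga, gb = contrast
    for g in contrast:
        if f"meth_{g}" not in windows.columns:
            raise ValueError(f"contrast group {g!r} missing from window table")
    chi2, p_raw = chi_square_counts(
        (windows[f"m_{ga}"].to_numpy(), windows[f"u_{ga}"].to_numpy()),
        (windows[f"m_{gb}"].to_numpy(), windows[f"u_{gb}"].to_numpy()),
    )
    out = windows[["window_id", "chrom", "start", "end", "n_cpgs"]].copy()
    out["group_a"] = ga
    out["group_b"] = gb
    out["meth_a"] = windows[f"meth_{ga}"].to_numpy()
    out["meth_b"] = windows[f"meth_{gb}"].to_numpy()
    out["delta_pp"] = out["meth_b"] - out["meth_a"]
    out["chi2"] = chi2
    out["p_raw"] = p_raw
    out["p_adj"] = adjust_pvalues(p_raw, method=correction)
    out["is_dmr"] = (out["p_adj"] < alpha) & (out["delta_pp"].abs() >= min_delta)
    out["direction"] = np.where(out["delta_pp"] >= 0, "hyper", "hypo")
    return out


def call_dcpgs(
    group_counts: dict[str, pd.DataFrame],
    contrast: tuple[str, str],
    min_cov: int = 5,
    alpha: float = 0.05,
    min_delta: float = 10.0,
    correction: str = "BH",
) -> pd.DataFrame:
    """Per-CpG differential methylation (the reduced-representation path).

    Only cytosines covered by at least ``min_cov`` observations in both
    compared groups are tested; adjustment runs across the tested CpGs.
    """
    ga, gb = contrast
    for g in contrast:
        if g not in group_counts:
            raise ValueError(f"contrast group {g!r} not in group counts")
    a = group_counts[ga].rename(columns={"n_meth": "m_a", "n_unmeth": "u_a"})
    b = group_counts[gb].rename(columns={"n_meth": "m_b", "n_unmeth": "u_b"})
    merged = a.merge(b, on=["chrom", "pos"], how="inner")
    cov_a = merged["m_a"] + merged["u_a"]
    cov_b = merged["m_b"] + merged["u_b"]
    merged = merged[(cov_a >= min_cov) & (cov_b >= min_cov)].reset_index(drop=True)
    chi2, p_raw = chi_square_counts(
        (merged["m_a"].to_numpy(), merged["u_a"].to_numpy()),
        (merged["m_b"].to_numpy(), merged["u_b"].to_numpy()),
    )
    pct_a = 100.0 * merged["m_a"] / (merged["m_a"] + merged["u_a"])
    pct_b = 100.0 * merged["m_b"] / (merged["m_b"] + merged["u_b"])
    out = merged[["chrom", "pos"]].copy()
    out["delta_pp"] = (pct_b - pct_a).to_numpy()
    out["chi2"] = chi2
    out["p_raw"] = p_raw
    out["p_adj"] = adjust_pvalues(p_raw, method=correction)
    out["is_dcpg"] = (out["p_adj"] < alpha) & (out["delta_pp"].abs() >= min_delta)
    out["direction"] = np.where(out["delta_pp"] >= 0, "hyper", "hypo")
    return out


def _binomial_lrt(groups: np.ndarray, m: np.ndarray, u: np.ndarray):
    """LRT p for a binomial GLM of methylation on group vs intercept-only."""
    endog = np.column_stack([m, u])
    exog = sm.add_constant(groups.astype(float))
    exog0 = np.ones((len(m), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit1 = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        fit0 = sm.GLM(endog, exog0, family=sm.families.Binomial()).fit()
    lrt = 2.0 * (fit1.llf - fit0.llf)
    lrt = max(lrt, 0.0)
    return lrt, float(stats.chi2.sf(lrt, df=1))


def logistic_dcpg(
    replicate_counts: pd.DataFrame,
    alpha: float = 0.05,
    min_cov: int = 3,
    correction: str = "BH",
) -> pd.DataFrame:
    """Replicate-sensitive logistic-regression test per CpG (amplicon data).

    ``replicate_counts`` has columns chrom, pos, sample, group, n_meth,
    n_unmeth with >= 2 replicates per group. Per CpG, a binomial GLM of the
    methylated proportion on the group indicator (weights = coverage) is
    compared with the intercept-only model by likelihood-ratio test; p-values
    are FDR-adjusted across CpGs. No minimal-difference cutoff is applied.

    Replicates below ``min_cov`` coverage are dropped. CpGs with perfect
    separation (one group entirely methylated, the other entirely not) are
    refit after adding 0.5 to every cell (Haldane continuity) and flagged in
    the ``separation_fallback`` column.
    """
    labels = sorted(replicate_counts["group"].unique())
    if len(labels) != 2:
        raise ValueError("logistic test needs exactly two groups")
    rows = []
    for (chrom, pos), sub in replicate_counts.groupby(["chrom", "pos"], sort=True):
        sub = sub[(sub["n_meth"] + sub["n_unmeth"]) >= min_cov]
        n_per_group = sub["group"].value_counts()
        if any(n_per_group.get(g, 0) < 2 for g in labels):
            raise ValueError(
                f"{chrom}:{pos}: need >= 2 replicates with coverage >= "
                f"{min_cov} in each group"
            )
        g = (sub["group"] == labels[1]).to_numpy()
        m = sub["n_meth"].to_numpy(dtype=float)
        u = sub["n_unmeth"].to_numpy(dtype=float)
        prop = m / (m + u)
        fallback = False
        # boundary MLE: a group entirely (un)methylated sends its logit to ±inf
        sep = any(
            prop[sel].min() >= 1.0 or prop[sel].max() <= 0.0 for sel in (g, ~g)
        )
        if sep:
            lrt, p = _binomial_lrt(g, m + 0.5, u + 0.5)
            fallback = True
        else:
            lrt, p = _binomial_lrt(g, m, u)
        with np.errstate(invalid="ignore"):
            mean_a = 100.0 * np.average(prop[~g], weights=m[~g] + u[~g])
            mean_b = 100.0 * np.average(prop[g], weights=m[g] + u[g])
        rows.append((chrom, pos, mean_b - mean_a, lrt, p, fallback))
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "delta_pp", "lrt", "p_raw", "separation_fallback"]
    )
    out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), method=correction)
    out["is_dcpg"] = out["p_adj"] < alpha
    out["direction"] = np.where(out["delta_pp"] >= 0, "hyper", "hypo")
    return out


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Significant DMRs as BED: score = −log10 adjusted p, name = direction."""
    sig = dmrs[dmrs["is_dmr"]].copy()
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(sig["p_adj"].to_numpy(), 1e-300))
    return pd.DataFrame(
        {
            "chrom": sig["chrom"],
            "start": sig["start"],
            "end": sig["end"],
            "name": sig["direction"],
            "score": np.round(score, 3),
        }
    )
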