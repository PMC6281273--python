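"""Derived gene annotations and methylation-expression integration.

Promoters stretch 5 kb upstream to 100 bp downstream of the TSS; uiDMRs
(undefined intragenic DMRs, where gene-body methylation anticorrelates with
expression) stretch 0.3–8 kb downstream of the TSS, restricted to genes of
at least 16 kb. CpG islands are classified unambiguously as promoter, gene
or intergenic, with promoter taking precedence. Gene-level methylation
calls are coupled to differential-expression tables through sign-quadrant
counts and an exact binomial test on the hypermethylated, differentially
expressed genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from longmeth.enrichment import annotate_windows


def promoter_region(gene: pd.Series, up: int = 5000, down: int = 100) -> tuple[int, int]:
    """Strand-aware promoter interval around the TSS, clipped at position 0."""
    tss = int(gene["tss"])
    if gene["strand"] == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down, tss + up + 1
    return max(start, 0), end


def promoter_track(genes: pd.DataFrame, up: int = 5000, down: int = 100) -> pd.DataFrame:
    rows = []
    for _, g in genes.iterrows():
        s, e = promoter_region(g, up=up, down=down)
        rows.append((g["chrom"], s, e, g["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def uidmr_region(
    gene: pd.Series,
    downstream_from: int = 300,
    downstream_to: int = 8000,
    min_gene_bp: int = 16_000,
) -> tuple[int, int] | None:
    """uiDMR interval 0.3–8 kb downstream of the TSS; None for short genes."""
    if int(gene["end"]) - int(gene["start"]) < min_gene_bp:
        return None
    tss = int(gene["tss"])
    if gene["strand"] == "+":
        return tss + downstream_from, tss + downstream_to
    return tss - downstream_to + 1, tss - downstream_from + 1


def uidmr_track(genes: pd.DataFrame, **kwargs) -> pd.DataFrame:
    rows = []
    for _, g in genes.iterrows():
        iv = uidmr_region(g, **kwargs)
        if iv is not None:
            rows.append((g["chrom"], iv[0], iv[1], g["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def classify_cgis(
    cgis: pd.DataFrame, promoters: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Label each CpG island as promoter, gene or intergenic.

    Promoter overlap wins over gene-body overlap; anything else is
    intergenic. The labels partition the CGI set.
    """
    in_promoter = annotate_windows(cgis, promoters)
    gene_bodies = genes.rename(columns={"gene_id": "name"})[
        ["chrom", "start", "end", "name"]
    ]
    in_gene = annotate_windows(cgis, gene_bodies)
    labels = np.where(in_promoter, "promoter", np.where(in_gene, "gene", "intergenic"))
    return pd.Series(labels, index=cgis.index, name="cgi_class")


def genes_with_uidmr_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    min_dmrs: int = 1,
    min_avg_delta: float = 10.0,
    **uidmr_kwargs,
) -> pd.DataFrame:
    """Gene-level methylation calls restricted to uiDMR intervals.

    A DMR counts for a gene when it overlaps the gene's uiDMR interval by
    >= 1 bp; one overlapping DMR suffices by default. Deltas of multiple
    DMRs are averaged before the sign is taken.
    """
    sig = dmrs[dmrs["is_dmr"]]
    rows = []
    for _, g in genes.iterrows():
        iv = uidmr_region(g, **uidmr_kwargs)
        if iv is None:
            continue
        dsub = sig[sig["chrom"] == g["chrom"]]
        hit = (dsub["start"].to_numpy() < iv[1]) & (dsub["end"].to_numpy() > iv[0])
        n = int(hit.sum())
        avg = float(dsub["delta_pp"].to_numpy()[hit].mean()) if n else np.nan
        rows.append((g["gene_id"], n, avg))
    out = pd.DataFrame(rows, columns=["gene_id", "n_dmrs", "avg_delta_pp"])
    out["retained"] = (out["n_dmrs"] >= min_dmrs) & (
        out["avg_delta_pp"].abs() >= min_avg_delta
    )
    out["direction"] = np.where(out["avg_delta_pp"] >= 0, "hyper", "hypo")
    out.loc[out["n_dmrs"] == 0, "direction"] = "none"
    return out


def methylation_expression_quadrants(
    gene_calls: pd.DataFrame,
    expression: pd.DataFrame,
    min_avg_delta: float = 10.0,
    alternative: str = "two-sided",
) -> dict:
    """Couple gene-level methylation calls to expression changes.

    Genes are matched by id; quadrant counts cross the sign of the average
    methylation delta with the sign of the expression log2 fold change over
    retained genes (|avg delta| >= cutoff; zero log2fc excluded from the
    quadrants). Among hypermethylated genes that are also differentially
    expressed, an exact binomial test (p0 = 0.5) probes for a trend towards
    down- or up-regulation.

    Returns a dict with the quadrant table, hyper+DE down/up counts, the
    binomial p (NaN, flagged, when no hyper+DE genes exist) and the merged
    per-gene table.
    """
    merged = gene_calls.merge(expression, on="gene_id", how="inner")
    retained = merged[
        (merged["n_dmrs"] > 0) & (merged["avg_delta_pp"].abs() >= min_avg_delta)
    ].copy()
    quad = retained[retained["log2fc"] != 0]
    q_pp = int(((quad["avg_delta_pp"] > 0) & (quad["log2fc"] > 0)).sum())
    q_pn = int(((quad["avg_delta_pp"] > 0) & (quad["log2fc"] < 0)).sum())
    q_np = int(((quad["avg_delta_pp"] < 0) & (quad["log2fc"] > 0)).sum())
    q_nn = int(((quad["avg_delta_pp"] < 0) & (quad["log2fc"] < 0)).sum())
    hyper_de = quad[(quad["avg_delta_pp"] > 0) & quad["is_de"]]
    n_down = int((hyper_de["log2fc"] < 0).sum())
    n_up = int((hyper_de["log2fc"] > 0).sum())
    if n_down + n_up == 0:
        p = np.nan
        undefined = True
    else:
        p = float(
            stats.binomtest(n_down, n_down + n_up, p=0.5, alternative=alternative).pvalue
        )
        undefined = False
    return {
        "quadrants": {"q_pp": q_pp, "q_pn": q_pn, "q_np": q_np, "q_nn": q_nn},
        "n_hyper_down": n_down,
        "n_hyper_up": n_up,
        "binomial_p": p,
        "binomial_undefined": undefined,
        "genes": merged,
    }


def transcriptome_concordance(
    log2fc_a: pd.Series | dict,
    log2fc_b: pd.Series | dict,
    universe_size: int | None = None,
) -> dict:
    """Directional concordance of two differential-expression signatures.

    Over genes differentially expressed in both conditions: sign-quadrant
    counts and a one-sided Fisher test for concordance. When
    ``universe_size`` (the number of expressed genes) is given, a second
    one-sided Fisher tests whether the two DE gene sets overlap more than
    expected.
    """
    a = pd.Series(log2fc_a, dtype=float)
    b = pd.Series(log2fc_b, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared genes between the two signatures")
    av, bv = a[common], b[common]
    keep = (av != 0) & (bv != 0)
    av, bv = av[keep], bv[keep]
    pp = int(((av > 0) & (bv > 0)).sum())
    pn = int(((av > 0) & (bv < 0)).sum())
    np_ = int(((av < 0) & (bv > 0)).sum())
    nn = int(((av < 0) & (bv < 0)).sum())
    _, p_dir = stats.fisher_exact([[pp, pn], [np_, nn]], alternative="greater")
    result = {
        "quadrants": {"q_pp": pp, "q_pn": pn, "q_np": np_, "q_nn": nn},
        "p_directionality": float(p_dir),
    }
    if universe_size is not None:
        inter = len(common)
        only_a = len(a) - inter
        only_b = len(b) - inter
        rest = universe_size - inter - only_a - only_b
        if rest < 0:
            raise ValueError("universe smaller than the union of gene sets")
        _, p_overlap = stats.fisher_exact(
            [[inter, only_a], [only_b, rest]], alternative="greater"
        )
        result["p_overlap"] = float(p_overlap)
    return result
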