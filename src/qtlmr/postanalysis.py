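"""Contextualization of causal calls: tissue expression, enrichment, overlap.

These operations consume the cascade's decision tables together with
user-supplied annotation inputs (a gene × tissue median-TPM matrix, curated
gene sets, mechanistic cluster assignments, gene coordinates) and produce the
descriptive summaries used to interpret a study: which causal genes are
expressed where, whether causal effects are enriched in known disease genes
or mechanism clusters, how calls overlap and disagree across tissues, and how
causal genes relate to previously prioritized genes at the same locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .cascade import bh_fdr
from .estimators import HeterogeneityStats


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows in-set / not-in-set, cols causal / not-causal
    odds_ratio: float
    p: float
    fold: float
    q: float = math.nan
    label: str = ""


def expression_filter(expr: pd.DataFrame, threshold: float = 0.1) -> dict[str, set]:
    """Tissues in which each gene is expressed (median TPM strictly above threshold)."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix has negative entries")
    mask = expr > threshold
    return {g: set(expr.columns[mask.loc[g]]) for g in expr.index}


def fisher_enrichment(causal: set, tested: set, annotation: GeneSet,
                      label: str = "") -> EnrichmentResult:
    """Two-sided Fisher's exact test of causal-call enrichment in a gene set.

    The 2x2 table is built over tested genes only; fold enrichment is the
    percentage of causal calls inside the set over the percentage outside.
    Infinite sample odds ratios are reported as ``inf`` with the exact
    hypergeometric p still computed.
    """
    if not tested:
        raise ValueError("tested gene set is empty")
    if not causal <= tested:
        raise ValueError("causal genes must be a subset of tested genes")
    in_set = tested & annotation.genes
    a = len(in_set & causal)
    b = len(in_set - causal)
    c = len(causal - in_set)
    d = len(tested - in_set - causal)
    table = np.array([[a, b], [c, d]])
    if a + b == 0 or c + d == 0:
        return EnrichmentResult(table, math.nan, 1.0, math.nan, label=label)
    _, p = _st.fisher_exact(table, alternative="two-sided")
    odds = math.inf if b * c == 0 and a * d > 0 else (
        math.nan if b * c == 0 else a * d / (b * c))
    pct_in = a / (a + b)
    pct_out = c / (c + d)
    fold = math.inf if (pct_out == 0 and pct_in > 0) else (
        math.nan if pct_out == 0 else pct_in / pct_out)
    return EnrichmentResult(table, odds, float(p), fold, label=label)


def cluster_tissue_enrichment(
    gene_clusters: dict[str, str],
    results: pd.DataFrame,
) -> pd.DataFrame:
    """Per (tissue, cluster) Fisher enrichment of causal calls, BH-corrected.

    ``results`` has one row per (gene, tissue) with a boolean ``causal``
    column covering the tested genes. Pairs whose cluster shares no causal
    gene with the tissue are excluded before the FDR, mirroring the
    at-least-one-overlapping-gene rule.
    """
    rows = []
    for tissue, sub in results.groupby("tissue"):
        tested = set(sub["gene"])
        causal = set(sub.loc[sub["causal"], "gene"])
        for cluster in sorted(set(gene_clusters.values())):
            members = {g for g, c in gene_clusters.items() if c == cluster}
            if not (members & causal):
                continue
            res = fisher_enrichment(causal, tested,
                                    GeneSet(cluster, frozenset(members)))
            rows.append({"tissue": tissue, "cluster": cluster,
                         "odds_ratio": res.odds_ratio, "p": res.p, "fold": res.fold,
                         "a": res.table[0, 0], "b": res.table[0, 1],
                         "c": res.table[1, 0], "d": res.table[1, 1]})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out["p"])
    return out


def tissue_overlap(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, int, int]:
    """Pairwise overlap of causal calls across tissues.

    ``calls`` has one row per (gene, tissue) with ``causal`` and ``estimate``
    columns. Returns the symmetric overlap-count matrix (diagonal =
    per-tissue totals), the per-gene causal-tissue counts, the number of
    genes causal in >= 2 tissues and the number of those with sign-concordant
    estimates across all their causal tissues.
    """
    caus = calls[calls["causal"]]
    tissues = sorted(calls["tissue"].unique())
    sets = {t: set(caus.loc[caus["tissue"] == t, "gene"]) for t in tissues}
    mat = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    for t1 in tissues:
        for t2 in tissues:
            mat.loc[t1, t2] = len(sets[t1] & sets[t2])
    per_gene = caus.groupby("gene")["tissue"].nunique()
    multi = per_gene[per_gene >= 2].index
    n_multi = len(multi)
    n_concordant = 0
    for g in multi:
        est = caus.loc[caus["gene"] == g, "estimate"]
        if est.notna().all() and (np.sign(est) == np.sign(est.iloc[0])).all():
            n_concordant += 1
    return mat, per_gene, n_multi, n_concordant


def tissue_heterogeneity(estimates: pd.DataFrame) -> tuple[pd.DataFrame, float, int]:
    """Cochran's Q / I² of per-gene causal estimates across tissues.

    ``estimates`` has one row per (gene, tissue) with ``estimate`` and ``se``.
    Genes with a single tissue are excluded (and counted). Returns the
    per-gene table, the fraction of included genes with nominally significant
    Q, and the number of excluded single-tissue genes.
    """
    rows = []
    n_single = 0
    for gene, sub in estimates.groupby("gene"):
        sub = sub.dropna(subset=["estimate", "se"])
        if len(sub) < 2:
            n_single += 1
            continue
        y = sub["estimate"].to_numpy()
        w = 1.0 / sub["se"].to_numpy() ** 2
        pooled = np.sum(w * y) / np.sum(w)
        Q = float(np.sum(w * (y - pooled) ** 2))
        df = len(sub) - 1
        het = HeterogeneityStats(Q=Q, df=df, p=float(_st.chi2.sf(Q, df)))
        rows.append({"gene": gene, "n_tissues": len(sub), "Q": het.Q,
                     "Q_p": het.p, "I2": het.I2})
    out = pd.DataFrame(rows)
    frac_sig = float((out["Q_p"] < 0.05).mean()) if not out.empty else math.nan
    return out, frac_sig, n_single


def locus_overlap(
    causal_genes: pd.DataFrame,
    reference: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.Series:
    """Group causal genes by locus overlap with a curated reference set.

    Both frames carry ``gene``, ``chrom`` and ``midpoint`` columns. Groups:
    1 = no reference gene within the window; 2 = the causal gene itself is in
    the reference set (takes precedence); 3 = a different reference gene lies
    within ``window_bp``/2 of the gene's midpoint. Genes lacking coordinates
    are reported as group 0 (ungrouped).
    """
    half = window_bp // 2
    ref_genes = set(reference["gene"])
    groups = {}
    for r in causal_genes.itertuples():
        if pd.isna(r.midpoint) or pd.isna(r.chrom):
            groups[r.gene] = 0
            continue
        if r.gene in ref_genes:
            groups[r.gene] = 2
            continue
        near = reference[
            (reference["chrom"].astype(str) == str(r.chrom))
            & ((reference["midpoint"] - r.midpoint).abs() <= half)
        ]
        groups[r.gene] = 3 if len(near) else 1
    return pd.Series(groups, name="locus_group")
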