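"""End-to-end orchestration of the cis-MR cascade over a study bundle.

Glue between the synthetic-data generator (or loaded summary statistics) and
the per-trait machinery: instrument selection, IVW, within-cohort FDR, and —
for FDR-significant traits — the sensitivity suite, colocalization and the
final causal call. Sensitivity and colocalization are computed lazily: a
trait failing the FDR criterion can never be called causal, so the expensive
layers are skipped and their flags recorded as not-applicable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cascade import CascadeThresholds, CausalDecision, bh_fdr, call_causal
from .coloc import ColocPriors, ColocResult, PwcocoConfig, pwcoco
from .estimators import MRResult, ivw
from .instruments import InstrumentSet, IVConfig, select_instruments
from .sensitivity import SensitivityConfig, SensitivitySuite, run_sensitivity_suite
from .simulate import StudyBundle


@dataclass
class TraitAnalysis:
    """Everything computed for one (gene, ancestry, tissue) trait."""

    trait_id: str
    ancestry: str
    tissue: str | None
    instruments: InstrumentSet
    mr: MRResult
    q: float = math.nan
    suite: SensitivitySuite | None = None
    coloc: ColocResult | None = None
    decision: CausalDecision | None = None


@dataclass
class PipelineConfig:
    iv: IVConfig = field(default_factory=IVConfig)
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)
    priors: ColocPriors = field(default_factory=ColocPriors)
    pwcoco: PwcocoConfig = field(default_factory=PwcocoConfig)
    thresholds: CascadeThresholds = field(default_factory=CascadeThresholds)
    always_run_full: bool = False  # force sensitivity/coloc even when q fails


def analyze_cohort(
    bundle: StudyBundle,
    ancestry: str,
    tissue: str,
    cfg: PipelineConfig | None = None,
) -> dict[str, TraitAnalysis]:
    """Single-ancestry, single-tissue analysis of every gene in a bundle.

    Returns per-trait analyses keyed by gene id; the FDR correction is
    applied within this (cohort x tissue) analysis, per the cascade's
    stratification rule.
    """
    cfg = cfg or PipelineConfig()
    outcome = bundle.outcomes[ancestry]
    analyses: dict[str, TraitAnalysis] = {}

    for gene_id, annot in bundle.genes.items():
        key = (gene_id, ancestry, tissue)
        if key not in bundle.exposures:
            continue
        exposure = bundle.exposures[key]
        panel = bundle.gene_panels.get((gene_id, ancestry), bundle.panels[ancestry])
        insts = select_instruments(exposure, outcome, panel, annot, cfg.iv)
        if insts.n_iv == 0:
            continue  # trait not tested
        mr, _ = ivw(insts)
        analyses[gene_id] = TraitAnalysis(gene_id, ancestry, tissue, insts, mr)

    if not analyses:
        return analyses
    ids = list(analyses)
    qs = bh_fdr([analyses[g].mr.p for g in ids])
    for g, q in zip(ids, qs):
        analyses[g].q = float(q)

    for g in ids:
        ta = analyses[g]
        needs_full = cfg.always_run_full or ta.q < cfg.thresholds.q_max
        if needs_full:
            exposure = bundle.exposures[(g, ancestry, tissue)]
            panel = bundle.gene_panels.get((g, ancestry), bundle.panels[ancestry])
            n_exp = bundle.truth[g].n_exp if g in bundle.truth else None
            ta.suite = run_sensitivity_suite(ta.instruments, cfg.sensitivity,
                                             exposure_n=n_exp)
            annot = bundle.genes[g]
            lo = max(annot.tss - cfg.iv.cis_window_bp, 1)
            hi = annot.tss + cfg.iv.cis_window_bp
            exp_loc = exposure.in_window(annot.chrom, lo, hi)
            out_loc = outcome.subset(exp_loc.df["id"])
            ta.coloc = pwcoco(exp_loc, out_loc, panel, cfg.priors, cfg.pwcoco)
        ta.decision = call_causal(ta.mr, ta.q, ta.suite, ta.coloc, cfg.thresholds,
                                  trait_id=g, ancestry=ancestry, tissue=tissue)
    return analyses


def decisions_frame(analyses: dict[str, TraitAnalysis]) -> pd.DataFrame:
    """One row per trait: MR estimate, q, criterion flags, causal call."""
    rows = []
    for g, ta in analyses.items():
        d = ta.decision
        rows.append({
            "trait_id": g, "ancestry": ta.ancestry, "tissue": ta.tissue,
            "n_iv": ta.instruments.n_iv,
            "estimate": ta.mr.estimate, "se": ta.mr.se, "p": ta.mr.p, "q": ta.q,
            "or": math.exp(ta.mr.estimate),
            "crit_q": d.crit_q, "crit_sensitivity": d.crit_sensitivity,
            "crit_het_pleio": d.crit_het_pleio, "crit_coloc": d.crit_coloc,
            "causal": d.causal,
            "pph4": ta.coloc.max_pph4 if ta.coloc is not None else math.nan,
        })
    return pd.DataFrame(rows)
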