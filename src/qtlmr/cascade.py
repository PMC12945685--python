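"""Causal-call cascade, replication evaluation and cross-ancestry meta-analysis.

A trait is declared causal when it passes, jointly: (1) FDR-adjusted IVW (or
Wald-ratio) significance within its cohort, (2) sign-concordant sensitivity
estimates, (3) no significant heterogeneity (I² < 50) or directional
pleiotropy (Egger intercept), and (4) colocalization with PPH4 > 0.8.
Criteria 2-3 are recorded as not-applicable — and excluded from the
conjunction — for single-instrument traits, where no sensitivity method can
run. Comparators are strict as stated (q < 0.05, I² < 50, PPH4 > 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .coloc import ColocResult
from .estimators import MRResult
from .sensitivity import SensitivitySuite


@dataclass
class CascadeThresholds:
    q_max: float = 0.05
    i2_max: float = 50.0
    egger_alpha: float = 0.05
    pph4_min: float = 0.8
    # criterion (3) requires NO significant Egger pleiotropy (intercept p >= alpha);
    # flip to False to require significance instead (the alternative reading)
    egger_requires_nonsignificant: bool = True


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CausalDecision:
    trait_id: str
    ancestry: str
    tissue: str | None
    q: float
    crit_q: bool
    crit_sensitivity: bool | None
    crit_het_pleio: bool | None
    crit_coloc: bool | None
    causal: bool

    def to_row(self) -> dict:
        return {
            "trait_id": self.trait_id, "ancestry": self.ancestry, "tissue": self.tissue,
            "q": self.q, "crit_q": self.crit_q, "crit_sensitivity": self.crit_sensitivity,
            "crit_het_pleio": self.crit_het_pleio, "crit_coloc": self.crit_coloc,
            "causal": self.causal,
        }


def call_causal(
    mr: MRResult,
    q: float,
    suite: SensitivitySuite | None,
    coloc: ColocResult | None,
    thresholds: CascadeThresholds | None = None,
    trait_id: str = "trait",
    ancestry: str = "NA",
    tissue: str | None = None,
) -> CausalDecision:
    """Combine the evidence layers into a per-trait causal call.

    ``suite`` / ``coloc`` may be None when the pipeline short-circuited them
    (e.g. the FDR criterion already failed); the corresponding flags are then
    not-applicable, and the call is negative because criterion 1 (and 4, which
    is always required) cannot both hold.
    """
    th = thresholds or CascadeThresholds()
    crit_q = q < th.q_max

    crit_sens: bool | None = None
    crit_hp: bool | None = None
    if suite is not None:
        crit_sens = suite.concordant
        i2_ok = suite.het.I2 < th.i2_max if suite.het.applicable else None
        if suite.egger.applicable:
            ip = suite.egger.extra["intercept_p"]
            egger_ok = (ip >= th.egger_alpha) if th.egger_requires_nonsignificant else (ip < th.egger_alpha)
        else:
            egger_ok = None
        parts = [x for x in (i2_ok, egger_ok) if x is not None]
        crit_hp = all(parts) if parts else None

    crit_coloc: bool | None = None
    if coloc is not None and coloc.applicable:
        crit_coloc = coloc.max_pph4 > th.pph4_min
    elif coloc is not None:
        crit_coloc = False

    causal = (
        crit_q
        and crit_coloc is True
        and crit_sens in (True, None)
        and crit_hp in (True, None)
    )
    return CausalDecision(trait_id, ancestry, tissue, q, crit_q, crit_sens,
                          crit_hp, crit_coloc, causal)


# ---------------------------------------------------------------------------
# replication


@dataclass
class ReplicationOutcome:
    trait_id: str
    q_replication: float
    direction_concordant: bool
    replicated: bool


def evaluate_replication(
    discovery: list[CausalDecision],
    replication_mr: dict[str, MRResult],
    discovery_mr: dict[str, MRResult],
) -> list[ReplicationOutcome]:
    """Replication of discovery-causal traits in an independent cohort.

    FDR is applied over exactly the discovery-causal traits testable in the
    replication set; a trait replicates when its replication q-value is
    below 5% with a direction of effect concordant with the discovery IVW
    estimate. Traits absent from the replication data are excluded entirely
    (they do not enter the FDR set or any rate denominator).
    """
    causal_ids = [d.trait_id for d in discovery if d.causal]
    tested = [t for t in causal_ids if t in replication_mr and replication_mr[t].applicable]
    if not tested:
        return []
    qs = bh_fdr([replication_mr[t].p for t in tested])
    out = []
    for t, q in zip(tested, qs):
        conc = math.copysign(1, replication_mr[t].estimate) == math.copysign(
            1, discovery_mr[t].estimate)
        out.append(ReplicationOutcome(t, float(q), bool(conc),
                                      bool(q < 0.05 and conc)))
    return out


def replication_ladder(
    discovery: pd.DataFrame,
    replication_mr: dict[str, MRResult],
) -> pd.DataFrame:
    """Replication rate under five nested discovery-significance criteria.

    ``discovery`` needs one row per trait with columns: trait_id, p, q,
    crit_sensitivity, crit_het_pleio, crit_coloc, n_iv. Rows of the ladder:
    (1) all tested traits, (2) nominal p < 0.05, (3) q < 0.05, (4) + sign-
    concordant sensitivity with no heterogeneity/pleiotropy, (5) + coloc;
    row 5 is additionally split by single- vs multi-IV. The replication rate
    is the proportion of tested traits with replication q < 0.05, the FDR
    being recomputed within each row's tested set.
    """
    def _ok(v):  # not-applicable counts as pass (cannot be evaluated)
        return (v is True) or (v is None) or (isinstance(v, float) and math.isnan(v))

    d = discovery
    crits = {
        "1_all_tested": pd.Series(True, index=d.index),
        "2_nominal_p": d["p"] < 0.05,
        "3_fdr_q": d["q"] < 0.05,
        "4_sensitivity": (d["q"] < 0.05)
        & d["crit_sensitivity"].map(_ok) & d["crit_het_pleio"].map(_ok),
    }
    crits["5_colocalization"] = crits["4_sensitivity"] & (d["crit_coloc"] == True)  # noqa: E712

    rows = []

    def _rate(sub: pd.DataFrame, label: str):
        traits = [t for t in sub["trait_id"]
                  if t in replication_mr and replication_mr[t].applicable]
        n_sig = len(sub)
        if not traits:
            rows.append({"criterion": label, "n_significant": n_sig, "n_tested": 0,
                         "n_replicated": 0, "rate": math.nan})
            return
        qs = bh_fdr([replication_mr[t].p for t in traits])
        n_rep = int(np.sum(qs < 0.05))
        rows.append({"criterion": label, "n_significant": n_sig, "n_tested": len(traits),
                     "n_replicated": n_rep, "rate": n_rep / len(traits)})

    for label, mask in crits.items():
        _rate(d[mask], label)
    final = d[crits["5_colocalization"]]
    _rate(final[final["n_iv"] == 1], "5_colocalization_single_iv")
    _rate(final[final["n_iv"] > 1], "5_colocalization_multi_iv")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-ancestry meta-analysis


@dataclass
class MetaResult:
    estimate: float
    se: float
    p: float
    k: int
    tau2: float
    Q_ancestry: float
    Q_p: float
    q: float = math.nan
    significant: bool = False


def meta_analyze(per_ancestry: list[MRResult], method: str = "DL") -> MetaResult:
    """Random-effects IVW pooling of per-ancestry log-OR estimates.

    DerSimonian-Laird by default: tau² = max(0, (Q-(k-1))/(Σw - Σw²/Σw)) with
    fixed-effect weights w = 1/se²; ``method="REML"`` iterates the restricted
    likelihood instead. Cochran's Q across ancestries is reported either way.
    Requires estimates from at least two ancestries.
    """
    res = [r for r in per_ancestry if r.applicable]
    k = len(res)
    if k < 2:
        raise ValueError("meta-analysis requires estimates from at least two ancestries")
    y = np.array([r.estimate for r in res])
    v = np.array([r.se**2 for r in res])
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    Q_p = float(_st.chi2.sf(Q, k - 1))

    if method.upper() == "DL":
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    elif method.upper() == "REML":
        tau2 = max(0.0, (Q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        for _ in range(200):
            ws = 1.0 / (v + tau2)
            mu = np.sum(ws * y) / np.sum(ws)
            num = np.sum(ws**2 * ((y - mu) ** 2 - v)) + np.sum(ws**2) / np.sum(ws)
            new = max(0.0, float(num / np.sum(ws**2)))
            if abs(new - tau2) < 1e-12:
                tau2 = new
                break
            tau2 = new
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")

    ws = 1.0 / (v + tau2)
    est = float(np.sum(ws * y) / np.sum(ws))
    se = float(1.0 / math.sqrt(np.sum(ws)))
    p = float(2 * _st.norm.sf(abs(est / se)))
    return MetaResult(est, se, p, k, float(tau2), Q, Q_p)


def call_meta_significant(
    meta: MetaResult,
    per_cohort: list[dict],
    thresholds: CascadeThresholds | None = None,
) -> bool:
    """Meta-analysis significance rule.

    Significant iff the meta q-value is below 5% and at least one entering
    cohort shows compelling evidence: nominally significant p together with
    its sensitivity and colocalization criteria met in that same cohort.
    ``per_cohort`` entries carry ``p`` and the cohort's ``decision``
    (:class:`CausalDecision`).
    """
    th = thresholds or CascadeThresholds()
    if not (meta.q < th.q_max):
        return False
    for entry in per_cohort:
        d: CausalDecision = entry["decision"]
        if (
            entry["p"] < 0.05
            and d.crit_sensitivity in (True, None)
            and d.crit_het_pleio in (True, None)
            and d.crit_coloc is True
        ):
            return True
    return False
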