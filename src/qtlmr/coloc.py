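"""Approximate-Bayes-factor colocalization with pairwise conditional analysis.

``abf_coloc`` is the classic single-causal-variant posterior over five
hypotheses (H0: no association, H1/H2: one trait only, H3: distinct causal
variants, H4: shared causal variant) built from per-variant Wakefield
approximate Bayes factors. ``pwcoco`` extends it to multi-signal loci: when
the marginal run yields PPH4 below the acceptance threshold, secondary
association signals are isolated by approximate conditional analysis from
marginal statistics plus reference LD, and colocalization is re-run on every
pair of conditioned (and conditioned-vs-marginal) datasets, reporting the
maximal PPH4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats as _st

from .simulate import ReferencePanel
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causality (field-standard defaults)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= min(p1, p2) < 1")


#: prior standard deviation of true effects for the Wakefield ABF
PRIOR_SD = {"quantitative": 0.20, "case_control": 0.15}


@dataclass
class ColocResult:
    pph: np.ndarray  # H0..H4
    n_variants: int
    conditioned_on: tuple[list[str], list[str]] = field(default_factory=lambda: ([], []))
    max_pph4: float = 0.0
    pairs_tested: int = 1
    pair_table: pd.DataFrame | None = None
    applicable: bool = True
    reason: str | None = None

    @property
    def pph4(self) -> float:
        return float(self.pph[4])

    @classmethod
    def not_applicable(cls, reason: str) -> "ColocResult":
        return cls(pph=np.full(5, math.nan), n_variants=0, applicable=False,
                   reason=reason, max_pph4=math.nan)


def wakefield_labf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Per-variant log approximate Bayes factor against the null."""
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def _intersect(stats1: SumStats, stats2: SumStats) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = stats1.df.set_index("id")
    b = stats2.df.set_index("id")
    common = a.index.intersection(b.index)
    return a.loc[common], b.loc[common]


def abf_coloc(
    stats1: SumStats,
    stats2: SumStats,
    priors: ColocPriors | None = None,
    trait_types: tuple[str, str] = ("quantitative", "case_control"),
) -> ColocResult:
    """Single-causal-variant colocalization of two locus slices.

    Hypothesis posteriors are sums over all single-causal configurations,
    assembled in log space; PPH0..4 are normalized to 1.
    """
    priors = priors or ColocPriors()
    a, b = _intersect(stats1, stats2)
    m = len(a)
    if m < 2:
        return ColocResult.not_applicable("fewer than 2 shared variants")
    l1 = wakefield_labf(a["beta"].to_numpy(), a["se"].to_numpy(), PRIOR_SD[trait_types[0]])
    l2 = wakefield_labf(b["beta"].to_numpy(), b["se"].to_numpy(), PRIOR_SD[trait_types[1]])
    if not (np.all(np.isfinite(l1)) and np.all(np.isfinite(l2))):
        return ColocResult.not_applicable("non-finite Bayes factors")

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over i != j of exp(l1_i + l2_j), in log space
    both = s1 + s2
    if both - s12 > 1e-12:
        s3 = both + math.log1p(-math.exp(s12 - both))
    else:  # degenerate: all cross mass on the diagonal
        s3 = -math.inf

    lh = np.array([
        0.0,
        math.log(priors.p1) + s1,
        math.log(priors.p2) + s2,
        math.log(priors.p1) + math.log(priors.p2) + s3,
        math.log(priors.p12) + s12,
    ])
    lh -= logsumexp(lh)
    pph = np.exp(lh)
    return ColocResult(pph=pph, n_variants=m, max_pph4=float(pph[4]), pairs_tested=1)


# ---------------------------------------------------------------------------
# approximate conditional analysis (COJO-style, standardized scale)


def _std_effects(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-scores, sample sizes and standardized betas z/sqrt(n - 2 + z²)."""
    z = (df["beta"] / df["se"]).to_numpy()
    n = df["n"].to_numpy(dtype=float)
    if np.any(~np.isfinite(n)):
        raise ValueError("conditional analysis needs per-variant sample size")
    b_std = z / np.sqrt(n - 2 + z**2)
    return z, n, b_std


def cojo_condition(
    stats: SumStats,
    panel: ReferencePanel,
    conditioning: list[str],
    cond_limit: float = 1e8,
) -> pd.DataFrame:
    """Approximate conditional beta/se from marginal statistics + reference LD.

    Marginal effects are mapped to the standardized-genotype scale, the
    conditioning set is fitted jointly through the LD submatrix, and each
    remaining variant's marginal effect is residualized on the conditioning
    set. Returns a copy of the canonical frame with conditional beta/se/p.
    """
    out = stats.df.copy()
    if not conditioning:
        return out
    ids = list(out["id"])
    missing = [c for c in conditioning if c not in ids or c not in panel]
    if missing:
        raise ValueError(f"conditioning variants absent from stats/panel: {missing}")
    _, n, b_std = _std_effects(out)
    R = panel.ld_dense(ids)
    pos = {v: i for i, v in enumerate(ids)}
    ci = [pos[c] for c in conditioning]
    Rcc = R[np.ix_(ci, ci)]
    if np.linalg.cond(Rcc) > cond_limit:
        raise np.linalg.LinAlgError("conditioning LD submatrix is near-singular")
    joint = np.linalg.solve(Rcc, b_std[ci])
    b_cond_std = b_std - R[:, ci] @ joint
    se_std = 1.0 / np.sqrt(n)
    z_cond = b_cond_std * np.sqrt(n - 2 + (out["beta"] / out["se"]).to_numpy() ** 2)
    # report on the original scale: keep marginal se, rescale beta to z_cond
    out["beta"] = z_cond * out["se"].to_numpy()
    out["p"] = np.maximum(2 * _st.norm.sf(np.abs(z_cond)), np.finfo(float).tiny)
    del se_std
    return out


@dataclass
class ConditionalSignal:
    lead: str
    conditioned_on: list[str]
    stats: SumStats  # association conditioned on the *other* leads


def select_signals(
    stats: SumStats,
    panel: ReferencePanel,
    p_threshold: float = 1e-5,
    collinearity_r2: float = 0.9,
    max_signals: int = 10,
) -> list[ConditionalSignal]:
    """Stepwise selection of independent association signals at a locus.

    Seeds with the minimum-p variant, then repeatedly adds the variant with
    the smallest conditional p below ``p_threshold`` whose r² with all
    selected leads stays below ``collinearity_r2``. Each returned signal
    carries the locus statistics conditioned on the other leads.
    """
    df = stats.df
    leads: list[str] = []
    current = df.copy()
    while len(leads) < max_signals:
        cand = current[~current["id"].isin(leads)]
        if cand.empty:
            break
        best = cand.loc[cand["p"].idxmin()]
        if not best["p"] < p_threshold:
            break
        ok = all(panel.r2(best["id"], l) < collinearity_r2 for l in leads)
        if not ok:
            current = current[current["id"] != best["id"]]
            continue
        leads.append(best["id"])
        try:
            current = cojo_condition(stats, panel, leads)
        except np.linalg.LinAlgError:
            leads.pop()
            break
    signals = []
    for lead in leads:
        others = [l for l in leads if l != lead]
        try:
            cond_df = cojo_condition(stats, panel, others)
        except np.linalg.LinAlgError:
            logger.warning("skipping signal %s: singular conditioning set", lead)
            continue
        s = SumStats(stats.trait_id, stats.trait_role, cond_df,
                     ancestry=stats.ancestry, tissue=stats.tissue)
        signals.append(ConditionalSignal(lead=lead, conditioned_on=others, stats=s))
    return signals


@dataclass
class PwcocoConfig:
    pph4_threshold: float = 0.8
    p_threshold_1: float = 1e-5   # QTL side
    p_threshold_2: float = 5e-8   # GWAS side
    collinearity_r2: float = 0.9
    max_signals: int = 10


def pwcoco(
    stats1: SumStats,
    stats2: SumStats,
    panel: ReferencePanel,
    priors: ColocPriors | None = None,
    cfg: PwcocoConfig | None = None,
    trait_types: tuple[str, str] = ("quantitative", "case_control"),
) -> ColocResult:
    """Pairwise conditional colocalization.

    Runs marginal colocalization first; only when its PPH4 falls below the
    acceptance threshold are secondary signals isolated on each side and
    every conditioned-vs-conditioned / conditioned-vs-marginal combination
    re-colocalized. Returns the result with maximal PPH4 plus the full pair
    table.
    """
    cfg = cfg or PwcocoConfig()
    priors = priors or ColocPriors()
    marginal = abf_coloc(stats1, stats2, priors, trait_types)
    if not marginal.applicable or marginal.pph4 >= cfg.pph4_threshold:
        return marginal

    sig1 = select_signals(stats1, panel, cfg.p_threshold_1, cfg.collinearity_r2, cfg.max_signals)
    sig2 = select_signals(stats2, panel, cfg.p_threshold_2, cfg.collinearity_r2, cfg.max_signals)
    side1 = [(f"cond:{s.lead}", s.conditioned_on, s.stats) for s in sig1]
    side2 = [(f"cond:{s.lead}", s.conditioned_on, s.stats) for s in sig2]
    # conditioned-vs-marginal combinations are part of the scan
    side1.append(("marginal", [], stats1))
    side2.append(("marginal", [], stats2))

    rows = []
    best = marginal
    best_cond: tuple[list[str], list[str]] = ([], [])
    tested = 1
    for lab1, cond1, s1 in side1:
        for lab2, cond2, s2 in side2:
            if lab1 == "marginal" and lab2 == "marginal":
                continue  # already run
            res = abf_coloc(s1, s2, priors, trait_types)
            tested += 1
            if not res.applicable:
                continue
            rows.append({"side1": lab1, "side2": lab2, "pph4": res.pph4,
                         **{f"pph{h}": res.pph[h] for h in range(5)}})
            if res.pph4 > best.pph4:
                best, best_cond = res, (cond1, cond2)

    table = pd.DataFrame(rows) if rows else None
    return ColocResult(
        pph=best.pph, n_variants=marginal.n_variants,
        conditioned_on=best_cond,
        max_pph4=max(marginal.pph4, best.pph4),
        pairs_tested=tested, pair_table=table,
    )
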