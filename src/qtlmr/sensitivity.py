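"""Sensitivity cascade: MR-PRESSO, Steiger filtering, and the assembled suite.

MR-PRESSO tests for horizontal pleiotropy by comparing the observed weighted
residual sum of squares of per-instrument effects around leave-one-out IVW
fits against a parametric simulation under the no-pleiotropy model. Steiger
filtering drops instruments explaining more variance in the (liability-scale)
outcome than in the exposure, guarding against reverse causation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .estimators import HeterogeneityStats, MRResult, ivw
from .instruments import Instrument, InstrumentSet
from .sumstats import VariantKey


@dataclass
class SensitivityConfig:
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05   # Bonferroni-adjusted over instruments
    presso_distortion_alpha: float = 0.05
    wm_n_boot: int = 1000
    steiger_K: float = 0.10
    seed: int = 0
    concordance: str = "sign"  # "sign" | "ci_overlap"


@dataclass
class PressoResult:
    global_p: float
    outliers: list[VariantKey]
    outlier_p: dict[str, float]
    distortion_p: float | None
    raw: MRResult
    corrected: MRResult | None
    chosen: MRResult
    n_sim: int
    seed: int
    applicable: bool = True
    reason: str | None = None

    @classmethod
    def not_applicable(cls, reason: str) -> "PressoResult":
        na = MRResult.not_applicable("presso", reason)
        return cls(math.nan, [], {}, None, na, None, na, 0, 0, applicable=False,
                   reason=reason)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each instrument in turn (vectorized)."""
    A = np.sum(w * bx * bx)
    B = np.sum(w * bx * by)
    return (B - w * bx * by) / (A - w * bx * bx)


def mr_presso(insts: InstrumentSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05, distortion_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests (seeded, deterministic).

    The global statistic is the weighted RSS of observed outcome effects
    around leave-one-out IVW predictions; its null distribution comes from
    ``n_sim`` parametric draws under the fitted model. Per-instrument outlier
    p-values are Bonferroni-thresholded at ``outlier_alpha``; the distortion
    test compares the raw-to-corrected estimate shift against shifts induced
    by removing random subsets of the same size.
    """
    n = insts.n_iv
    if n < 4:
        return PressoResult.not_applicable("needs >= 4 instruments")
    bx, sx, by, sy = insts.arrays()
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    slopes = _loo_slopes(bx, by, w)
    resid2_obs = w * (by - slopes * bx) ** 2
    rss_obs = float(resid2_obs.sum())

    # parametric simulation under the no-pleiotropy model
    bxs = rng.normal(bx, sx, size=(n_sim, n))
    bys = rng.normal(slopes * bx, sy, size=(n_sim, n))
    ws = w[None, :]
    A = np.sum(ws * bxs * bxs, axis=1, keepdims=True)
    B = np.sum(ws * bxs * bys, axis=1, keepdims=True)
    loo = (B - ws * bxs * bys) / (A - ws * bxs * bxs)
    resid2_sim = ws * (bys - loo * bxs) ** 2
    rss_sim = resid2_sim.sum(axis=1)
    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    per_p = (1.0 + np.sum(resid2_sim >= resid2_obs[None, :], axis=0)) / (n_sim + 1.0)
    thresh = outlier_alpha / n
    out_idx = np.where(per_p < thresh)[0]
    outliers = [insts.instruments[i].variant for i in out_idx]
    outlier_p = {insts.instruments[i].variant.id: float(per_p[i]) for i in range(n)}

    raw, _ = ivw(insts)
    raw = MRResult("presso_raw", raw.estimate, raw.se, raw.p, n_iv=n)
    corrected = None
    distortion_p = None
    chosen = raw
    if len(out_idx) and len(out_idx) < n - 1:
        keep = [insts.instruments[i] for i in range(n) if i not in set(out_idx)]
        sub = InstrumentSet(insts.trait_id, insts.ancestry, insts.tissue, keep)
        c, _ = ivw(sub)
        corrected = MRResult("presso_corrected", c.estimate, c.se, c.p, n_iv=len(keep))
        d_obs = corrected.estimate - raw.estimate
        n_out = len(out_idx)
        shifts = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(n, size=n_out, replace=False)
            mask = np.ones(n, bool)
            mask[drop] = False
            denom = np.sum(w[mask] * bx[mask] ** 2)
            est_b = np.sum(w[mask] * bx[mask] * by[mask]) / denom
            shifts[b] = est_b - raw.estimate
        distortion_p = float((1.0 + np.sum(np.abs(shifts) >= abs(d_obs))) / (n_sim + 1.0))
        if distortion_p < distortion_alpha:
            chosen = corrected
    return PressoResult(float(global_p), outliers, outlier_p, distortion_p,
                        raw, corrected, chosen, n_sim, seed)


# ---------------------------------------------------------------------------
# Steiger directionality filtering


@dataclass
class SteigerResult:
    kept: InstrumentSet
    removed: list[VariantKey]
    r2_exposure: dict[str, float]
    r2_outcome_liability: dict[str, float]
    K: float
    steiger_ivw: MRResult = None  # set by caller or steiger_filter


def r2_exposure_variant(inst: Instrument, eaf: float | None, n: int | None) -> float:
    """Variance of a standardized exposure explained by one instrument.

    2·maf·(1−maf)·beta_x² when the exposure EAF is available; otherwise the
    F-statistic fallback F/(F + n − 2).
    """
    if eaf is not None and not math.isnan(eaf):
        maf = min(eaf, 1 - eaf)
        return 2 * maf * (1 - maf) * inst.pair.beta_x**2
    if n is None:
        raise ValueError("need eaf or exposure sample size for Steiger r2")
    f = inst.f_stat
    return f / (f + n - 2)


def r2_outcome_liability_variant(beta_logor: float, eaf: float, K: float) -> float:
    """Liability-scale variance explained by one variant's log-OR.

    Composes the logistic-to-linear observed-scale conversion with the
    ascertained observed-to-liability transformation at prevalence ``K``;
    the case fraction cancels, leaving r² = beta² · 2f(1−f) · (K(1−K)/phi(t))².
    """
    t = _st.norm.ppf(1 - K)
    c = K * (1 - K) / _st.norm.pdf(t)
    var_g = 2 * eaf * (1 - eaf)
    return beta_logor**2 * var_g * c**2


def steiger_filter(
    insts: InstrumentSet,
    K: float = 0.10,
    exposure_n: int | None = None,
) -> SteigerResult:
    """Drop instruments explaining more outcome (liability) than exposure variance.

    Outcome records must carry case/control counts for the liability
    conversion to be meaningful; the exposure EAF enters the exposure-side r².
    The returned ``steiger_ivw`` is IVW on the kept set (not-applicable if
    everything is removed).
    """
    kept_i: list[Instrument] = []
    removed: list[VariantKey] = []
    r2x: dict[str, float] = {}
    r2y: dict[str, float] = {}
    for inst in insts.instruments:
        p = inst.pair
        eaf = p.eaf_x if p.eaf_x is not None else p.eaf_y
        if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)):
            eaf = None
        rx = r2_exposure_variant(inst, eaf, exposure_n)
        eaf_o = p.eaf_y if p.eaf_y is not None and not math.isnan(p.eaf_y) else (eaf or 0.5)
        ry = r2_outcome_liability_variant(p.beta_y, eaf_o, K)
        r2x[p.variant.id] = rx
        r2y[p.variant.id] = ry
        if rx > ry:
            kept_i.append(inst)
        else:
            removed.append(p.variant)
    kept = InstrumentSet(insts.trait_id, insts.ancestry, insts.tissue, kept_i)
    if kept.n_iv:
        s, _ = ivw(kept)
        s = MRResult("steiger_ivw", s.estimate, s.se, s.p, n_iv=kept.n_iv)
    else:
        s = MRResult.not_applicable("steiger_ivw", "all instruments removed")
    return SteigerResult(kept, removed, r2x, r2y, K, steiger_ivw=s)


# ---------------------------------------------------------------------------
# suite assembly


@dataclass
class SensitivitySuite:
    ivw: MRResult
    het: HeterogeneityStats
    wm: MRResult
    egger: MRResult
    presso: PressoResult
    presso_chosen: MRResult
    steiger: SteigerResult
    steiger_ivw: MRResult

    @property
    def egger_intercept_p(self) -> float | None:
        if not self.egger.applicable:
            return None
        return self.egger.extra["intercept_p"]

    @property
    def concordant(self) -> bool | None:
        """True iff every applicable sensitivity estimate matches IVW's sign.

        None (not applicable) when no sensitivity method could run, e.g. a
        single-instrument trait.
        """
        comps = [r for r in (self.wm, self.egger, self.presso_chosen, self.steiger_ivw)
                 if r is not None and r.applicable]
        if not comps:
            return None
        ref = math.copysign(1.0, self.ivw.estimate)
        return all(math.copysign(1.0, r.estimate) == ref for r in comps)


def run_sensitivity_suite(insts: InstrumentSet, cfg: SensitivityConfig | None = None,
                          exposure_n: int | None = None) -> SensitivitySuite:
    """All applicable sensitivity analyses for one instrument set.

    Single-IV sets yield a suite where everything except IVW (= Wald ratio)
    is not-applicable; each method's own minimum instrument count is
    respected.
    """
    from .estimators import mr_egger, weighted_median  # local to avoid cycle at import

    if insts.n_iv == 0:
        raise ValueError("run_sensitivity_suite: empty instrument set")
    cfg = cfg or SensitivityConfig()
    main, het = ivw(insts)
    wm = weighted_median(insts, n_boot=cfg.wm_n_boot, seed=cfg.seed)
    egger = mr_egger(insts)
    presso = mr_presso(insts, n_sim=cfg.presso_n_sim, seed=cfg.seed,
                       outlier_alpha=cfg.presso_outlier_alpha,
                       distortion_alpha=cfg.presso_distortion_alpha)
    if insts.n_iv >= 2:
        steiger = steiger_filter(insts, K=cfg.steiger_K, exposure_n=exposure_n)
        s_ivw = steiger.steiger_ivw
    else:
        steiger = SteigerResult(insts, [], {}, {}, cfg.steiger_K,
                                steiger_ivw=MRResult.not_applicable("steiger_ivw", "single IV"))
        s_ivw = steiger.steiger_ivw
    chosen = presso.chosen if presso.applicable else MRResult.not_applicable("presso", "n_iv < 4")
    return SensitivitySuite(ivw=main, het=het, wm=wm, egger=egger, presso=presso,
                            presso_chosen=chosen, steiger=steiger, steiger_ivw=s_ivw)
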