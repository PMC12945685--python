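"""Two-sample MR point estimators and heterogeneity statistics.

Estimates are on the log-OR-per-SD-exposure scale. The headline estimator is
fixed-effect IVW (weighted regression through the origin, weights 1/se_y²);
with a single instrument it reduces exactly to the Wald ratio. MR-Egger,
the weighted median and Cochran's Q/I² support the sensitivity cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .instruments import Instrument, InstrumentSet


@dataclass
class MRResult:
    method: str
    estimate: float = math.nan
    se: float = math.nan
    p: float = math.nan
    n_iv: int = 0
    extra: dict = field(default_factory=dict)
    applicable: bool = True
    reason: str | None = None

    @classmethod
    def not_applicable(cls, method: str, reason: str) -> "MRResult":
        return cls(method=method, applicable=False, reason=reason)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = _st.norm.ppf(0.5 + level / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    p: float
    applicable: bool = True

    @property
    def I2(self) -> float:
        """Percent of variance attributed to heterogeneity: (Q-df)/Q, floored at 0."""
        if self.Q <= 0:
            return 0.0
        return max(0.0, (self.Q - self.df) / self.Q) * 100.0

    @classmethod
    def not_applicable(cls) -> "HeterogeneityStats":
        return cls(Q=math.nan, df=0, p=math.nan, applicable=False)


def _arrays(insts: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return insts.arrays()


def wald_ratio(inst: Instrument) -> MRResult:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    p = inst.pair
    if p.beta_x == 0:
        raise ValueError("wald_ratio: exposure effect is zero; cannot instrument")
    est = p.beta_y / p.beta_x
    se = p.se_y / abs(p.beta_x)
    z = est / se
    pval = 2 * _st.norm.sf(abs(z))
    return MRResult("wald", est, se, pval, n_iv=1)


def ivw(insts: InstrumentSet) -> tuple[MRResult, HeterogeneityStats]:
    """Fixed-effect inverse-variance-weighted estimate and Cochran's Q.

    Weighted regression of beta_y on beta_x through the origin with weights
    1/se_y²; a single instrument delegates to the Wald ratio (Q undefined).
    """
    n = insts.n_iv
    if n == 0:
        return MRResult.not_applicable("ivw", "no instruments"), HeterogeneityStats.not_applicable()
    if n == 1:
        r = wald_ratio(insts.instruments[0])
        return MRResult("ivw", r.estimate, r.se, r.p, n_iv=1), HeterogeneityStats.not_applicable()
    bx, _, by, sy = _arrays(insts)
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    est = float(np.sum(bx * by * w)) / denom
    se = 1.0 / math.sqrt(denom)
    p = 2 * _st.norm.sf(abs(est / se))
    het = cochran_arrays(bx, by, sy, est)
    return MRResult("ivw", est, se, p, n_iv=n), het


def cochran_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, estimate: float) -> HeterogeneityStats:
    ratios = by / bx
    w = (bx / sy) ** 2
    Q = float(np.sum(w * (ratios - estimate) ** 2))
    df = len(bx) - 1
    p = float(_st.chi2.sf(Q, df)) if df > 0 else math.nan
    return HeterogeneityStats(Q=Q, df=df, p=p)


def cochran(insts: InstrumentSet, estimate: float) -> HeterogeneityStats:
    """Cochran's Q of per-IV Wald ratios around ``estimate`` (w = (beta_x/se_y)²)."""
    if insts.n_iv < 2:
        return HeterogeneityStats.not_applicable()
    bx, _, by, sy = _arrays(insts)
    return cochran_arrays(bx, by, sy, estimate)


def mr_egger(insts: InstrumentSet) -> MRResult:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    Instruments are oriented so every beta_x is positive (beta_y flipped
    jointly). Standard errors use multiplicative overdispersion with the
    residual scale floored at 1; p-values use a t reference with n_iv - 2
    degrees of freedom. The intercept estimates directional pleiotropy.
    """
    n = insts.n_iv
    if n < 3:
        return MRResult.not_applicable("egger", "needs >= 3 instruments")
    bx, _, by, sy = _arrays(insts)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2
    sw = w.sum()
    xb = np.sum(w * x) / sw
    yb = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xb) ** 2)
    if sxx <= 0:
        return MRResult.not_applicable("egger", "exposure effects collinear")
    slope = float(np.sum(w * (x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)
    resid = y - intercept - slope * x
    scale = max(1.0, float(np.sum(w * resid**2) / (n - 2)))
    se_slope = math.sqrt(scale / sxx)
    se_int = math.sqrt(scale * (1.0 / sw + xb**2 / sxx))
    p_slope = 2 * _st.t.sf(abs(slope / se_slope), n - 2)
    p_int = 2 * _st.t.sf(abs(intercept / se_int), n - 2)
    return MRResult(
        "egger", slope, se_slope, p_slope, n_iv=n,
        extra={"intercept": intercept, "intercept_se": se_int, "intercept_p": p_int,
               "scale": scale},
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(insts: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of per-IV Wald ratios (inverse-variance weights).

    Consistent when less than half of the weight comes from invalid
    instruments. SE by seeded parametric bootstrap of (beta_x, beta_y).
    """
    n = insts.n_iv
    if n < 3:
        return MRResult.not_applicable("weighted_median", "needs >= 3 instruments")
    bx, sx, by, sy = _arrays(insts)
    ratios = by / bx
    var_ratio = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    w = 1.0 / var_ratio
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, n))
    bys = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rb = bys[b] / bxs[b]
        vb = sy**2 / bxs[b] ** 2 + bys[b] ** 2 * sx**2 / bxs[b] ** 4
        boots[b] = _weighted_median(rb, 1.0 / vb)
    se = float(boots.std(ddof=1))
    p = 2 * _st.norm.sf(abs(est / se)) if se > 0 else (1.0 if est == 0 else 0.0)
    return MRResult("weighted_median", est, se, p, n_iv=n)
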