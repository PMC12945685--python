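"""Binary-outcome MR statistical power and minimal detectable effect (MDE).

Power is derived from the non-centrality parameter NCP = b_MR²/var(b_MR) of a
1-df chi-square test, with

    b_MR       = K * (OR / (1 + K*(OR - 1)) - 1)
    var(b_MR)  = (K*(1-K) - b_MR²) / (N * R²)        ["corrected" form]
    R²         = Σ 2*MAF_i*(1-MAF_i)*b_{E,i}²

where K is the outcome prevalence (case proportion), N the outcome sample
size and R² the exposure variance explained by the instruments. The widely
circulated product form var(b_MR) = K(1-K)·b_MR²/(N·R²) makes the NCP
independent of OR — under it no minimal detectable effect exists — so the
difference form is the default; the product form stays available via
``form="printed"`` for comparison. Likewise R² uses squared per-instrument
effects (the unsquared sum could go negative). The MDE is the OR at which
power first reaches the target (80% by default), searched on both the risk
(OR > 1) and protective (OR < 1) sides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st


@dataclass
class PowerParams:
    K: float
    N: int
    R2: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.K < 1:
            raise ValueError("K must lie in (0, 1)")
        if not 0 <= self.R2 < 1:
            raise ValueError("R2 must lie in [0, 1)")


@dataclass
class PowerResult:
    or_grid: np.ndarray
    power: np.ndarray
    mde: float | None
    mde_protective: float | None
    ncp_at_mde: float
    b_mr_at_mde: float
    params: PowerParams = field(repr=False, default=None)


def iv_r2(mafs, betas, form: str = "corrected") -> float:
    """Exposure variance explained by the instruments.

    R² = Σ 2·MAF_i·(1−MAF_i)·b_{E,i}² with betas on the standardized-exposure
    scale; ``form="printed"`` reproduces the unsquared sum for comparison.
    Values at or above 1 are capped just below 1 with a warning.
    """
    mafs = np.asarray(mafs, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if mafs.shape != betas.shape:
        raise ValueError("mafs and betas must have equal length")
    if mafs.size == 0:
        return 0.0
    term = betas**2 if form == "corrected" else betas
    r2 = float(np.sum(2 * mafs * (1 - mafs) * term))
    if r2 >= 1:
        warnings.warn("instrument R2 >= 1; capping below 1", stacklevel=2)
        r2 = 1 - 1e-12
    return r2


def b_mr(K: float, OR: float) -> float:
    """Attenuated observed-scale slope implied by a true odds ratio."""
    if not OR > 0:
        raise ValueError("OR must be positive")
    return K * (OR / (1 + K * (OR - 1)) - 1)


def var_b_mr(params: PowerParams, OR: float, form: str = "corrected") -> float:
    b = b_mr(params.K, OR)
    if form == "corrected":
        num = params.K * (1 - params.K) - b * b
    elif form == "printed":
        num = params.K * (1 - params.K) * b * b
    else:
        raise ValueError(f"unknown variance form {form!r}")
    return num / (params.N * params.R2)


def power_binary(params: PowerParams, OR, form: str = "corrected"):
    """Power of the 1-df chi-square MR test at the given odds ratio(s)."""
    if params.R2 == 0:
        warnings.warn("R2 = 0: no instrument information, power equals alpha",
                      stacklevel=2)
        return params.alpha if np.isscalar(OR) else np.full(np.shape(OR), params.alpha)
    ors = np.atleast_1d(np.asarray(OR, dtype=float))
    b = params.K * (ors / (1 + params.K * (ors - 1)) - 1)
    if form == "corrected":
        var = (params.K * (1 - params.K) - b * b) / (params.N * params.R2)
    else:
        var = (params.K * (1 - params.K) * b * b) / (params.N * params.R2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncp = np.where(var > 0, b * b / var, np.inf)
    crit = _st.chi2.ppf(1 - params.alpha, 1)
    pw = np.where(ncp == 0, params.alpha, _st.ncx2.sf(crit, 1, np.maximum(ncp, 1e-300)))
    pw = np.where(np.isinf(ncp), 1.0, pw)
    return float(pw[0]) if np.isscalar(OR) else pw


def _bisect_mde(params: PowerParams, lo: float, hi: float, tol: float = 1e-6) -> float:
    target = params.target_power
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            break
        if power_binary(params, mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def mde(params: PowerParams, or_max: float = 100.0, n_grid: int = 200) -> PowerResult:
    """Minimal detectable odds ratio at the target power (both directions).

    Bisection on OR > 1 to an OR tolerance of 1e-6, plus the symmetric
    search on the protective side OR < 1; the evaluated grid and power curve
    are recorded. Either side is None when the target power is unreachable
    within (1, ``or_max``] (respectively [1/``or_max``, 1)).
    """
    if params.R2 <= 0:
        raise ValueError("MDE requires R2 > 0")
    grid = np.concatenate([
        np.geomspace(1 / or_max, 1.0, n_grid // 2, endpoint=False),
        np.geomspace(1.0, or_max, n_grid // 2),
    ])
    curve = power_binary(params, grid)

    risk = None
    if power_binary(params, or_max) >= params.target_power:
        risk = _bisect_mde(params, 1.0 + 1e-12, or_max)
    protective = None
    if power_binary(params, 1.0 / or_max) >= params.target_power:
        # power is monotone in |log OR|; bisect on the inverse scale
        lo, hi = 1.0 / or_max, 1.0 - 1e-12
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if hi - lo < 1e-6:
                break
            if power_binary(params, mid) >= params.target_power:
                lo = mid
            else:
                hi = mid
        protective = lo

    ref = risk if risk is not None else (protective if protective is not None else math.nan)
    if isinstance(ref, float) and not math.isnan(ref):
        b = b_mr(params.K, ref)
        ncp = b * b / var_b_mr(params, ref)
    else:
        b, ncp = math.nan, math.nan
    return PowerResult(or_grid=grid, power=curve, mde=risk, mde_protective=protective,
                       ncp_at_mde=float(ncp), b_mr_at_mde=float(b), params=params)
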