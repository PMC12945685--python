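"""Synthetic multi-ancestry reference panels and QTL/GWAS summary statistics.

The generator produces individual-level data so that marginal statistics, LD
and case-control ascertainment are mutually consistent:

* genotypes are drawn per variant under Hardy-Weinberg from a latent Gaussian
  copula inducing AR(1) linkage disequilibrium along the locus;
* expression is a linear genetic score plus Gaussian noise, scaled to a target
  cis-heritability with unit total variance;
* the binary outcome follows a liability-threshold model at prevalence K, with
  the causal effect of expression specified on the marginal log-odds-ratio
  scale (what MR estimates) and converted internally to the liability scale;
* case-control samples are ascertained by rejection sampling and analysed by
  per-variant logistic regression.

A fast multivariate-normal z-score generator (``simulate_locus_zscores``) is
also provided for colocalization-scale experiments where individual-level
simulation is unnecessarily expensive. All randomness flows from explicit
integer seeds; there is no global random state.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy import stats as _st

from .sumstats import COLUMNS, SumStats, TraitRole, VariantKey

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass
class PanelConfig:
    """Parameters of one simulated LD reference panel."""

    ancestry: str = "EUR"
    m_variants: int = 50
    n_ref: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 2_000

    def __post_init__(self) -> None:
        if self.m_variants < 2:
            raise ValueError("m_variants must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")


class ReferencePanel:
    """Variant-indexed LD information for one ancestry.

    ``ld`` is the dosage correlation matrix (dense, or sparse block-diagonal
    for study-scale panels); ``eaf`` is the effect-allele (alt) frequency and
    ``maf`` its folded minor-allele counterpart.
    """

    def __init__(
        self,
        ancestry: str,
        variants: Sequence[VariantKey],
        eaf: np.ndarray,
        ld,
        dosages: np.ndarray | None = None,
        config: PanelConfig | None = None,
        latent_rho: np.ndarray | None = None,
    ) -> None:
        self.ancestry = ancestry
        self.variants = list(variants)
        self.eaf = np.asarray(eaf, dtype=float)
        self.ld = ld
        self.dosages = dosages
        self.config = config
        # adjacent-pair latent correlations used to redraw cohorts
        self.latent_rho = latent_rho
        self._index = {v.id: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variant ids in panel")
        if np.any(self.eaf <= 0) or np.any(self.eaf >= 1):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if not sparse.issparse(ld):
            d = np.diagonal(ld)
            if not np.allclose(d, 1.0, atol=1e-8):
                raise ValueError("LD diagonal must be 1")
            w = np.linalg.eigvalsh(np.asarray(ld))
            if w.min() < -1e-8:
                raise ValueError("LD matrix not positive semi-definite")

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.eaf, 1 - self.eaf)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def ld_dense(self, ids: Sequence[str] | None = None) -> np.ndarray:
        idx = None if ids is None else [self._index[i] for i in ids]
        if sparse.issparse(self.ld):
            mat = self.ld.tocsr()
            if idx is not None:
                mat = mat[idx][:, idx]
            return np.asarray(mat.todense())
        mat = np.asarray(self.ld)
        return mat if idx is None else mat[np.ix_(idx, idx)]

    def r(self, id1: str, id2: str) -> float:
        i, j = self._index[id1], self._index[id2]
        if sparse.issparse(self.ld):
            return float(self.ld.tocsr()[i, j])
        return float(self.ld[i, j])

    def r2(self, id1: str, id2: str) -> float:
        return self.r(id1, id2) ** 2

    def subpanel(self, ids: Sequence[str]) -> "ReferencePanel":
        idx = [self._index[i] for i in ids]
        lat = None
        if self.latent_rho is not None and idx == list(range(idx[0], idx[-1] + 1)):
            lat = self.latent_rho[idx[0]: idx[-1]] if len(idx) > 1 else np.empty(0)
        return ReferencePanel(
            self.ancestry,
            [self.variants[i] for i in idx],
            self.eaf[idx],
            self.ld_dense(ids),
            dosages=None if self.dosages is None else self.dosages[:, idx],
            config=self.config,
            latent_rho=lat,
        )

    def draw_dosages(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw a fresh cohort of ``n`` individuals from the panel's process."""
        if self.latent_rho is not None:
            return _draw_dosages_ar1(rng, n, self.eaf, self.latent_rho)
        # fall back to a Gaussian copula with the observed LD as latent corr
        r_lat = self.ld_dense()
        L = np.linalg.cholesky(r_lat + 1e-8 * np.eye(self.m))
        thr = _st.norm.ppf(self.eaf)
        hap = lambda: (rng.standard_normal((n, self.m)) @ L.T) < thr
        return (hap().astype(np.int8) + hap().astype(np.int8)).astype(float)


@dataclass
class TruthTable:
    """Known causal architecture of one gene used to grade the pipeline.

    ``theta`` is the causal effect of one SD of expression on the outcome on
    the marginal log-OR scale; ``delta`` holds per-variant direct (pleiotropic)
    liability effects bypassing expression.
    """

    gamma: np.ndarray
    theta: float
    delta: np.ndarray
    h2_expr: float
    K: float
    n_exp: int
    n_case: int
    n_ctrl: int

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if not 0 <= self.h2_expr < 1:
            raise ValueError("h2_expr must lie in [0, 1)")
        if not 0 < self.K < 1:
            raise ValueError("K must lie in (0, 1)")
        if self.h2_expr > 0 and not np.any(self.gamma != 0):
            raise ValueError("h2_expr > 0 requires at least one nonzero gamma")


@dataclass
class GeneAnnot:
    """Gene annotation record: coordinates and TSS for cis-window lookup."""

    gene_id: str
    chrom: str
    tss: int
    start: int
    end: int
    strand: str = "+"


@dataclass
class StudyBundle:
    """Complete synthetic study: panels, summary statistics and ground truth."""

    panels: dict[str, ReferencePanel]
    exposures: dict[tuple[str, str, str], SumStats]  # (gene, ancestry, tissue)
    outcomes: dict[str, SumStats]
    truth: dict[str, TruthTable]
    genes: dict[str, GeneAnnot]
    gene_panels: dict[tuple[str, str], ReferencePanel] = field(default_factory=dict)

    def exposure(self, gene: str, ancestry: str, tissue: str) -> SumStats:
        return self.exposures[(gene, ancestry, tissue)]


# ---------------------------------------------------------------------------
# genotype machinery


@functools.lru_cache(maxsize=4096)
def _latent_rho_for(maf_i: float, maf_j: float, target_r: float) -> float:
    """Latent Gaussian correlation yielding a target haplotype correlation.

    Thresholding a bivariate normal attenuates correlation; invert the
    relationship numerically (frequencies are rounded by the caller so the
    cache is effective).
    """
    if target_r <= 0:
        return 0.0
    ti, tj = _st.norm.ppf(maf_i), _st.norm.ppf(maf_j)
    denom = math.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))

    def binary_corr(rho: float) -> float:
        p11 = _st.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([ti, tj])
        return (p11 - maf_i * maf_j) / denom

    if binary_corr(0.9999) <= target_r:
        return 0.9999
    return optimize.brentq(lambda r: binary_corr(r) - target_r, 0.0, 0.9999, xtol=1e-4)


def _draw_dosages_ar1(
    rng: np.random.Generator, n: int, eaf: np.ndarray, latent_rho: np.ndarray
) -> np.ndarray:
    """Two haplotypes per individual from an AR(1) latent Gaussian chain."""
    m = len(eaf)
    thr = _st.norm.ppf(eaf)
    dos = np.zeros((n, m))
    for _ in range(2):
        if np.all(latent_rho == 0):
            z = rng.standard_normal((n, m))
        else:
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            noise = rng.standard_normal((n, m - 1))
            for j in range(1, m):
                r = latent_rho[j - 1]
                z[:, j] = r * z[:, j - 1] + math.sqrt(1 - r * r) * noise[:, j - 1]
        dos += z < thr
    return dos


def simulate_reference_panel(cfg: PanelConfig) -> ReferencePanel:
    """Simulate a reference panel of ``n_ref`` individuals with AR(1) LD.

    Deterministic given ``cfg.seed``. Monomorphic draws (possible at extreme
    MAF with a small panel) are re-drawn so empirical frequencies stay inside
    (0, 1) and the LD matrix is well defined.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_variants
    target = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    rounded = np.round(target, 2).clip(0.01, 0.5)
    latent = np.array(
        [_latent_rho_for(rounded[j], rounded[j + 1], cfg.ld_rho) for j in range(m - 1)]
    )
    dosages = _draw_dosages_ar1(rng, cfg.n_ref, target, latent)
    for _ in range(100):  # re-draw monomorphic columns
        freq = dosages.mean(axis=0) / 2
        bad = (freq <= 0) | (freq >= 1)
        if not bad.any():
            break
        redo = _draw_dosages_ar1(rng, cfg.n_ref, target, latent)
        dosages[:, bad] = redo[:, bad]
    freq = dosages.mean(axis=0) / 2
    ld = _safe_corrcoef(dosages)

    variants = []
    for j in range(m):
        ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        pos = cfg.pos_start + j * cfg.pos_step
        variants.append(VariantKey(f"{cfg.ancestry}_rs{pos}", cfg.chrom, pos, ea, oa))
    return ReferencePanel(
        cfg.ancestry, variants, freq, ld, dosages=dosages, config=cfg, latent_rho=latent
    )


def _safe_corrcoef(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    xc = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    r = (xc.T @ xc) / len(x)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# marginal association engines


def linear_marginals(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple linear regression of ``y`` on each dosage column."""
    n, m = G.shape
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    sxx = np.where(sxx > 0, sxx, np.nan)
    beta = sxy / sxx
    sse = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(sse / (n - 2) / sxx)
    se = np.where(se > 0, se, np.nan)
    t = beta / se
    p = np.maximum(2 * _st.t.sf(np.abs(t), n - 2), np.finfo(float).tiny)
    return beta, se, p


def logistic_marginals(
    G: np.ndarray, y: np.ndarray, n_iter: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic regression (intercept + dosage), Newton-Raphson.

    All variants are fitted simultaneously; each fit is a 2-parameter model
    solved in closed form per iteration.
    """
    n, m = G.shape
    ybar = y.mean()
    a = np.full(m, math.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    yv = y[:, None]
    for _ in range(n_iter):
        eta = a[None, :] + G * b[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        r = yv - mu
        ga = r.sum(axis=0)
        gb = (G * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * G).sum(axis=0)
        h11 = (w * G * G).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(det > 1e-12, det, np.nan)
        da = (h11 * ga - h01 * gb) / det
        db = (h00 * gb - h01 * ga) / det
        a += np.nan_to_num(da)
        b += np.nan_to_num(db)
        if max(np.nanmax(np.abs(da), initial=0), np.nanmax(np.abs(db), initial=0)) < 1e-10:
            break
    eta = a[None, :] + G * b[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * G).sum(axis=0)
    h11 = (w * G * G).sum(axis=0)
    det = h00 * h11 - h01 * h01
    se = np.sqrt(np.where(det > 0, h00 / det, np.nan))
    z = b / se
    p = np.maximum(2 * _st.norm.sf(np.abs(z)), np.finfo(float).tiny)
    return b, se, p


def _panel_frame(panel: ReferencePanel, beta, se, p, eaf, n, n_case=None, n_ctrl=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "id": [v.id for v in panel.variants],
        "chrom": [v.chrom for v in panel.variants],
        "pos": panel.positions,
        "effect_allele": [v.effect_allele for v in panel.variants],
        "other_allele": [v.other_allele for v in panel.variants],
        "beta": beta, "se": se, "eaf": eaf, "p": p,
        "n": float(n),
        "n_case": np.nan if n_case is None else float(n_case),
        "n_ctrl": np.nan if n_ctrl is None else float(n_ctrl),
    })
    return df[COLUMNS]


# ---------------------------------------------------------------------------
# exposure / outcome simulation


def simulate_expression_sumstats(
    panel: ReferencePanel,
    gamma: np.ndarray,
    h2_expr: float,
    n_exp: int,
    seed: int,
    trait_id: str = "gene",
    ancestry: str | None = None,
    tissue: str | None = None,
) -> SumStats:
    """cis-eQTL-style marginal summary statistics for one gene.

    Expression ``y = s * G @ gamma + e`` where ``s`` scales the genetic score
    so its variance equals ``h2_expr`` and total variance is 1.
    """
    gamma = np.asarray(gamma, dtype=float)
    if len(gamma) != panel.m:
        raise ValueError("gamma length must match panel variants")
    if h2_expr > 0 and not np.any(gamma != 0):
        raise ValueError("h2_expr > 0 but gamma is identically zero")
    rng = np.random.default_rng(seed)
    G = panel.draw_dosages(n_exp, rng)
    score = G @ gamma
    if h2_expr > 0:
        s = math.sqrt(h2_expr / max(score.var(), 1e-12))
    else:
        s = 0.0
    y = s * score + rng.standard_normal(n_exp) * math.sqrt(1 - h2_expr)
    beta, se, p = linear_marginals(G, y)
    df = _panel_frame(panel, beta, se, p, G.mean(axis=0) / 2, n_exp)
    df = df.dropna(subset=["beta", "se"]).reset_index(drop=True)
    return SumStats(trait_id, TraitRole.EXPOSURE, df,
                    ancestry=ancestry or panel.ancestry, tissue=tissue)


def liability_scale_factor(K: float) -> float:
    """Multiplier converting a marginal log-OR into a liability-scale slope.

    For small effects under the liability-threshold model at prevalence K,
    a liability slope b induces a marginal log-OR of b * phi(t) / (K(1-K))
    with t the (1-K) standard-normal quantile; this returns the inverse
    factor K(1-K)/phi(t).
    """
    t = _st.norm.ppf(1 - K)
    return K * (1 - K) / _st.norm.pdf(t)


def simulate_outcome_sumstats(
    panel: ReferencePanel,
    truth: TruthTable,
    seed: int,
    trait_id: str = "outcome",
    max_chunks: int = 2000,
) -> SumStats:
    """Case-control GWAS marginal statistics under the liability model.

    Liability is ``theta_liab * expr + G @ delta + eps`` with unit total
    variance; an individual is a case when liability exceeds the (1-K)
    standard-normal quantile. ``n_case`` cases and ``n_ctrl`` controls are
    ascertained by rejection sampling, then each variant is analysed by
    logistic regression.
    """
    rng = np.random.default_rng(seed)
    K = truth.K
    theta_liab = truth.theta * liability_scale_factor(K)
    t_thresh = _st.norm.ppf(1 - K)
    m = panel.m

    need_case, need_ctrl = truth.n_case, truth.n_ctrl
    cases_G, ctrls_G = [], []
    got_case = got_ctrl = 0
    scale_s = eps_sd = mean_l = None
    for _ in range(max_chunks):
        if got_case >= need_case and got_ctrl >= need_ctrl:
            break
        # size the draw for the binding quota, with slack for sampling noise
        want = max((need_case - got_case) / K, (need_ctrl - got_ctrl) / (1 - K))
        chunk = int(min(400_000, 1.1 * want + 2000))
        G = panel.draw_dosages(chunk, rng)
        score = G @ truth.gamma
        if scale_s is None:
            sv = score.var()
            scale_s = math.sqrt(truth.h2_expr / sv) if (truth.h2_expr > 0 and sv > 0) else 0.0
        expr = scale_s * score + rng.standard_normal(chunk) * math.sqrt(1 - truth.h2_expr)
        direct = G @ truth.delta
        if eps_sd is None:
            var_direct = direct.var()
            eps_var = max(1.0 - theta_liab ** 2 - var_direct, 0.05)
            eps_sd = math.sqrt(eps_var)
        liab = theta_liab * expr + direct + rng.standard_normal(chunk) * eps_sd
        if mean_l is None:
            mean_l = liab.mean()
        case = (liab - mean_l) > t_thresh
        if got_case < need_case:
            take = G[case][: need_case - got_case]
            cases_G.append(take)
            got_case += len(take)
        if got_ctrl < need_ctrl:
            take = G[~case][: need_ctrl - got_ctrl]
            ctrls_G.append(take)
            got_ctrl += len(take)
    else:
        raise RuntimeError(
            "rejection sampling exceeded the iteration cap; "
            "check that K is compatible with the requested case count"
        )

    Gcc = np.vstack(cases_G + ctrls_G)
    y = np.concatenate([np.ones(need_case), np.zeros(need_ctrl)])
    beta, se, p = logistic_marginals(Gcc, y)
    df = _panel_frame(panel, beta, se, p, Gcc.mean(axis=0) / 2,
                      need_case + need_ctrl, need_case, need_ctrl)
    df = df.dropna(subset=["beta", "se"]).reset_index(drop=True)
    return SumStats(trait_id, TraitRole.OUTCOME, df, ancestry=panel.ancestry)


def simulate_locus_zscores(
    panel: ReferencePanel,
    noncentrality: np.ndarray,
    n: int,
    seed: int,
    trait_id: str = "trait",
    trait_role: TraitRole | str = TraitRole.EXPOSURE,
    n_case: int | None = None,
    n_ctrl: int | None = None,
) -> SumStats:
    """Fast locus-level generator: ``z ~ MVN(R @ lam, R)``.

    ``noncentrality`` holds the joint z-scale effects ``lam`` of the causal
    variants (zero elsewhere); marginal betas are reported as ``z/sqrt(n)``
    with standard error ``1/sqrt(n)``. Suitable for colocalization-scale
    experiments where LD-consistent z-scores are all that matters.
    """
    lam = np.asarray(noncentrality, dtype=float)
    if len(lam) != panel.m:
        raise ValueError("noncentrality length must match panel variants")
    rng = np.random.default_rng(seed)
    R = panel.ld_dense()
    L = np.linalg.cholesky(R + 1e-6 * np.eye(panel.m))
    z = R @ lam + L @ rng.standard_normal(panel.m)
    se = np.full(panel.m, 1.0 / math.sqrt(n))
    beta = z * se
    p = np.maximum(2 * _st.norm.sf(np.abs(z)), np.finfo(float).tiny)
    df = _panel_frame(panel, beta, se, p, panel.eaf, n, n_case, n_ctrl)
    return SumStats(trait_id, trait_role, df, ancestry=panel.ancestry)


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class AncestryConfig:
    name: str
    n_ref: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    n_exp: int = 5000
    n_case: int = 2000
    n_ctrl: int = 2000


@dataclass
class GeneConfig:
    gene_id: str
    theta: float = 0.0
    n_causal: int = 3
    h2_expr: float = 0.15
    m_variants: int = 50
    n_pleio: int = 0
    pleio_sd: float = 0.0
    ancestries: tuple[str, ...] | None = None  # None = all


@dataclass
class StudyConfig:
    """Design of a synthetic multi-ancestry, multi-tissue MR study."""

    ancestries: list[AncestryConfig]
    genes: list[GeneConfig]
    tissues: list[str] = field(default_factory=lambda: ["blood"])
    gamma_sharing: str = "shared"  # shared | independent | sign_flipped
    causal_tissue: str | None = None  # defaults to the first tissue
    K: float = 0.10
    locus_spacing_bp: int = 5_000_000
    pos_step: int = 2_000

    def __post_init__(self) -> None:
        if self.gamma_sharing not in ("shared", "independent", "sign_flipped"):
            raise ValueError(f"study config: unknown gamma_sharing {self.gamma_sharing!r}")
        if not self.ancestries:
            raise ValueError("study config: ancestries list is empty")
        if not self.genes:
            raise ValueError("study config: genes list is empty")
        if self.causal_tissue is None:
            self.causal_tissue = self.tissues[0]
        if self.causal_tissue not in self.tissues:
            raise ValueError("study config: causal_tissue not among tissues")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        anc = [AncestryConfig(**a) for a in d["ancestries"]]
        genes = [GeneConfig(**g) for g in d["genes"]]
        extra = {k: v for k, v in d.items() if k not in ("ancestries", "genes")}
        return cls(ancestries=anc, genes=genes, **extra)


def _gene_gamma(rng: np.random.Generator, m: int, n_causal: int) -> np.ndarray:
    gamma = np.zeros(m)
    idx = np.linspace(0, m - 1, num=min(n_causal, m), dtype=int)
    vals = rng.normal(0.0, 1.0, size=len(idx))
    vals[np.abs(vals) < 0.3] = 0.3 * np.sign(vals[np.abs(vals) < 0.3] + 1e-12)
    gamma[idx] = vals
    return gamma


def simulate_study(
    config: StudyConfig | Mapping, seed: int, architecture_seed: int | None = None
) -> StudyBundle:
    """Generate a complete multi-ancestry, multi-tissue study bundle.

    One reference panel per ancestry (block-diagonal LD, one block per gene
    locus); one exposure table per (gene, ancestry, tissue); one outcome
    table per ancestry. Outcome samples are drawn independently per gene
    locus — loci are unlinked, so per-locus marginals are distributionally
    equivalent to a genome-wide cohort while memory stays bounded. Causal
    variant positions and effects are shared across ancestries; across
    tissues they follow ``gamma_sharing``. ``architecture_seed`` fixes the
    causal architecture (gamma/delta draws) independently of the cohort
    noise, so independent discovery and replication cohorts of the same
    study are obtained by varying ``seed`` at a fixed ``architecture_seed``.
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_dict(dict(config))
    ss = np.random.SeedSequence(seed)
    ss.spawn(1)  # reserved

    # per-gene architecture, shared across ancestries
    gammas: dict[tuple[str, str], np.ndarray] = {}
    deltas: dict[str, np.ndarray] = {}
    arch_ss = (np.random.SeedSequence(architecture_seed).spawn(2)[1]
               if architecture_seed is not None else ss.spawn(1)[0])
    base_rng = np.random.default_rng(arch_ss)
    for gcfg in config.genes:
        base = _gene_gamma(base_rng, gcfg.m_variants, gcfg.n_causal)
        for tissue in config.tissues:
            if tissue == config.tissues[0] or config.gamma_sharing == "shared":
                g = base
            elif config.gamma_sharing == "sign_flipped":
                g = -base
            else:
                g = _gene_gamma(base_rng, gcfg.m_variants, gcfg.n_causal)
            gammas[(gcfg.gene_id, tissue)] = g
        delta = np.zeros(gcfg.m_variants)
        if gcfg.n_pleio > 0 and gcfg.pleio_sd > 0:
            idx = base_rng.choice(gcfg.m_variants, size=gcfg.n_pleio, replace=False)
            delta[idx] = base_rng.normal(0.0, gcfg.pleio_sd, size=gcfg.n_pleio)
        deltas[gcfg.gene_id] = delta

    genes: dict[str, GeneAnnot] = {}
    truth: dict[str, TruthTable] = {}
    panels: dict[str, ReferencePanel] = {}
    gene_panels: dict[tuple[str, str], ReferencePanel] = {}
    exposures: dict[tuple[str, str, str], SumStats] = {}
    outcomes: dict[str, SumStats] = {}

    for gi, gcfg in enumerate(config.genes):
        start = 1_000_000 + gi * config.locus_spacing_bp
        end = start + (gcfg.m_variants - 1) * config.pos_step
        genes[gcfg.gene_id] = GeneAnnot(gcfg.gene_id, "1", tss=start, start=start, end=end)

    for acfg in config.ancestries:
        anc_ss = ss.spawn(1)[0]
        blocks, variants, eafs, latents = [], [], [], []
        anc_children = anc_ss.spawn(len(config.genes) * 3)
        for gi, gcfg in enumerate(config.genes):
            pcfg = PanelConfig(
                ancestry=acfg.name, m_variants=gcfg.m_variants, n_ref=acfg.n_ref,
                maf_range=acfg.maf_range, ld_rho=acfg.ld_rho,
                seed=int(anc_children[3 * gi].generate_state(1)[0] % (2 ** 31)),
                chrom="1", pos_start=genes[gcfg.gene_id].tss, pos_step=config.pos_step,
            )
            gp = simulate_reference_panel(pcfg)
            gene_panels[(gcfg.gene_id, acfg.name)] = gp
            blocks.append(gp.ld_dense())
            variants.extend(gp.variants)
            eafs.append(gp.eaf)
            latents.append(gp.latent_rho)

        big_ld = sparse.block_diag([sparse.csr_matrix(b) for b in blocks], format="csr")
        panels[acfg.name] = ReferencePanel(
            acfg.name, variants, np.concatenate(eafs), big_ld, config=None,
            latent_rho=None,
        )

        out_frames = []
        for gi, gcfg in enumerate(config.genes):
            if gcfg.ancestries is not None and acfg.name not in gcfg.ancestries:
                continue
            gp = gene_panels[(gcfg.gene_id, acfg.name)]
            tt = TruthTable(
                gamma=gammas[(gcfg.gene_id, config.causal_tissue)],
                theta=gcfg.theta, delta=deltas[gcfg.gene_id],
                h2_expr=gcfg.h2_expr, K=config.K,
                n_exp=acfg.n_exp, n_case=acfg.n_case, n_ctrl=acfg.n_ctrl,
            )
            if acfg.name == config.ancestries[0].name:
                truth[gcfg.gene_id] = tt
            for ti, tissue in enumerate(config.tissues):
                exposures[(gcfg.gene_id, acfg.name, tissue)] = simulate_expression_sumstats(
                    gp, gammas[(gcfg.gene_id, tissue)], gcfg.h2_expr, acfg.n_exp,
                    seed=int(anc_children[3 * gi + 1].generate_state(2)[ti % 2] % (2 ** 31)) + ti,
                    trait_id=gcfg.gene_id, tissue=tissue,
                )
            out = simulate_outcome_sumstats(
                gp, tt, seed=int(anc_children[3 * gi + 2].generate_state(1)[0] % (2 ** 31)),
                trait_id="outcome",
            )
            out_frames.append(out.df)
        odf = pd.concat(out_frames, ignore_index=True)
        outcomes[acfg.name] = SumStats("outcome", TraitRole.OUTCOME, odf, ancestry=acfg.name)

    bundle = StudyBundle(panels=panels, exposures=exposures, outcomes=outcomes,
                         truth=truth, genes=genes, gene_panels=gene_panels)
    for (gene, anc, tissue), s in bundle.exposures.items():
        missing = [v for v in s.df["id"] if v not in bundle.panels[anc]]
        if missing:
            raise RuntimeError(f"exposure {gene}/{anc}/{tissue} has variants absent from panel")
    return bundle


# ---------------------------------------------------------------------------
# serialization


def write_panel(panel: ReferencePanel, prefix) -> None:
    """Serialize a (dense) panel as a variant TSV plus a correlation text file."""
    rows = [{
        "variant_id": v.id, "chromosome": v.chrom, "base_pair_location": v.pos,
        "effect_allele": v.effect_allele, "other_allele": v.other_allele,
        "effect_allele_frequency": panel.eaf[i],
    } for i, v in enumerate(panel.variants)]
    pd.DataFrame(rows).to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.ld.txt", panel.ld_dense(), fmt="%.10g")


def write_study(bundle: StudyBundle, outdir) -> None:
    """Serialize a study bundle as a directory tree of text tables.

    Layout: ``exposures/<gene>.<ancestry>.<tissue>.tsv``,
    ``outcomes/<ancestry>.tsv``, ``panels/<gene>.<ancestry>.*`` (per-locus),
    ``genes.tsv`` and ``truth.tsv``.
    """
    import os

    from .sumstats import write_sumstats

    for sub in ("exposures", "outcomes", "panels"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    for (gene, anc, tissue), s in bundle.exposures.items():
        write_sumstats(s, os.path.join(outdir, "exposures", f"{gene}.{anc}.{tissue}.tsv"))
    for anc, s in bundle.outcomes.items():
        write_sumstats(s, os.path.join(outdir, "outcomes", f"{anc}.tsv"))
    for (gene, anc), p in bundle.gene_panels.items():
        write_panel(p, os.path.join(outdir, "panels", f"{gene}.{anc}"))
    pd.DataFrame([{
        "gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
        "start": g.start, "end": g.end, "strand": g.strand,
    } for g in bundle.genes.values()]).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    pd.DataFrame([{
        "gene_id": g, "theta": t.theta, "h2_expr": t.h2_expr, "K": t.K,
        "n_exp": t.n_exp, "n_case": t.n_case, "n_ctrl": t.n_ctrl,
        "gamma": ",".join(format(x, ".10g") for x in t.gamma),
        "delta": ",".join(format(x, ".10g") for x in t.delta),
    } for g, t in bundle.truth.items()]).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def read_panel(prefix, ancestry: str = "NA") -> ReferencePanel:
    var = pd.read_csv(f"{prefix}.variants.tsv", sep="\t", dtype={"chromosome": str})
    ld = np.loadtxt(f"{prefix}.ld.txt")
    variants = [
        VariantKey(r.variant_id, str(r.chromosome), int(r.base_pair_location),
                   r.effect_allele, r.other_allele)
        for r in var.itertuples()
    ]
    return ReferencePanel(ancestry, variants, var["effect_allele_frequency"].to_numpy(), ld)
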