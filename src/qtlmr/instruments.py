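"""Instrumental-variable selection for cis-QTL two-sample MR.

Pipeline per molecular trait: restrict the exposure table to the gene's
cis-window, keep study-significant QTLs, greedily LD-clump them, substitute
LD proxies for instruments missing from the outcome GWAS, apply the
F-statistic filter (F > f_min, strict) and harmonize against the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GeneAnnot, ReferencePanel
from .sumstats import AssocRecord, HarmonizedPair, SumStats, VariantKey, harmonize


@dataclass
class IVConfig:
    """Thresholds of the instrument-selection pipeline.

    Defaults follow standard cis-MR practice: clumping at r² 0.001 within a
    10 Mb window, proxies at r² > 0.8, weak-instrument cutoff F > 10, and a
    ±1 Mb cis-window around the TSS unless the study defines its own.
    """

    cis_window_bp: int = 1_000_000
    qtl_sig_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    proxy_r2: float = 0.8
    f_min: float = 10.0
    palindrome_eaf_limit: float = 0.42

    def __post_init__(self) -> None:
        if not self.clump_r2 < self.proxy_r2:
            raise ValueError("clump_r2 must be below proxy_r2")
        for name in ("qtl_sig_threshold", "clump_r2", "proxy_r2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class Instrument:
    """One harmonized instrument with its strength and provenance."""

    pair: HarmonizedPair
    f_stat: float
    is_proxy: bool = False
    proxy_source: VariantKey | None = None
    r2_with_source: float | None = None

    @property
    def variant(self) -> VariantKey:
        return self.pair.variant


@dataclass
class InstrumentSet:
    trait_id: str
    ancestry: str
    tissue: str | None
    instruments: list[Instrument]
    selection_log: list[tuple[str, str, str, str]] = field(default_factory=list)
    # entries: (variant_id, stage, action, reason)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def n_iv(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) over instruments."""
        bx = np.array([i.pair.beta_x for i in self.instruments])
        sx = np.array([i.pair.se_x for i in self.instruments])
        by = np.array([i.pair.beta_y for i in self.instruments])
        sy = np.array([i.pair.se_y for i in self.instruments])
        return bx, sx, by, sy

    def log_text(self) -> str:
        lines = ["variant\tstage\taction\treason"]
        lines += ["\t".join(e) for e in self.selection_log]
        return "\n".join(lines) + "\n"


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength F = beta^2 / se^2."""
    if not se > 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def ld_clump(stats: SumStats, panel: ReferencePanel, cfg: IVConfig) -> list[VariantKey]:
    """Greedy p-value-ordered LD pruning.

    Repeatedly take the remaining variant with the smallest p (ties broken by
    position, then id), then discard all remaining variants with r² above
    ``cfg.clump_r2`` within ±``clump_window_bp``/2 of it. Variants absent
    from the panel are dropped with a log entry on the returned list's
    ``dropped`` attribute (the caller's selection log records them).
    """
    df = stats.df
    dropped: list[str] = []
    rows = []
    for r in df.itertuples():
        if r.id not in panel:
            dropped.append(r.id)
            continue
        rows.append((float(r.p), int(r.pos), str(r.id)))
    rows.sort()
    half_window = cfg.clump_window_bp // 2

    kept: list[str] = []
    alive = {rid for _, _, rid in rows}
    for _, pos, rid in rows:
        if rid not in alive:
            continue
        kept.append(rid)
        alive.discard(rid)
        for _, pos2, rid2 in rows:
            if rid2 in alive and abs(pos2 - pos) <= half_window:
                if panel.r2(rid, rid2) > cfg.clump_r2:
                    alive.discard(rid2)

    id2key = {v.id: v for v in panel.variants}
    out = [id2key[i] for i in kept]
    out_with_log = _ListWithDropped(out)
    out_with_log.dropped = dropped
    return out_with_log


class _ListWithDropped(list):
    dropped: list[str] = []


def find_proxy(
    iv: VariantKey,
    outcome: SumStats,
    panel: ReferencePanel,
    cfg: IVConfig,
    exposure: SumStats | None = None,
) -> tuple[VariantKey, float] | None:
    """LD proxy for an instrument missing from the outcome GWAS.

    Among panel variants present in the outcome (and, when given, in the
    exposure table — the exposure effect must be re-anchored to the proxy)
    with r² > ``cfg.proxy_r2`` to ``iv``, return the one with maximal r²;
    ties broken by distance to ``iv``, then lexicographic id.
    """
    if iv.id not in panel:
        return None
    half_window = cfg.clump_window_bp // 2
    out_ids = set(outcome.df["id"])
    exp_ids = None if exposure is None else set(exposure.df["id"])
    best: tuple[float, int, str] | None = None  # (-r2, distance, id)
    for v in panel.variants:
        if v.id == iv.id or v.id not in out_ids:
            continue
        if exp_ids is not None and v.id not in exp_ids:
            continue
        if abs(v.pos - iv.pos) > half_window:
            continue
        r2 = panel.r2(iv.id, v.id)
        if r2 > cfg.proxy_r2:
            cand = (-r2, abs(v.pos - iv.pos), v.id)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    id2key = {v.id: v for v in panel.variants}
    return id2key[best[2]], -best[0]


def select_instruments(
    exposure: SumStats,
    outcome: SumStats,
    panel: ReferencePanel,
    gene: GeneAnnot,
    cfg: IVConfig | None = None,
) -> InstrumentSet:
    """Full IV-selection pipeline for one molecular trait.

    An empty result is a valid outcome (the trait is simply not tested).
    Every variant's fate is recorded in the selection log.
    """
    cfg = cfg or IVConfig()
    log: list[tuple[str, str, str, str]] = []

    lo, hi = gene.tss - cfg.cis_window_bp, gene.tss + cfg.cis_window_bp
    cis = exposure.in_window(gene.chrom, max(lo, 1), hi)
    for rid in set(exposure.df["id"]) - set(cis.df["id"]):
        log.append((rid, "cis_filter", "drop", "outside_cis_window"))

    sig = cis.df[cis.df["p"] < cfg.qtl_sig_threshold]
    for rid in set(cis.df["id"]) - set(sig["id"]):
        log.append((rid, "significance", "drop", "above_qtl_threshold"))
    sig_stats = cis.subset(sig["id"])

    if len(sig_stats) == 0:
        return InstrumentSet(exposure.trait_id, exposure.ancestry, exposure.tissue, [], log)

    clumped = ld_clump(sig_stats, panel, cfg)
    for rid in getattr(clumped, "dropped", []):
        log.append((rid, "clump", "drop", "absent_from_panel"))
    clumped_ids = {v.id for v in clumped}
    for rid in set(sig_stats.df["id"]) - clumped_ids - set(getattr(clumped, "dropped", [])):
        log.append((rid, "clump", "drop", "in_ld_with_index"))
    for v in clumped:
        log.append((v.id, "clump", "keep", "index_variant"))

    out_ids = set(outcome.df["id"])
    instruments: list[Instrument] = []
    for v in clumped:
        exp_rec = exposure.record(v.id)
        is_proxy, source, r2s = False, None, None
        if v.id in out_ids:
            use_v = v
        else:
            hit = find_proxy(v, outcome, panel, cfg, exposure=exposure)
            if hit is None:
                log.append((v.id, "proxy", "drop", "absent_from_outcome_no_proxy"))
                continue
            use_v, r2s = hit
            is_proxy, source = True, v
            exp_rec = exposure.record(use_v.id)
            log.append((v.id, "proxy", "substitute", f"proxy={use_v.id},r2={r2s:.3f}"))

        f = f_statistic(exp_rec.beta, exp_rec.se)
        if not f > cfg.f_min:
            log.append((use_v.id, "f_filter", "drop", f"F={f:.2f}<= {cfg.f_min}"))
            continue

        out_rec = outcome.record(use_v.id)
        pair = harmonize(exp_rec, out_rec, cfg.palindrome_eaf_limit)
        if not pair.usable:
            log.append((use_v.id, "harmonize", "drop", pair.status.value))
            continue
        log.append((use_v.id, "harmonize", "keep", pair.status.value))
        instruments.append(Instrument(pair=pair, f_stat=f, is_proxy=is_proxy,
                                      proxy_source=source, r2_with_source=r2s))

    return InstrumentSet(exposure.trait_id, exposure.ancestry, exposure.tissue,
                         instruments, log)
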