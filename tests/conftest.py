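import numpy as np
import pytest

from qtlmr.instruments import Instrument, InstrumentSet
from qtlmr.simulate import ReferencePanel
from qtlmr.sumstats import (
    AssocRecord,
    HarmonizedPair,
    HarmonizeStatus,
    SumStats,
    TraitRole,
    VariantKey,
    records_to_frame,
)


def make_instrument_set(bx, sx, by, sy, eaf=None, trait="gene", ancestry="EUR"):
    """Instrument set from effect arrays (pre-harmonized, status kept)."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    eaf = np.full(len(bx), 0.3) if eaf is None else np.atleast_1d(eaf)
    insts = []
    for i in range(len(bx)):
        vk = VariantKey(f"rs{i}", "1", 1000 + i * 10, "A", "G")
        pair = HarmonizedPair(vk, float(bx[i]), float(sx[i]), float(by[i]),
                              float(sy[i]), float(eaf[i]), float(eaf[i]),
                              HarmonizeStatus.KEPT)
        insts.append(Instrument(pair=pair, f_stat=(bx[i] / sx[i]) ** 2))
    return InstrumentSet(trait, ancestry, None, insts)


def make_panel(ld, eaf=None, positions=None, ancestry="EUR", chrom="1"):
    """Dense reference panel from an explicit LD matrix."""
    ld = np.asarray(ld, dtype=float)
    m = len(ld)
    eaf = np.full(m, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
    positions = positions if positions is not None else [1000 + 10 * i for i in range(m)]
    variants = [VariantKey(f"v{i}", chrom, int(positions[i]), "A", "G") for i in range(m)]
    return ReferencePanel(ancestry, variants, eaf, ld)


def make_sumstats(ids, pos, beta, se, p=None, eaf=None, n=10000, chrom="1",
                  trait="gene", role=TraitRole.EXPOSURE, n_case=None, n_ctrl=None,
                  ea=None, oa=None):
    recs = []
    m = len(ids)
    ea = ea or ["A"] * m
    oa = oa or ["G"] * m
    for i in range(m):
        vk = VariantKey(ids[i], chrom, int(pos[i]), ea[i], oa[i])
        pv = None if p is None else float(p[i])
        recs.append(AssocRecord(
            vk, float(beta[i]), float(se[i]),
            eaf=None if eaf is None else float(eaf[i]), p=pv, n=n,
            n_case=n_case, n_ctrl=n_ctrl,
        ))
    return SumStats(trait, role, records_to_frame(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
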