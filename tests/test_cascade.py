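"""FDR, the four-criterion causal call, replication and meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qtlmr
from qtlmr.cascade import (
    CascadeThresholds,
    bh_fdr,
    call_causal,
    call_meta_significant,
    evaluate_replication,
    meta_analyze,
    replication_ladder,
)
from qtlmr.coloc import ColocResult
from qtlmr.estimators import MRResult


def bh_oracle(p):
    """Independent brute-force step-up implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_ties_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_matches_stepup_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 50))
            p = rng.uniform(1e-8, 1, m)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_preserving_and_bounded(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1 + 1e-15)


def _coloc(pph4):
    pph = np.array([0.0, 0.0, 0.0, 1 - pph4, pph4])
    return ColocResult(pph=pph, n_variants=50, max_pph4=pph4)


class _FakeSuite:
    """Minimal stand-in exposing what call_causal reads."""

    def __init__(self, concordant=True, i2=10.0, intercept_p=0.5, applicable=True):
        from qtlmr.estimators import HeterogeneityStats
        self.concordant = concordant
        Q = 1.0 if i2 == 0 else (10 / (1 - i2 / 100) if i2 < 100 else 1e6)
        df = 10
        # construct a HeterogeneityStats with the requested I2
        if i2 <= 0:
            self.het = HeterogeneityStats(Q=0.0, df=df, p=1.0)
        else:
            self.het = HeterogeneityStats(Q=df / (1 - i2 / 100), df=df, p=0.5)
        self.egger = MRResult("egger", 0.2, 0.05, 0.01, 10,
                              extra={"intercept": 0.0, "intercept_se": 0.01,
                                     "intercept_p": intercept_p})
        if not applicable:
            self.egger = MRResult.not_applicable("egger", "few IVs")
            self.het = HeterogeneityStats.not_applicable()
            self.concordant = None


class TestCallCausal:
    def _mr(self, p=1e-5):
        return MRResult("ivw", 0.3, 0.05, p, 5)

    def test_all_criteria_pass(self):
        d = call_causal(self._mr(), 0.01, _FakeSuite(), _coloc(0.95))
        assert d.causal

    def test_pph4_threshold_is_strict(self):
        d = call_causal(self._mr(), 0.01, _FakeSuite(), _coloc(0.79))
        assert not d.causal and d.crit_coloc is False
        d2 = call_causal(self._mr(), 0.01, _FakeSuite(), _coloc(0.80))
        assert d2.crit_coloc is False  # exactly 0.8 does not exceed 0.8

    def test_single_iv_trait_can_be_causal(self):
        d = call_causal(self._mr(), 0.001, _FakeSuite(applicable=False), _coloc(0.9))
        assert d.crit_sensitivity is None and d.crit_het_pleio is None
        assert d.causal

    def test_i2_cutoff(self):
        d = call_causal(self._mr(), 0.01, _FakeSuite(i2=60.0), _coloc(0.9))
        assert d.crit_het_pleio is False and not d.causal
        d2 = call_causal(self._mr(), 0.01, _FakeSuite(i2=49.0), _coloc(0.9))
        assert d2.crit_het_pleio is True

    def test_egger_pleiotropy_blocks(self):
        d = call_causal(self._mr(), 0.01, _FakeSuite(intercept_p=0.01), _coloc(0.9))
        assert d.crit_het_pleio is False and not d.causal

    def test_discordant_sensitivity_blocks(self):
        d = call_causal(self._mr(), 0.01, _FakeSuite(concordant=False), _coloc(0.9))
        assert not d.causal

    def test_q_threshold(self):
        d = call_causal(self._mr(), 0.06, _FakeSuite(), _coloc(0.9))
        assert not d.crit_q and not d.causal


def _decision(trait, causal=True):
    from qtlmr.cascade import CausalDecision
    return CausalDecision(trait, "EUR", None, 0.01, True, True, True, True, causal)


class TestReplication:
    def test_absent_traits_excluded(self):
        disc = [_decision("g1"), _decision("g2")]
        rep = {"g1": MRResult("ivw", 0.25, 0.05, 1e-4, 3)}
        dmr = {"g1": MRResult("ivw", 0.3, 0.05, 1e-6, 3),
               "g2": MRResult("ivw", 0.2, 0.05, 1e-6, 3)}
        out = evaluate_replication(disc, rep, dmr)
        assert len(out) == 1 and out[0].trait_id == "g1"

    def test_opposite_sign_not_replicated(self):
        disc = [_decision("g1")]
        rep = {"g1": MRResult("ivw", -0.25, 0.05, 1e-4, 3)}
        dmr = {"g1": MRResult("ivw", 0.3, 0.05, 1e-6, 3)}
        out = evaluate_replication(disc, rep, dmr)
        assert not out[0].replicated and not out[0].direction_concordant

    def test_same_sign_below_q_replicates(self):
        disc = [_decision("g1")]
        rep = {"g1": MRResult("ivw", 0.25, 0.05, 0.04, 3)}
        dmr = {"g1": MRResult("ivw", 0.3, 0.05, 1e-6, 3)}
        out = evaluate_replication(disc, rep, dmr)
        assert out[0].replicated


class TestLadder:
    def _discovery(self, rng, n=20):
        rows = []
        for i in range(n):
            causal = i < 8
            rows.append({
                "trait_id": f"g{i}",
                "p": 10 ** -rng.uniform(3, 9) if causal else rng.uniform(0.001, 1),
                "crit_sensitivity": True if causal else (None if i % 3 else False),
                "crit_het_pleio": True,
                "crit_coloc": causal or (i % 4 == 0),
                "n_iv": 1 + (i % 4),
            })
        d = pd.DataFrame(rows)
        d["q"] = bh_fdr(d["p"])
        return d

    def test_rows_nested_nonincreasing(self, rng):
        d = self._discovery(rng)
        rep = {f"g{i}": MRResult("ivw", 0.2, 0.05, rng.uniform(1e-6, 1), 2)
               for i in range(20)}
        tab = replication_ladder(d, rep)
        ns = tab.set_index("criterion").loc[
            ["1_all_tested", "2_nominal_p", "3_fdr_q", "4_sensitivity",
             "5_colocalization"], "n_significant"]
        assert (ns.diff().dropna() <= 0).all()

    def test_empty_replication_overlap_rate_nan(self, rng):
        d = self._discovery(rng)
        tab = replication_ladder(d, {})
        assert tab["n_tested"].eq(0).all()
        assert tab["rate"].isna().all()

    def test_single_vs_multi_iv_split_present(self, rng):
        d = self._discovery(rng)
        rep = {f"g{i}": MRResult("ivw", 0.2, 0.05, 1e-4, 2) for i in range(20)}
        tab = replication_ladder(d, rep)
        assert {"5_colocalization_single_iv", "5_colocalization_multi_iv"} <= set(tab["criterion"])


class TestMeta:
    def test_identical_inputs_pooled_exactly(self):
        r = MRResult("ivw", 0.3, 0.05, 1e-5, 2)
        m = meta_analyze([r, MRResult("ivw", 0.3, 0.05, 1e-5, 2)])
        assert m.estimate == pytest.approx(0.3)
        assert m.tau2 == 0.0

    def test_dl_closed_form_oracle(self):
        m = meta_analyze([MRResult("ivw", 0.2, 0.05, 0.01, 3),
                          MRResult("ivw", 0.4, 0.05, 0.001, 3)])
        # independent hand computation of DerSimonian-Laird
        w = 1 / 0.05**2
        mu_fe = 0.3
        Q = w * (0.1**2 + 0.1**2)
        tau2 = max(0.0, (Q - 1) / (2 * w - 2 * w**2 / (2 * w)))
        ws = 1 / (0.05**2 + tau2)
        assert m.tau2 == pytest.approx(tau2, abs=1e-10)
        assert m.estimate == pytest.approx(0.3, abs=1e-10)
        assert m.se == pytest.approx(1 / math.sqrt(2 * ws), abs=1e-10)
        assert m.Q_ancestry == pytest.approx(Q, abs=1e-10)

    def test_single_ancestry_fatal(self):
        with pytest.raises(ValueError, match="two ancestries"):
            meta_analyze([MRResult("ivw", 0.2, 0.05, 0.01, 3)])

    def test_zero_tau2_equals_fixed_effect(self, rng):
        # homogeneous estimates: DL tau2 truncates to 0 -> plain IVW pooling
        ests = [0.30, 0.301, 0.299]
        ses = [0.1, 0.12, 0.11]
        rs = [MRResult("ivw", e, s, 0.01, 2) for e, s in zip(ests, ses)]
        m = meta_analyze(rs)
        assert m.tau2 == 0.0
        w = np.array([1 / s**2 for s in ses])
        assert m.estimate == pytest.approx(np.sum(w * ests) / w.sum(), abs=1e-12)

    def test_matches_statsmodels_combine_effects(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects
        for _ in range(10):
            k = int(rng.integers(2, 6))
            eff = rng.normal(0.2, 0.2, k)
            var = rng.uniform(0.001, 0.01, k)
            rs = [MRResult("ivw", e, math.sqrt(v), 0.01, 2) for e, v in zip(eff, var)]
            m = meta_analyze(rs, method="DL")
            ce = combine_effects(eff, var, method_re="chi2")
            # statsmodels reports the untruncated DL tau2; we floor at 0
            assert m.tau2 == pytest.approx(max(ce.tau2, 0.0), abs=1e-10)
            if ce.tau2 > 0:
                re_row = ce.summary_frame().loc["random effect"]
                assert m.estimate == pytest.approx(re_row["eff"], abs=1e-10)


class TestMetaSignificance:
    def _meta(self, q):
        m = meta_analyze([MRResult("ivw", 0.3, 0.05, 1e-4, 3),
                          MRResult("ivw", 0.25, 0.06, 1e-3, 3)])
        m.q = q
        return m

    def test_rule_conjunction(self):
        per = [{"p": 0.03, "decision": _decision("g1")}]
        assert call_meta_significant(self._meta(0.01), per)

    def test_no_cohort_with_coloc_fails(self):
        d = _decision("g1")
        d.crit_coloc = False
        per = [{"p": 0.03, "decision": d}]
        assert not call_meta_significant(self._meta(0.01), per)

    def test_meta_q_above_threshold_fails(self):
        per = [{"p": 0.001, "decision": _decision("g1")}]
        assert not call_meta_significant(self._meta(0.06), per)
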