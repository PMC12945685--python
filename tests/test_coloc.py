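"""Colocalization: ABF posteriors, conditional analysis and PWCoCo behavior."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

import qtlmr
from qtlmr.coloc import (
    ColocPriors,
    PwcocoConfig,
    abf_coloc,
    cojo_condition,
    pwcoco,
    select_signals,
    wakefield_labf,
)
from qtlmr.simulate import simulate_locus_zscores
from qtlmr.sumstats import SumStats

from conftest import make_sumstats


def brute_force_coloc(l1, l2, priors):
    """Independent enumeration over all single-causal configurations."""
    m = len(l1)
    lp1, lp2, lp12 = math.log(priors.p1), math.log(priors.p2), math.log(priors.p12)
    h = [0.0, -math.inf, -math.inf, -math.inf, -math.inf]
    for i in range(m):
        h[1] = np.logaddexp(h[1], lp1 + l1[i])
        h[2] = np.logaddexp(h[2], lp2 + l2[i])
        h[4] = np.logaddexp(h[4], lp12 + l1[i] + l2[i])
        for j in range(m):
            if i != j:
                h[3] = np.logaddexp(h[3], lp1 + lp2 + l1[i] + l2[j])
    h = np.array(h)
    return np.exp(h - logsumexp(h))


def _stats_from_z(z, n=10000, trait="t", role="exposure"):
    m = len(z)
    se = np.full(m, 1 / math.sqrt(n))
    return make_sumstats([f"v{i}" for i in range(m)],
                         [1000 + 10 * i for i in range(m)],
                         z * se, se, p=np.full(m, 0.5), n=n,
                         trait=trait, role=role)


class TestAbfColoc:
    def test_null_locus_favors_h0(self, rng):
        s1 = _stats_from_z(rng.normal(0, 1, 100))
        s2 = _stats_from_z(rng.normal(0, 1, 100))
        r = abf_coloc(s1, s2)
        assert np.argmax(r.pph) == 0

    def test_identical_strong_signal_high_pph4(self, rng):
        z = rng.normal(0, 1, 50)
        z[20] = 12.0
        s1 = _stats_from_z(z)
        s2 = _stats_from_z(z + rng.normal(0, 0.1, 50))
        r = abf_coloc(s1, s2, trait_types=("quantitative", "quantitative"))
        assert r.pph[4] > 0.99

    def test_posteriors_normalized(self, rng):
        for _ in range(10):
            s1 = _stats_from_z(rng.normal(0, 2, 30))
            s2 = _stats_from_z(rng.normal(0, 2, 30))
            r = abf_coloc(s1, s2)
            assert r.pph.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_enumeration_oracle(self, rng):
        priors = ColocPriors()
        for _ in range(10):
            m = int(rng.integers(5, 60))
            z1, z2 = rng.normal(0, 3, m), rng.normal(0, 3, m)
            s1, s2 = _stats_from_z(z1), _stats_from_z(z2)
            r = abf_coloc(s1, s2, priors)
            l1 = wakefield_labf(s1.df["beta"].to_numpy(), s1.df["se"].to_numpy(), 0.20)
            l2 = wakefield_labf(s2.df["beta"].to_numpy(), s2.df["se"].to_numpy(), 0.15)
            expected = brute_force_coloc(l1, l2, priors)
            np.testing.assert_allclose(r.pph, expected, atol=1e-10)

    def test_too_few_shared_variants_not_applicable(self):
        s1 = _stats_from_z(np.array([1.0, 2.0]))
        s2 = make_sumstats(["v0"], [1000], [0.01], [0.01], p=[0.5])
        assert not abf_coloc(s1, s2).applicable

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=1e-4, p2=1e-4, p12=1e-3)


def _ld_panel(rng, m=40, rho=0.6, n_ref=4000, seed=5):
    cfg = qtlmr.PanelConfig(m_variants=m, n_ref=n_ref, ld_rho=rho, seed=seed,
                            maf_range=(0.15, 0.5))
    return qtlmr.simulate_reference_panel(cfg)


class TestCojoCondition:
    def test_empty_conditioning_is_identity(self, rng):
        p = _ld_panel(rng)
        s = simulate_locus_zscores(p, np.zeros(p.m), 10000, seed=1)
        out = cojo_condition(s, p, [])
        np.testing.assert_array_equal(out["beta"], s.df["beta"])

    def test_self_conditioning_zeroes_effect(self, rng):
        p = _ld_panel(rng)
        lam = np.zeros(p.m)
        lam[10] = 8.0
        s = simulate_locus_zscores(p, lam, 10000, seed=2)
        vid = p.variants[10].id
        out = cojo_condition(s, p, [vid])
        assert abs(out.set_index("id").loc[vid, "beta"]) < 1e-10

    def test_orthogonal_variants_unchanged(self):
        ld = np.eye(3)
        from conftest import make_panel
        p = make_panel(ld)
        s = make_sumstats(["v0", "v1", "v2"], [1000, 1010, 1020],
                          [0.1, 0.05, 0.02], [0.01] * 3, p=[1e-5] * 3, n=10000)
        out = cojo_condition(s, p, ["v0"]).set_index("id")
        assert out.loc["v1", "beta"] == pytest.approx(0.05, abs=1e-10)
        assert out.loc["v2", "beta"] == pytest.approx(0.02, abs=1e-10)

    def test_matches_multiple_regression_oracle(self, rng):
        """Conditional estimates from marginals + LD track a full two-variable
        regression on simulated individual-level data."""
        p = _ld_panel(rng, m=12, rho=0.5, n_ref=4000, seed=9)
        n = 20000
        G = p.draw_dosages(n, np.random.default_rng(3))
        b_true = np.zeros(12)
        b_true[2], b_true[8] = 0.15, -0.12
        y = G @ b_true + np.random.default_rng(4).normal(0, 1, n)
        from qtlmr.simulate import linear_marginals
        beta, se, pv = linear_marginals(G, y)
        df = make_sumstats([v.id for v in p.variants], p.positions, beta, se,
                           p=pv, n=n)
        cond_id = p.variants[2].id
        out = cojo_condition(df, p, [cond_id]).set_index("id")
        # oracle: joint regression on [conditioning variant, target variant]
        for target in (5, 8):
            X = np.column_stack([np.ones(n), G[:, 2], G[:, target]])
            bj = np.linalg.lstsq(X, y, rcond=None)[0][2]
            got = out.loc[p.variants[target].id, "beta"]
            assert got == pytest.approx(bj, abs=max(0.1 * abs(bj), 0.02))

    def test_singular_conditioning_set_fatal(self):
        from conftest import make_panel
        ld = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        p = make_panel(ld)
        s = make_sumstats(["v0", "v1", "v2"], [1000, 1010, 1020],
                          [0.1, 0.1, 0.02], [0.01] * 3, p=[1e-5] * 3, n=10000)
        with pytest.raises(np.linalg.LinAlgError):
            cojo_condition(s, p, ["v0", "v1"])


class TestSelectSignals:
    def test_null_locus_returns_empty(self, rng):
        p = _ld_panel(rng, seed=21)
        s = simulate_locus_zscores(p, np.zeros(p.m), 10000, seed=3)
        assert select_signals(s, p, p_threshold=1e-5) == []

    def test_single_causal_yields_one_signal(self, rng):
        hits = 0
        correct_lead = 0
        reps = 20
        for k in range(reps):
            p = _ld_panel(rng, m=30, rho=0.5, seed=100 + k)
            lam = np.zeros(p.m)
            lam[12] = 9.0
            s = simulate_locus_zscores(p, lam, 20000, seed=200 + k)
            sig = select_signals(s, p, p_threshold=1e-5)
            if len(sig) == 1:
                hits += 1
                if sig[0].lead == p.variants[12].id:
                    correct_lead += 1
        assert hits >= int(0.9 * reps)
        assert correct_lead >= int(0.8 * hits)

    def test_two_independent_causals_found(self, rng):
        found = 0
        reps = 15
        for k in range(reps):
            p = _ld_panel(rng, m=40, rho=0.3, seed=300 + k)
            lam = np.zeros(p.m)
            lam[5], lam[34] = 9.0, 9.0  # far apart: r2 << 0.01
            s = simulate_locus_zscores(p, lam, 20000, seed=400 + k)
            sig = select_signals(s, p, p_threshold=1e-5)
            if len(sig) == 2:
                found += 1
        assert found >= int(0.8 * reps)


class TestPwcoco:
    def test_high_marginal_pph4_short_circuits(self, rng):
        p = _ld_panel(rng, seed=31)
        lam = np.zeros(p.m)
        lam[10] = 10.0
        s1 = simulate_locus_zscores(p, lam, 20000, seed=5)
        s2 = simulate_locus_zscores(p, lam, 20000, seed=6)
        marg = abf_coloc(s1, s2)
        assert marg.pph4 >= 0.8
        r = pwcoco(s1, s2, p)
        assert r.pairs_tested == 1
        np.testing.assert_array_equal(r.pph, marg.pph)

    def test_single_signal_locus_equals_abf(self, rng):
        p = _ld_panel(rng, seed=41)
        lam = np.zeros(p.m)
        lam[10] = 10.0
        s1 = simulate_locus_zscores(p, lam, 20000, seed=7)
        s2 = simulate_locus_zscores(p, lam, 20000, seed=8)
        r1 = abf_coloc(s1, s2)
        r2 = pwcoco(s1, s2, p)
        np.testing.assert_array_equal(r1.pph, r2.pph)

    def test_shared_secondary_signal_rescued(self, rng):
        """Two causal variants per trait sharing exactly one: marginal coloc
        is ambiguous but a conditioned pair colocalizes."""
        rescued = 0
        reps = 10
        for k in range(reps):
            p = _ld_panel(rng, m=60, rho=0.4, seed=500 + k)
            shared, own1, own2 = 30, 5, 55
            lam1 = np.zeros(p.m)
            lam2 = np.zeros(p.m)
            lam1[shared] = lam2[shared] = 8.0
            lam1[own1] = 14.0
            lam2[own2] = 14.0
            s1 = simulate_locus_zscores(p, lam1, 20000, seed=600 + k)
            s2 = simulate_locus_zscores(p, lam2, 20000, seed=700 + k)
            cfg = PwcocoConfig(p_threshold_1=1e-4, p_threshold_2=1e-4)
            r = pwcoco(s1, s2, p, cfg=cfg)
            if r.max_pph4 > 0.8:
                rescued += 1
        assert rescued >= int(0.8 * reps)

    def test_max_pph4_not_below_marginal(self, rng):
        p = _ld_panel(rng, seed=61)
        s1 = simulate_locus_zscores(p, rng.normal(0, 2, p.m), 10000, seed=9)
        s2 = simulate_locus_zscores(p, rng.normal(0, 2, p.m), 10000, seed=10)
        marg = abf_coloc(s1, s2)
        r = pwcoco(s1, s2, p)
        assert r.max_pph4 >= marg.pph4 - 1e-12
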