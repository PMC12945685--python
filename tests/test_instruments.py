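"""Instrument selection: F filter, clumping, proxies and the full pipeline."""

import numpy as np
import pytest

import qtlmr
from qtlmr.instruments import IVConfig, f_statistic, find_proxy, ld_clump, select_instruments
from qtlmr.simulate import GeneAnnot
from qtlmr.sumstats import TraitRole

from conftest import make_panel, make_sumstats


def _corr(m, pairs):
    """Correlation matrix with specified off-diagonal entries (PSD by design)."""
    r = np.eye(m)
    for i, j, v in pairs:
        r[i, j] = r[j, i] = v
    w = np.linalg.eigvalsh(r)
    assert w.min() > -1e-10
    return r


class TestFStatistic:
    def test_printed_formula(self):
        assert f_statistic(0.5, 0.05) == pytest.approx(100.0)

    def test_null_effect(self):
        assert f_statistic(0.0, 0.1) == 0.0

    def test_sign_irrelevant_and_boundary_excluded(self):
        f = f_statistic(-0.3, 0.1)
        assert f == pytest.approx(9.0)
        assert not f > IVConfig().f_min  # strictly-greater rule excludes F=9

    def test_nonpositive_se_fatal(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


class TestLdClump:
    def test_independent_variants_both_kept(self):
        panel = make_panel(_corr(2, []))
        s = make_sumstats(["v0", "v1"], [1000, 1010], [0.1, 0.1], [0.01, 0.01],
                          p=[1e-10, 1e-8])
        kept = ld_clump(s, panel, IVConfig())
        assert {v.id for v in kept} == {"v0", "v1"}

    def test_correlated_pair_keeps_smaller_p(self):
        panel = make_panel(_corr(2, [(0, 1, np.sqrt(0.5))]))
        s = make_sumstats(["v0", "v1"], [1000, 1010], [0.1, 0.1], [0.01, 0.01],
                          p=[1e-10, 1e-4])
        kept = ld_clump(s, panel, IVConfig())
        assert [v.id for v in kept] == ["v0"]

    def test_window_limits_pruning(self):
        # correlated but outside the clump window: both survive
        panel = make_panel(_corr(2, [(0, 1, 0.9)]), positions=[1000, 20_000_000])
        s = make_sumstats(["v0", "v1"], [1000, 20_000_000], [0.1, 0.1], [0.01, 0.01],
                          p=[1e-10, 1e-4])
        cfg = IVConfig(clump_window_bp=10_000_000)
        kept = ld_clump(s, panel, cfg)
        assert {v.id for v in kept} == {"v0", "v1"}

    def test_matches_brute_force_oracle(self, rng):
        """Greedy clumping equals an independently coded exhaustive oracle."""
        def oracle(pvals, positions, R, r2_max, half_window):
            remaining = sorted(range(len(pvals)),
                               key=lambda i: (pvals[i], positions[i], f"v{i}"))
            kept = []
            alive = set(remaining)
            for i in remaining:
                if i not in alive:
                    continue
                kept.append(i)
                alive.discard(i)
                for j in list(alive):
                    if abs(positions[j] - positions[i]) <= half_window and R[i, j] ** 2 > r2_max:
                        alive.discard(j)
            return kept

        for trial in range(100):
            m = 50
            A = rng.normal(size=(m, 5))
            cov = A @ A.T + np.diag(rng.uniform(0.5, 2, m))
            d = np.sqrt(np.diag(cov))
            R = cov / np.outer(d, d)
            positions = np.sort(rng.integers(1, 5_000_000, size=m))
            pvals = rng.uniform(1e-12, 1, size=m)
            panel = make_panel(R, positions=positions)
            s = make_sumstats([f"v{i}" for i in range(m)], positions,
                              np.full(m, 0.1), np.full(m, 0.01), p=pvals)
            cfg = IVConfig(clump_r2=0.1, clump_window_bp=2_000_000)
            kept = [v.id for v in ld_clump(s, panel, cfg)]
            exp = [f"v{i}" for i in oracle(pvals, positions, R, 0.1, 1_000_000)]
            assert kept == exp, f"trial {trial}"

    def test_kept_pairs_below_threshold(self, rng):
        m = 30
        A = rng.normal(size=(m, 3))
        cov = A @ A.T + np.eye(m)
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        positions = [1000 + i * 10 for i in range(m)]
        panel = make_panel(R, positions=positions)
        s = make_sumstats([f"v{i}" for i in range(m)], positions,
                          np.full(m, 0.1), np.full(m, 0.01),
                          p=rng.uniform(size=m))
        cfg = IVConfig(clump_r2=0.05)
        kept = [v.id for v in ld_clump(s, panel, cfg)]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert panel.r2(a, b) <= 0.05

    def test_row_order_invariance(self, rng):
        m = 20
        R = np.eye(m)
        positions = [1000 + i * 10 for i in range(m)]
        pvals = rng.uniform(size=m)
        panel = make_panel(R, positions=positions)
        ids = [f"v{i}" for i in range(m)]
        s1 = make_sumstats(ids, positions, np.full(m, 0.1), np.full(m, 0.01), p=pvals)
        perm = rng.permutation(m)
        s2 = make_sumstats([ids[i] for i in perm], [positions[i] for i in perm],
                           np.full(m, 0.1), np.full(m, 0.01), p=pvals[perm])
        k1 = [v.id for v in ld_clump(s1, panel, IVConfig())]
        k2 = [v.id for v in ld_clump(s2, panel, IVConfig())]
        assert k1 == k2


class TestFindProxy:
    def _setup(self, r2_proxy):
        r = np.sqrt(r2_proxy)
        panel = make_panel(_corr(3, [(0, 1, r)]), positions=[1000, 2000, 3000])
        outcome = make_sumstats(["v1", "v2"], [2000, 3000], [0.05, 0.05],
                                [0.01, 0.01], p=[1e-4, 1e-4], role=TraitRole.OUTCOME)
        return panel, outcome

    def test_unique_candidate_returned(self):
        panel, outcome = self._setup(0.9)
        iv = panel.variants[0]
        hit = find_proxy(iv, outcome, panel, IVConfig())
        assert hit is not None
        vid, r2 = hit
        assert vid.id == "v1" and r2 == pytest.approx(0.9, abs=1e-9)

    def test_threshold_is_strict(self):
        panel, outcome = self._setup(0.79)
        assert find_proxy(panel.variants[0], outcome, panel, IVConfig()) is None

    def test_tie_broken_by_distance(self):
        r = np.sqrt(0.9)
        panel = make_panel(_corr(3, [(0, 1, r), (0, 2, r), (1, 2, 0.85)]),
                           positions=[10_000, 15_000, 11_000])
        outcome = make_sumstats(["v1", "v2"], [15_000, 11_000], [0.05, 0.05],
                                [0.01, 0.01], p=[1e-4, 1e-4], role=TraitRole.OUTCOME)
        hit = find_proxy(panel.variants[0], outcome, panel, IVConfig())
        assert hit[0].id == "v2"  # 1 kb away beats 5 kb away


class TestSelectInstruments:
    def _gene(self):
        return GeneAnnot("G1", "1", tss=1000, start=1000, end=5000)

    def _exposure(self, beta, se, p):
        return make_sumstats(["v0"], [1000], [beta], [se], p=[p], eaf=[0.3], n=5000)

    def test_single_strong_instrument_passes(self):
        panel = make_panel(np.eye(1))
        exp = self._exposure(0.5, 0.05, 1e-20)  # F = 100
        out = make_sumstats(["v0"], [1000], [0.1], [0.02], p=[1e-6],
                            role=TraitRole.OUTCOME)
        s = select_instruments(exp, out, panel, self._gene(), IVConfig())
        assert s.n_iv == 1 and s.instruments[0].f_stat == pytest.approx(100)

    def test_weak_instrument_filtered(self):
        panel = make_panel(np.eye(1))
        exp = self._exposure(0.3, 0.1, 1e-20)  # F = 9
        out = make_sumstats(["v0"], [1000], [0.1], [0.02], p=[1e-6],
                            role=TraitRole.OUTCOME)
        s = select_instruments(exp, out, panel, self._gene(), IVConfig())
        assert s.n_iv == 0
        assert any(e[1] == "f_filter" for e in s.selection_log)

    def test_proxy_path(self):
        r = np.sqrt(0.95)
        panel = make_panel(_corr(2, [(0, 1, r)]), positions=[1000, 1500])
        exp = make_sumstats(["v0", "v1"], [1000, 1500], [0.5, 0.48], [0.05, 0.05],
                            p=[1e-20, 1e-19], eaf=[0.3, 0.3])
        out = make_sumstats(["v1"], [1500], [0.1], [0.02], p=[1e-6],
                            role=TraitRole.OUTCOME)
        s = select_instruments(exp, out, panel, self._gene(), IVConfig())
        assert s.n_iv == 1
        inst = s.instruments[0]
        assert inst.is_proxy and inst.variant.id == "v1"
        assert inst.proxy_source.id == "v0"
        assert inst.r2_with_source > 0.8

    def test_outside_cis_window_excluded(self):
        panel = make_panel(np.eye(1), positions=[5_000_000])
        exp = make_sumstats(["v0"], [5_000_000], [0.5], [0.05], p=[1e-20], eaf=[0.3])
        out = make_sumstats(["v0"], [5_000_000], [0.1], [0.02], p=[1e-6],
                            role=TraitRole.OUTCOME)
        s = select_instruments(exp, out, panel, self._gene(),
                               IVConfig(cis_window_bp=1_000_000))
        assert s.n_iv == 0
        assert any(e[1] == "cis_filter" for e in s.selection_log)

    def test_monotone_in_f_min(self, rng):
        m = 10
        panel = make_panel(np.eye(m), positions=[1000 + 10 * i for i in range(m)])
        beta = rng.uniform(0.1, 0.6, m)
        se = np.full(m, 0.05)
        exp = make_sumstats([f"v{i}" for i in range(m)],
                            [1000 + 10 * i for i in range(m)], beta, se,
                            p=np.full(m, 1e-20), eaf=np.full(m, 0.3))
        out = make_sumstats([f"v{i}" for i in range(m)],
                            [1000 + 10 * i for i in range(m)],
                            rng.normal(0, 0.05, m), np.full(m, 0.02),
                            p=np.full(m, 1e-3), role=TraitRole.OUTCOME)
        counts = []
        for fmin in (5, 10, 50, 100):
            s = select_instruments(exp, out, panel, self._gene(), IVConfig(f_min=fmin))
            counts.append(s.n_iv)
        assert counts == sorted(counts, reverse=True)
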