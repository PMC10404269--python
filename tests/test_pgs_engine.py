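"""LD scores, LD-score regression, Gibbs shrinkage and score projection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multipgs import pgs_engine as pe
from multipgs import synthetic_data as sd
from multipgs import sumstats_io as sio


def _sumstats_from_std(panel, beta_hat_std, n):
    """Wrap standardized marginal effects as a canonical SumStats table."""
    sd_ref = panel.sd
    tab = pd.DataFrame({
        "rsid": panel.variants["id"], "chr": panel.variants["chromosome"],
        "pos": panel.variants["position"], "a1": panel.variants["allele_alt"],
        "a0": panel.variants["allele_ref"], "beta": beta_hat_std / sd_ref,
        "se": 1.0 / (sd_ref * np.sqrt(n)), "freq": panel.maf,
        "n_eff": float(n), "panel_index": np.arange(panel.m),
    })
    return sio.SumStats(table=tab, meta={"trait": "toy"})


class TestLdScores:
    def test_identity_ld_gives_ones(self):
        panel = sd.simulate_panel(20, 5, rho=0.0, seed=1)
        np.testing.assert_allclose(pe.ld_scores(panel), 1.0)

    def test_pair_block_closed_form(self):
        panel = sd.simulate_panel(2, 2, rho=0.5, seed=1)
        np.testing.assert_allclose(pe.ld_scores(panel), [1.25, 1.25])

    def test_matches_bruteforce_row_sums(self):
        panel = sd.simulate_panel(100, 100, rho=0.9, seed=2)
        (_, R) = panel.blocks[0]
        brute = np.array([(R[j] ** 2).sum() for j in range(100)])
        np.testing.assert_allclose(pe.ld_scores(panel), brute)

    def test_lower_bounded_by_one(self, small_panel):
        assert pe.ld_scores(small_panel).min() >= 1.0


class TestLdscH2:
    def test_null_simulation_estimates_near_zero(self):
        panel = sd.simulate_panel(5000, 50, rho=0.5, seed=3)
        arch = sd.simulate_architecture(panel, 1, h2=0.5, polygenicity=0.1,
                                        seed=3)
        arch.beta_true[:] = 0.0
        ld = pe.ld_scores(panel)
        ests = []
        for s in range(5):
            ss = sd.simulate_sumstats(panel, arch, 0, 50_000, seed=40 + s)
            ests.append(pe.ldsc_h2(ss, ld)[0])
        assert np.median(ests) <= 0.02

    def test_recovers_simulated_h2(self):
        panel = sd.simulate_panel(5000, 50, rho=0.5, seed=4)
        ld = pe.ld_scores(panel)
        ests = []
        for s in range(5):
            arch = sd.simulate_architecture(panel, 1, h2=0.5,
                                            polygenicity=0.05, seed=50 + s)
            ss = sd.simulate_sumstats(panel, arch, 0, 50_000, seed=60 + s)
            ests.append(pe.ldsc_h2(ss, ld)[0])
        assert np.median(ests) == pytest.approx(0.5, abs=0.1)

    def test_constant_chi2_clamps_to_floor(self):
        panel = sd.simulate_panel(100, 10, rho=0.3, seed=5)
        beta_hat = np.full(100, 1.0 / np.sqrt(1000))   # chi2_j = 1 everywhere
        ss = _sumstats_from_std(panel, beta_hat, 1000)
        h2, meta = pe.ldsc_h2(ss, pe.ld_scores(panel))
        assert h2 == pytest.approx(0.001)

    def test_degenerate_design_falls_back(self):
        panel = sd.simulate_panel(100, 10, rho=0.0, seed=6)   # all l_j = 1
        rng = np.random.default_rng(6)
        ss = _sumstats_from_std(panel, rng.standard_normal(100) / 30, 1000)
        h2, meta = pe.ldsc_h2(ss, pe.ld_scores(panel))
        assert meta.get("fallback") == "mean_chi2"


class TestGibbs:
    def test_zero_signal_gives_zero_posterior(self):
        panel = sd.simulate_panel(100, 10, rho=0.4, seed=7)
        ss = _sumstats_from_std(panel, np.zeros(100), 10_000)
        w = pe.ldpred_auto(ss, panel, n_chains=4, burn_in=50, n_iter=50,
                           h2_init=0.1, seed=7)
        assert np.abs(w.beta).max() < 5e-3

    def test_infinitesimal_closed_form_identity_ld(self):
        # p fixed at 1, identity LD: shrinkage is beta_hat / (1 + M/(n h2))
        panel = sd.simulate_panel(50, 1, rho=0.0, seed=8)
        rng = np.random.default_rng(8)
        beta_hat = rng.standard_normal(50) * 0.05
        n, h2 = 10_000, 0.3
        ss = _sumstats_from_std(panel, beta_hat, n)
        w = pe.ldpred_auto(ss, panel, n_chains=1, burn_in=5, n_iter=5,
                           p_fixed=1.0, h2_fixed=h2, sample_effects=False,
                           seed=8)
        expected = beta_hat / (1.0 + panel.m / (n * h2))
        np.testing.assert_allclose(w.beta, expected, atol=1e-6)

    def test_posterior_matches_bruteforce_enumeration(self):
        # M=3, one block: exact posterior mean by enumerating all 2^3
        # causal configurations under fixed (p, h2)
        rho = 0.4
        panel = sd.simulate_panel(3, 3, rho=rho, seed=9)
        (_, R) = panel.blocks[0]
        n, p, h2 = 2000.0, 0.3, 0.2
        M = 3
        s2 = h2 / (M * p)
        beta_hat = np.array([0.04, -0.01, 0.02])

        # oracle: beta_hat | C ~ N(0, s2 R_C R_C' + R/n)
        post_mean = np.zeros(M)
        total_w = 0.0
        for mask in range(8):
            C = np.array([(mask >> j) & 1 for j in range(M)], dtype=bool)
            Sigma = R / n
            if C.any():
                Rc = R[:, C]
                Sigma = Sigma + s2 * (Rc @ Rc.T)
            wgt = (p ** C.sum()) * ((1 - p) ** (M - C.sum())) * \
                stats.multivariate_normal.pdf(beta_hat, mean=np.zeros(M),
                                              cov=Sigma)
            mean_c = np.zeros(M)
            if C.any():
                cross = s2 * R[:, C].T            # cov(beta_C, beta_hat)
                mean_c[C] = cross @ np.linalg.solve(Sigma, beta_hat)
            post_mean += wgt * mean_c
            total_w += wgt
        post_mean /= total_w

        ss = _sumstats_from_std(panel, beta_hat, n)
        w = pe.ldpred_auto(ss, panel, n_chains=4, burn_in=2000, n_iter=20_000,
                           p_fixed=p, h2_fixed=h2, seed=9)
        live = w.chain_betas[w.alive]
        mc_se = live.std(axis=0) / np.sqrt(live.shape[0]) + 1e-4
        np.testing.assert_array_less(np.abs(w.beta - post_mean), 3 * mc_se)

    def test_shrinkage_monotone_in_prior_ratio(self):
        # identity LD: posterior |beta| non-increasing as M p/(n h2) grows
        panel = sd.simulate_panel(20, 1, rho=0.0, seed=10)
        beta_hat = np.full(20, 0.05)
        n = 5000.0
        out = []
        for h2 in (0.5, 0.2, 0.05, 0.01):
            ss = _sumstats_from_std(panel, beta_hat, n)
            w = pe.ldpred_auto(ss, panel, n_chains=1, burn_in=5, n_iter=5,
                               p_fixed=1.0, h2_fixed=h2, sample_effects=False,
                               seed=10)
            out.append(np.abs(w.beta).mean())
        assert all(a >= b for a, b in zip(out, out[1:]))

    def test_recovers_h2_and_p_from_simulation(self):
        panel = sd.simulate_panel(2000, 50, rho=0.5, seed=11)
        h2s, ps = [], []
        for s in range(3):
            arch = sd.simulate_architecture(panel, 1, h2=0.4,
                                            polygenicity=0.02, seed=70 + s)
            ss = sio.harmonize(
                sd.simulate_sumstats(panel, arch, 0, 50_000, seed=80 + s),
                panel)
            w = pe.ldpred_auto(ss, panel, n_chains=10, burn_in=200,
                               n_iter=100, seed=80 + s)
            h2s.append(w.h2_hat)
            ps.append(w.p_hat)
        assert np.median(h2s) == pytest.approx(0.4, abs=0.1)
        assert 0.5 * 0.02 <= np.median(ps) <= 1.5 * 0.02

    def test_fixed_seed_reproducible(self, small_panel, small_sumstats):
        ss = sio.harmonize(small_sumstats, small_panel)
        a = pe.ldpred_auto(ss, small_panel, n_chains=2, burn_in=20, n_iter=20,
                           seed=12)
        b = pe.ldpred_auto(ss, small_panel, n_chains=2, burn_in=20, n_iter=20,
                           seed=12)
        np.testing.assert_array_equal(a.beta, b.beta)


class TestFilterChains:
    def _weights(self, chain_betas, alive=None):
        n_chains, m = chain_betas.shape
        return pe.PGSWeights(
            panel_index=np.arange(m), rsid=np.array([f"rs{i}" for i in range(m)]),
            a1=np.array(["A"] * m), chain_betas=chain_betas,
            p_trace=np.full((n_chains, 3), 0.1),
            h2_trace=np.full((n_chains, 3), 0.3),
            alive=np.ones(n_chains, bool) if alive is None else alive)

    def test_identical_chains_all_kept(self):
        cb = np.tile(np.linspace(-1, 1, 10), (5, 1))
        w = pe.filter_chains(self._weights(cb))
        assert w.meta["kept_chains"] == 5
        np.testing.assert_allclose(w.beta, cb[0])

    def test_zeroed_chain_excluded(self):
        rng = np.random.default_rng(0)
        cb = rng.standard_normal((10, 50))
        cb[3] = 0.0
        w = pe.filter_chains(self._weights(cb))
        assert not w.kept[3]
        assert w.meta["kept_chains"] == int(w.kept.sum())

    def test_fallback_single_chain(self):
        cb = np.zeros((3, 10))
        cb[1, 0] = 1e-30
        w = pe.filter_chains(self._weights(np.zeros((3, 10))))
        assert w.meta.get("fallback_single_chain", False) or \
            w.meta["kept_chains"] >= 1


class TestProject:
    def test_zero_weights_zero_scores(self, small_panel, small_cohort,
                                      small_sumstats):
        ss = sio.harmonize(small_sumstats, small_panel)
        w = pe.ldpred_auto(ss, small_panel, n_chains=2, burn_in=10, n_iter=10,
                           seed=13)
        w.beta = np.zeros_like(w.beta)
        np.testing.assert_allclose(pe.project(w, small_cohort), 0.0)

    def test_single_variant_weight_is_standardized_dosage(self, small_panel,
                                                          small_cohort):
        m = small_panel.m
        beta = np.zeros(m)
        beta[7] = 1.0
        w = pe.PGSWeights(
            panel_index=np.arange(m), rsid=small_panel.variants["id"].to_numpy(),
            a1=small_panel.variants["allele_alt"].to_numpy(),
            chain_betas=beta[None, :], p_trace=np.zeros((1, 1)),
            h2_trace=np.zeros((1, 1)), alive=np.ones(1, bool))
        w.beta = beta
        score = pe.project(w, small_cohort)
        expected = small_cohort.standardized_dosages()[:, 7]
        np.testing.assert_allclose(score, expected, atol=1e-5)

    def test_projected_score_tracks_genetic_value(self, small_panel, small_arch,
                                                  small_cohort):
        ss = sio.harmonize(
            sd.simulate_sumstats(small_panel, small_arch, 0, 80_000, seed=14),
            small_panel)
        w = pe.ldpred_auto(ss, small_panel, n_chains=6, burn_in=100, n_iter=50,
                           seed=14)
        score = pe.project(w, small_cohort)
        r2 = np.corrcoef(score, small_cohort.genetic_values[:, 0])[0, 1] ** 2
        assert 0.5 < r2 <= 1.0

    def test_accuracy_increases_with_gwas_n(self, small_panel, small_arch,
                                            small_cohort):
        r2s = []
        for n_gwas in (5_000, 20_000, 80_000):
            ss = sio.harmonize(
                sd.simulate_sumstats(small_panel, small_arch, 0, n_gwas,
                                     seed=15), small_panel)
            w = pe.ldpred_auto(ss, small_panel, n_chains=6, burn_in=100,
                               n_iter=50, seed=15)
            score = pe.project(w, small_cohort)
            r2s.append(np.corrcoef(score,
                                   small_cohort.genetic_values[:, 0])[0, 1] ** 2)
        assert r2s[0] < r2s[1] < r2s[2]
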