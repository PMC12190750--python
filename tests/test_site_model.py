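"""Per-site binomial GLM: IRLS vs closed form, Cook's distances, pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmscall.site_model import (
    SiteModelConfig,
    fit_glm_batch,
    fit_site_glm,
    glm_cooks,
    pooled_logodds_oracle,
)
from dmscall.site_model import test_sites_per_line as fit_sites_per_line
from dmscall.synthetic_data import SimConfig, simulate_experiment


def random_tables(rng, n_sites, n_samples=7, depth=80):
    cond = (np.arange(n_samples) % 2).astype(float)
    n = rng.poisson(depth, size=(n_sites, n_samples)) + 1
    p = rng.uniform(0.05, 0.95, size=(n_sites, 1))
    shift = rng.normal(0, 0.5, size=(n_sites, 1))
    from scipy.special import expit, logit

    probs = expit(logit(p) + shift * cond[None, :])
    m = rng.binomial(n, probs)
    return m, n - m, cond


class TestFitSiteGlm:
    def test_matches_worked_closed_form(self):
        # pooled low (10, 90), high (30, 70)
        fit = fit_site_glm([10, 30], [90, 70], ["low", "high"])
        assert fit.converged
        assert fit.beta1 == pytest.approx(np.log(27 / 7), abs=1e-9)
        assert fit.se1 == pytest.approx(
            np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90), abs=1e-9
        )
        assert fit.wald_z == pytest.approx(fit.beta1 / fit.se1)

    def test_identical_conditions_give_null(self):
        fit = fit_site_glm([10, 10], [90, 90], ["low", "high"])
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.p == pytest.approx(1.0)

    def test_label_swap_negates_effect(self):
        a = fit_site_glm([10, 30], [90, 70], ["low", "high"])
        b = fit_site_glm([10, 30], [90, 70], ["high", "low"])
        assert b.beta1 == pytest.approx(-a.beta1, abs=1e-10)
        assert b.se1 == pytest.approx(a.se1, abs=1e-12)
        assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_separation_flagged_not_estimable(self):
        fit = fit_site_glm([0, 30], [90, 70], ["low", "high"])
        assert not fit.converged
        assert np.isnan(fit.beta1)

    def test_zero_coverage_condition_not_testable(self):
        with pytest.raises(ValueError, match="not testable"):
            fit_site_glm([0, 30], [0, 70], ["low", "high"])

    def test_leverages_sum_to_coefficient_count(self):
        fit = fit_site_glm([10, 12, 30, 28], [90, 88, 70, 72],
                           ["low", "low", "high", "high"])
        assert fit.leverages.sum() == pytest.approx(2.0, abs=1e-8)

    def test_irls_matches_oracle_on_random_tables(self, rng):
        m, c, cond = random_tables(rng, 1000)
        res = fit_glm_batch(m, c, cond)
        ok = res["converged"]
        assert ok.mean() > 0.99
        for i in np.flatnonzero(ok)[:1000]:
            b, s = pooled_logodds_oracle(m[i], c[i], cond)
            assert abs(res["beta1"][i] - b) <= 1e-8
            assert abs(res["se1"][i] - s) <= 1e-8

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        m = np.array([12, 9, 14, 30, 25, 28, 33])
        c = np.array([88, 91, 86, 70, 75, 72, 67])
        cond = np.array([0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = fit_site_glm(m, c, cond)
        X = np.column_stack([np.ones(7), cond])
        glm = sm.GLM(np.column_stack([m, c]), X, family=sm.families.Binomial()).fit()
        assert fit.beta0 == pytest.approx(glm.params[0], abs=1e-8)
        assert fit.beta1 == pytest.approx(glm.params[1], abs=1e-8)
        assert fit.se1 == pytest.approx(glm.bse[1], abs=1e-8)

    def test_depth_scaling_shrinks_se(self):
        ses = []
        for scale in (1, 2, 4, 8):
            fit = fit_site_glm(
                np.array([10, 30]) * scale, np.array([90, 70]) * scale,
                ["low", "high"],
            )
            ses.append(fit.se1)
        assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_null_wald_p_approximately_uniform(self, rng):
        # pooled depth >= 300 per condition; rejection at 5% within MC band
        n_sites = 5000
        cond = np.array([0, 0, 0, 1, 1, 1, 1], dtype=float)
        n = np.full((n_sites, 7), 100)
        p0 = rng.uniform(0.1, 0.5, size=(n_sites, 1))
        m = rng.binomial(n, np.broadcast_to(p0, n.shape))
        res = fit_glm_batch(m, n - m, cond)
        rej = (res["p"][res["converged"]] < 0.05).mean()
        assert 0.035 <= rej <= 0.065


class TestCooks:
    def test_symmetric_samples_share_cooks_d(self):
        fit = fit_site_glm([10, 10, 30, 30], [90, 90, 70, 70],
                           ["low", "low", "high", "high"])
        d = fit.cooks_d
        assert d[0] == pytest.approx(d[1], abs=1e-12)
        assert d[2] == pytest.approx(d[3], abs=1e-12)

    def test_zero_residual_gives_cooks_p_one(self):
        fit = fit_site_glm([10, 10, 30, 30], [90, 90, 70, 70],
                           ["low", "low", "high", "high"])
        assert np.allclose(fit.cooks_d, 0.0, atol=1e-20)
        assert np.allclose(fit.cooks_p, 1.0)

    def test_matches_independent_formula_recomputation(self):
        m = np.array([12, 9, 14, 30, 45, 28, 33])
        c = np.array([88, 91, 86, 70, 55, 72, 67])
        cond = np.array([0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = fit_site_glm(m, c, cond)
        # brute-force recomputation from the weighted hat matrix
        n = (m + c).astype(float)
        mu = 1 / (1 + np.exp(-(fit.beta0 + fit.beta1 * cond)))
        W = np.diag(n * mu * (1 - mu))
        X = np.column_stack([np.ones(7), cond])
        H = np.sqrt(W) @ X @ np.linalg.inv(X.T @ W @ X) @ X.T @ np.sqrt(W)
        h = np.diag(H)
        r = (m / n - mu) * np.sqrt(n / (mu * (1 - mu)))
        d = r**2 * h / (2 * (1 - h) ** 2)
        np.testing.assert_allclose(fit.cooks_d, d, atol=1e-8)
        np.testing.assert_allclose(
            fit.cooks_p, stats.f.sf(d, 2, 5), atol=1e-8
        )

    def test_glm_cooks_consistent_with_fit(self):
        m = np.array([12, 9, 30, 45])
        c = np.array([88, 91, 70, 55])
        cond = np.array([0, 0, 1, 1], dtype=float)
        fit = fit_site_glm(m, c, cond)
        mu = 1 / (1 + np.exp(-(fit.beta0 + fit.beta1 * cond)))
        d, p = glm_cooks(m, c, cond, mu)
        np.testing.assert_allclose(d, fit.cooks_d, atol=1e-10)
        np.testing.assert_allclose(p, fit.cooks_p, atol=1e-10)

    def test_two_samples_unprunable(self):
        # n == p: F distribution undefined, cooks_p NaN
        fit = fit_site_glm([10, 30], [90, 70], ["low", "high"])
        assert np.isnan(fit.cooks_p).all()


@pytest.fixture(scope="module")
def line_sim():
    return simulate_experiment(SimConfig(seed=42, n_sites=300, depth_mean=80.0))


class TestTestSitesPerLine:
    def test_emits_one_row_per_site_with_flags(self, line_sim):
        fits = fit_sites_per_line(
            line_sim.native["a"], line_sim.sample_sheet, "lineA"
        )
        assert len(fits) == line_sim.native["a"].n_sites
        assert fits.loc[fits["tested"], "p"].notna().all()
        assert (fits["cell_line"] == "lineA").all()

    def test_low_coverage_site_not_tested(self, line_sim):
        fits = fit_sites_per_line(
            line_sim.native["a"], line_sim.sample_sheet, "lineA",
            SiteModelConfig(min_mean_reads=1e9),
        )
        assert not fits["tested"].any()

    def test_unknown_line_rejected(self, line_sim):
        with pytest.raises(ValueError):
            fit_sites_per_line(line_sim.native["a"], line_sim.sample_sheet, "nope")

    def test_outlier_replicate_inflates_pruning_rate(self):
        sim = simulate_experiment(
            SimConfig(
                seed=5,
                n_sites=400,
                depth_mean=100.0,
                depth_dispersion=None,
                frac_dms=1.0,
                frac_ivt_artifact=0.0,
                frac_line_heterogeneous=0.0,
                outlier_replicates={"lineA": (2,), "lineB": ()},
            )
        )
        fits = fit_sites_per_line(sim.native["a"], sim.sample_sheet, "lineA")
        tested = fits[fits["tested"] & fits["converged"]]
        clean = fit_sites_per_line(sim.native["a"], sim.sample_sheet, "lineB")
        tested_clean = clean[clean["tested"] & clean["converged"]]
        # swapped replicate drives the fit at many sites -> pruning fires
        # far more often than in the clean line
        assert tested["pruned"].mean() > 0.25
        assert tested_clean["pruned"].mean() < 0.2
        assert tested["pruned"].mean() > 2 * tested_clean["pruned"].mean()
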