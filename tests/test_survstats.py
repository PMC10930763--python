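"""Cox fitting, proportional-hazards diagnostics, multiple-testing
correction, concordance, log-rank, Kaplan-Meier, and the exact 1-D
two-cluster cutoff — each checked against independent brute-force oracles
on small data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import histomark as hm
from histomark import survstats
from histomark.survstats import (
    bh_adjust,
    concordance_index,
    fit_cox,
    km_estimate,
    kmeans2_cutoff,
    logrank_test,
    ph_test,
    stratify,
)
from histomark.synthetic import CohortConfig, generate_expression, generate_survival, survival_design

from oracles import (
    bh_stepup,
    breslow_negloglik,
    harrell_c,
    km_curve,
    kmeans2_exhaustive,
    logrank_statistic,
)


class TestFitCox:
    def test_null_covariate_gives_zero_beta_unit_hr(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        fit = fit_cox(t, e, np.zeros((5, 1)))
        assert fit.coef[0] == 0.0 and fit.hr[0] == 1.0

    def test_requires_events_and_finite_covariates(self):
        t = np.array([1.0, 2, 3])
        with pytest.raises(ValueError):
            fit_cox(t, np.zeros(3), np.ones((3, 1)))
        with pytest.raises(ValueError):
            fit_cox(t, np.array([1, 0, 1]), np.array([[1.0], [np.nan], [0.0]]))

    def test_loglik_matches_brute_force_at_fitted_beta(self):
        rng = np.random.default_rng(0)
        for n in (5, 6, 7, 8):
            for _ in range(10):
                x = rng.normal(size=(n, 1))
                t = np.round(rng.exponential(np.exp(-0.5 * x[:, 0])), 1) + 0.1
                e = (rng.uniform(size=n) < 0.8).astype(int)
                if e.sum() == 0:
                    e[0] = 1
                fit = fit_cox(t, e, x)
                if fit.separation_flag:
                    continue  # monotone likelihood: no finite optimum to compare
                oracle = -breslow_negloglik(t, e, x[:, 0] * fit.coef[0]) * e.sum()
                np.testing.assert_allclose(fit.loglik, oracle, atol=1e-9)

    def test_fitted_beta_maximizes_brute_force_likelihood(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 1))
        t = rng.exponential(np.exp(-x[:, 0]))
        e = np.ones(8, dtype=int)
        fit = fit_cox(t, e, x)
        best = -breslow_negloglik(t, e, x[:, 0] * fit.coef[0])
        for db in (-0.05, 0.05):
            assert -breslow_negloglik(t, e, x[:, 0] * (fit.coef[0] + db)) <= best + 1e-12

    def test_planted_beta_recovered_at_n2000(self):
        cfg = CohortConfig(n_samples=2000, n_genes=1, seed=13,
                           cox_coefficients=(1.0, 0.2, 0.1, 0.3))
        expr = generate_expression(cfg)
        clin = generate_survival(expr, None, cfg)
        x, names = survival_design(expr, clin)
        fit = fit_cox(clin["os_months"], clin["os_event"], x, names)
        assert 0.9 <= fit.coef[0] <= 1.1
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]

    def test_reproducible_to_1e6(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 2))
        t = rng.exponential(np.exp(-x[:, 0]))
        e = (rng.uniform(size=60) < 0.7).astype(int)
        f1 = fit_cox(t, e, x)
        f2 = fit_cox(t, e, x)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-6)


class TestPHTest:
    def test_pvalues_in_unit_interval_and_min_events(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 2))
        t = rng.exponential(np.exp(-x[:, 0]))
        e = (rng.uniform(size=80) < 0.7).astype(int)
        res = ph_test(t, e, x)
        assert ((res.p >= 0) & (res.p <= 1)).all()
        with pytest.raises(ValueError):
            ph_test(t[:4], np.array([1, 1, 0, 0]), x[:4])

    def test_detects_planted_time_varying_effect(self):
        # effect reverses sign at the median time: strong PH violation
        rng = np.random.default_rng(4)
        n, hits = 500, 0
        reps = 20
        for rep in range(reps):
            x = rng.normal(size=(n, 1))
            u = rng.uniform(size=n)
            # piecewise hazard: beta=+1.5 early, -1.5 late
            t_early = rng.exponential(np.exp(-1.5 * x[:, 0]))
            t_late = 1.0 + rng.exponential(np.exp(1.5 * x[:, 0]))
            t = np.where(t_early < 1.0, t_early, t_late)
            e = np.ones(n, dtype=int)
            res = ph_test(t, e, x)
            hits += res.p[0] < 0.05
        assert hits / reps >= 0.5


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_trivial_cases(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_direct_stepup_and_never_decreases(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_stepup(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        # order preservation: adjustment is monotone in the raw p-values
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestConcordance:
    def test_perfect_and_uninformative_scores(self):
        t = np.array([5.0, 4, 3, 2, 1])
        e = np.ones(5, dtype=int)
        assert concordance_index(t, e, np.arange(5.0)) == 1.0
        assert concordance_index(t, e, np.zeros(5)) == 0.5

    def test_matches_pair_enumeration_with_censoring(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = 50
            t = np.round(rng.exponential(size=n), 2) + 0.01
            e = (rng.uniform(size=n) < 0.6).astype(int)
            r = np.round(rng.normal(size=n), 1)  # induce score ties
            if e.sum() == 0:
                e[0] = 1
            assert concordance_index(t, e, r) == pytest.approx(
                harrell_c(t, e, r), abs=1e-12
            )

    def test_no_admissible_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestLogrankKM:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([1.0, 2, 3, 4] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.repeat([0, 1], 4)
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_tables_and_symmetry(self):
        t = np.array([1.0, 3.0, 2.0, 4.0])
        e = np.array([1, 1, 1, 0])
        g = np.array([0, 0, 1, 1])
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(8 / 13, abs=1e-9)
        assert stat == pytest.approx(logrank_statistic(t, e, g), abs=1e-12)
        stat_swapped, _ = logrank_test(t, e, 1 - g)
        assert stat_swapped == pytest.approx(stat, abs=1e-12)
        with pytest.raises(ValueError):
            logrank_test(t, e, np.zeros(4))

    def test_km_uncensored_and_all_censored(self):
        t = np.array([1.0, 2, 3, 4])
        times, surv = km_estimate(t, np.ones(4, int))
        np.testing.assert_allclose(surv[np.searchsorted(times, t)], [0.75, 0.5, 0.25, 0.0])
        _, flat = km_estimate(t, np.zeros(4, int))
        np.testing.assert_allclose(flat, 1.0)

    def test_km_matches_hand_product_limit_with_censoring(self):
        t = np.array([1.0, 2, 2, 3, 4])
        e = np.array([1, 0, 1, 1, 0])
        times, surv = km_estimate(t, e)
        ot, os_ = km_curve(t, e)
        drop_vals = surv[np.searchsorted(times, ot)]
        np.testing.assert_allclose(drop_vals, os_, atol=1e-12)


class TestKMeansCutoff:
    def test_symmetric_clusters(self):
        cutoff, labels = kmeans2_cutoff([0, 0, 0, 10, 10, 10])
        assert cutoff == 5.0
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1])

    def test_three_point_example(self):
        cutoff, _ = kmeans2_cutoff([1.0, 2.0, 9.0])
        assert cutoff == pytest.approx((1.5 + 9) / 2)

    def test_order_invariance_and_constant_rejection(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=30)
        c1, l1 = kmeans2_cutoff(v)
        perm = rng.permutation(30)
        c2, l2 = kmeans2_cutoff(v[perm])
        assert c1 == c2
        np.testing.assert_array_equal(l1[perm], l2)
        with pytest.raises(ValueError):
            kmeans2_cutoff(np.full(5, 3.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=30).filter(
        lambda v: len(set(v)) >= 2))
    def test_matches_exhaustive_split_enumeration(self, values):
        cutoff, _ = kmeans2_cutoff(np.array(values, dtype=float))
        assert cutoff == pytest.approx(kmeans2_exhaustive(values), abs=1e-9)


@pytest.fixture(scope="module")
def harmful_gene_cohort():
    cfg = CohortConfig(n_samples=300, n_genes=1, seed=15,
                       cox_coefficients=(1.2, 0.2, 0.1, 0.3))
    expr = generate_expression(cfg)
    clin = generate_survival(expr, None, cfg)
    return expr, clin


class TestStratify:
    def test_harmful_gene_yields_hr_above_one(self, harmful_gene_cohort):
        expr, clin = harmful_gene_cohort
        res = stratify(expr.values[0], clin, gene=expr.genes[0])
        assert res.hr > 1.0
        assert res.labels.sum() > 0 and res.labels.sum() < len(clin)
        assert 0 <= res.logrank_p <= 1
        assert 0.5 < res.cindex <= 1.0

    def test_group_flip_inverts_hazard_ratio(self, harmful_gene_cohort):
        expr, clin = harmful_gene_cohort
        res = stratify(expr.values[0], clin)
        flipped = stratify(-expr.values[0], clin)
        assert flipped.hr == pytest.approx(1 / res.hr, rel=1e-4)

    def test_same_code_path_for_real_and_predicted(self, harmful_gene_cohort):
        expr, clin = harmful_gene_cohort
        noisy = expr.values[0] + np.random.default_rng(7).normal(
            0, 0.05 * expr.values[0].std(), size=len(clin)
        )
        from histomark.pipeline import stratify_real_vs_predicted

        out = stratify_real_vs_predicted("G000", expr.values[0], noisy, clin)
        assert out["delta_cindex"] == pytest.approx(
            out["predicted"].cindex - out["real"].cindex
        )
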