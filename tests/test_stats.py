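import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibconn.session import build_session
from fibconn.simulate import BehaviorParams, sample_cohort, simulate_behavior
from fibconn.stats import (
    ModelSpec,
    SmoothSpec,
    build_design,
    compare_models,
    evaluate_smooth,
    fdr_correct,
    fit_behavior_models,
    fit_penalized,
    iqr_outlier_screen,
    smooth_peak,
)
from fibconn.stats import test_smooths as smooth_block_tests

from conftest import make_edge_table

BUMP_EDGE = "left_central->right_parietal"


def bump_table(cohort, height=0.05, center=10.0, width=1.5, noise=0.002, seed=0):
    rng = np.random.default_rng(seed)

    def gc(p, a, b):
        base = 0.01 + noise * rng.standard_normal()
        if f"{a}->{b}" == BUMP_EDGE:
            base += height * np.exp(-((p.lsbq - center) ** 2) / (2 * width**2))
        return base

    return make_edge_table(cohort, gc)


class TestDesign:
    def test_dimensions(self, null_edge_table):
        design = build_design(null_edge_table)
        # 56 smooths x 14 constrained basis functions
        smooth_cols = sum(
            len(idx) for t, idx in design.blocks.items() if t.startswith("s(")
        )
        assert smooth_cols == 56 * 14
        assert len(design.smooth_levels) == 56
        assert design.n_obs == 28 * 56

    def test_missing_covariate_reported(self, null_edge_table):
        broken = null_edge_table.copy()
        broken.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="missing covariate"):
            build_design(broken)

    def test_smooth_contributions_sum_to_zero(self, null_edge_table):
        design = build_design(null_edge_table)
        fit = fit_penalized(design)
        for level in design.smooth_levels[:5]:
            idx = design.blocks[f"s({level})"]
            contrib = design.X[:, idx] @ fit.beta[idx]
            assert abs(contrib.sum()) < 1e-8

    def test_zero_penalty_reduces_to_unpenalized_ls(self, cohort28):
        table = bump_table(cohort28)
        spec = ModelSpec(
            smooth=SmoothSpec(penalty=0.0), random_effects=(), covariates=("age",)
        )
        design = build_design(table, spec)
        fit = fit_penalized(design)
        beta_ls, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        np.testing.assert_allclose(design.X @ fit.beta, design.X @ beta_ls, atol=1e-6)

    def test_doubling_data_equals_halving_penalty(self, cohort28):
        table = bump_table(cohort28)
        doubled = pd.concat([table, table], ignore_index=True)
        spec_half = ModelSpec(smooth=SmoothSpec(penalty=0.01), re_penalty=0.5)
        spec_full = ModelSpec(smooth=SmoothSpec(penalty=0.02), re_penalty=1.0)
        fit_d = fit_penalized(build_design(doubled, spec_full))
        fit_s = fit_penalized(build_design(table, spec_half))
        np.testing.assert_allclose(fit_d.beta, fit_s.beta, atol=1e-8)

    def test_edf_monotone_in_penalty(self, null_edge_table):
        edfs = []
        for lam in (0.002, 0.02, 0.2, 2.0, 200.0):
            design = build_design(null_edge_table, ModelSpec(smooth=SmoothSpec(penalty=lam)))
            fit = fit_penalized(design)
            edfs.append(fit.edf[f"s({BUMP_EDGE})"])
        assert all(a > b for a, b in zip(edfs, edfs[1:]))
        # a huge penalty collapses each smooth toward its (linear) null space
        assert edfs[-1] < 2.0


class TestSmoothTests:
    def test_constant_response_gives_p_one(self, null_edge_table):
        design = build_design(null_edge_table)
        fit = fit_penalized(design, y=np.full(design.n_obs, 0.01))
        res = smooth_block_tests(fit, method="analytic")
        assert (res.p_value > 0.99).all()

    def test_zeroed_smooth_coefficients_give_p_one(self, null_edge_table):
        design = build_design(null_edge_table)
        rng = np.random.default_rng(3)
        fit = fit_penalized(design, y=rng.standard_normal(design.n_obs))
        fit.beta = np.zeros_like(fit.beta)
        fit.fitted = np.zeros_like(fit.fitted)
        for method in ("analytic", "bootstrap"):
            res = smooth_block_tests(fit, method=method, n_boot=200)
            assert (res.p_value > 0.99).all()

    def test_bump_detected_and_localized(self, cohort28):
        design = build_design(bump_table(cohort28, seed=1))
        fit = fit_penalized(design)
        res = smooth_block_tests(fit, method="bootstrap", n_boot=2000, seed=0)
        _, rej = fdr_correct(res.p_value)
        flagged = set(res.connection[rej])
        assert flagged == {BUMP_EDGE}
        assert smooth_peak(fit, BUMP_EDGE) == pytest.approx(10.0, abs=1.0)

    def test_gaussian_null_type_i_error(self, null_edge_table):
        design = build_design(null_edge_table)
        rng = np.random.default_rng(0)
        hits = []
        for _ in range(60):
            fit = fit_penalized(design, y=rng.standard_normal(design.n_obs))
            res = smooth_block_tests(fit, method="analytic")
            hits.append((res.p_value < 0.05).mean())
        assert np.mean(hits) == pytest.approx(0.05, abs=0.025)

    def test_evaluate_smooth_shape(self, cohort28):
        design = build_design(bump_table(cohort28, seed=2))
        fit = fit_penalized(design)
        grid, vals = evaluate_smooth(fit, BUMP_EDGE)
        assert grid.shape == vals.shape
        assert grid.min() >= design.xrange[0] and grid.max() <= design.xrange[1]


class TestFdr:
    def test_worked_example(self):
        # brute-force BH: p(i) * m / i with monotone enforcement
        p = [0.001, 0.01, 0.02, 0.2]
        adj, rej = fdr_correct(p, q=0.05)
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.0267, 0.2], atol=1e-4)
        assert list(rej) == [True, True, True, False]

    def test_equal_pvalues_unchanged(self):
        adj, _ = fdr_correct([0.03] * 7)
        np.testing.assert_allclose(adj, 0.03)

    def test_empty_input(self):
        adj, rej = fdr_correct([])
        assert adj.size == 0 and rej.size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    def test_adjusted_at_least_raw(self, pvals):
        adj, _ = fdr_correct(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()


class TestCompareModels:
    def _fits(self, cohort, effect, seed=0):
        rng = np.random.default_rng(seed)

        def gc(p, a, b):
            y = 0.01 + 0.002 * rng.standard_normal()
            if effect and p.gender == "male":
                y += 0.004
            return y

        table = make_edge_table(cohort, gc)
        reduced = ModelSpec(covariates=("age", "l2_aoa", "education"))
        full = ModelSpec(covariates=("age", "l2_aoa", "education", "gender"))
        fr = fit_penalized(build_design(table, reduced))
        ff = fit_penalized(build_design(table, full))
        return fr, ff

    def test_identical_models_zero_deltas(self, cohort28):
        fr, _ = self._fits(cohort28, effect=False)
        rep = compare_models(fr, fr)
        assert rep["deviance_delta"] == 0.0
        assert rep["aic_delta"] == 0.0
        assert rep["preferred"] == "reduced"

    def test_true_covariate_prefers_full(self, cohort28):
        fr, ff = self._fits(cohort28, effect=True)
        rep = compare_models(fr, ff)
        assert rep["p_value"] < 0.05
        assert rep["aic_delta"] < 0
        assert rep["preferred"] == "full"

    def test_noise_covariate_prefers_reduced_in_majority(self, cohort28):
        wins = 0
        for seed in range(5):
            fr, ff = self._fits(cohort28, effect=False, seed=seed)
            rep = compare_models(fr, ff)
            wins += rep["aic_delta"] > 0
        assert wins >= 3

    def test_non_nested_rejected(self, cohort28):
        fr, ff = self._fits(cohort28, effect=False)
        with pytest.raises(ValueError):
            compare_models(ff, fr)


class TestIqrScreen:
    def test_worked_example(self):
        values = list(range(1, 11)) + [100]
        flags = iqr_outlier_screen(values)
        assert flags[-1]
        assert not flags[:-1].any()

    def test_tight_cluster_clean(self):
        assert not iqr_outlier_screen([5.0, 5.1, 4.9, 5.05, 4.95]).any()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            iqr_outlier_screen([1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=4, max_size=20
        ),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance(self, values, a, b):
        before = iqr_outlier_screen(values)
        after = iqr_outlier_screen([a * v + b for v in values])
        np.testing.assert_array_equal(before, after)


class TestBehaviorModels:
    def test_reports_levels_and_terms(self):
        cohort = sample_cohort(10, seed=0)
        session = build_session(seed=0)
        beh = simulate_behavior(cohort, session, BehaviorParams(), seed=1)
        models = fit_behavior_models(beh)
        assert set(models) == {0, 1, 2, 3, 4}
        for table in models.values():
            assert {"block", "lsbq_c", "block:lsbq_c"} <= set(table.term)

    def test_null_generator_recovers_null(self):
        cohort = sample_cohort(12, seed=1)
        session = build_session(seed=0)
        params = BehaviorParams(
            block_rt_change_ms=0.0,
            lsbq_rt_offset_ms=0.0,
            lsbq_slope_flattening_ms={},
            level_slowing_ms=0.0,
            noise_sigma=0.05,
        )
        beh = simulate_behavior(cohort, session, params, seed=2)
        models = fit_behavior_models(beh)
        t0 = models[0].set_index("term")
        for term in ("block", "lsbq_c", "block:lsbq_c"):
            assert abs(t0.loc[term, "coef"]) < 3 * t0.loc[term, "se"] + 1e-9
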