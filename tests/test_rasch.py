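import numpy as np
import pandas as pd
import pytest

import explirt as ex
from explirt.items import ITEMS, ResponseTable
from _oracle import trapezoid_loglik, trapezoid_prevalence

FINE_RULE = ex.QuadratureRule.gauss_hermite(201)


class TestLogistic:
    def test_midpoint(self):
        assert ex.logistic(0.0) == 0.5

    def test_symmetry(self):
        assert ex.logistic(2.58) + ex.logistic(-2.58) == pytest.approx(1.0, abs=1e-12)

    def test_direct_value(self):
        assert ex.logistic(1.879) == pytest.approx(1 / (1 + np.exp(-1.879)), abs=1e-12)
        assert ex.logistic(1.879) == pytest.approx(0.8675, abs=5e-5)

    def test_extreme_arguments_stable(self):
        assert ex.logistic(700.0) == 1.0
        assert ex.logistic(-700.0) == pytest.approx(0.0, abs=1e-300)


def _single_cell(response: int) -> ResponseTable:
    return ResponseTable(pd.DataFrame({
        "person_id": ["a"], "item_id": ["Larger"], "response": [response]}))


class TestMarginalLoglik:
    def test_degenerate_limit_single_cell(self):
        ll = ex.marginal_loglik(_single_cell(1), np.zeros(11), person_sd=1e-6)
        assert ll == pytest.approx(np.log(0.5), abs=1e-8)

    def test_additivity_duplicated_persons(self, null_dataset):
        rt = null_dataset.responses
        eas = np.linspace(-1, 2.5, 11)
        ll1 = ex.marginal_loglik(rt, eas, 1.4)
        doubled = pd.concat([
            rt.data, rt.data.assign(person_id="dup_" + rt.data["person_id"])])
        ll2 = ex.marginal_loglik(ResponseTable(doubled.reset_index(drop=True)), eas, 1.4)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_empty_errors(self):
        empty = ResponseTable(pd.DataFrame(columns=["person_id", "item_id", "response"]))
        with pytest.raises(ValueError, match="empty"):
            ex.marginal_loglik(empty, np.zeros(11), 1.0)

    def test_invariant_to_person_order_and_layout(self, tmp_path, null_dataset):
        rt = null_dataset.responses
        eas = np.linspace(2.4, -0.6, 11)
        ll = ex.marginal_loglik(rt, eas, 1.6)
        shuffled = rt.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        ll_shuffled = ex.marginal_loglik(ResponseTable(shuffled), eas, 1.6)
        assert ll_shuffled == pytest.approx(ll, rel=1e-12)
        for layout in ("wide", "long"):
            path = tmp_path / f"r.{layout}.csv"
            ex.write_responses(rt, path, layout=layout)
            ll_io = ex.marginal_loglik(ex.load_responses(path, layout=layout), eas, 1.6)
            assert ll_io == pytest.approx(ll, rel=1e-12)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(2, 13))
            ds = ex.simulate_dataset(
                ex.null_config(n_persons=n, seed=int(rng.integers(0, 2**31))))
            eas = rng.normal(1.5, 1.0, 11)
            sd = float(rng.uniform(0.3, 2.5))
            gh = ex.marginal_loglik(ds.responses, eas, sd, rule=FINE_RULE)
            assert gh == pytest.approx(
                trapezoid_loglik(ds.responses, eas, sd), abs=1e-6)


class TestMarginalPrevalence:
    def test_zero_sd_collapses_to_logistic(self):
        assert ex.marginal_prevalence(0.7, 0.0) == pytest.approx(ex.logistic(0.7), abs=1e-15)

    def test_against_dense_grid(self):
        val = ex.marginal_prevalence(2.58, 1.60)
        assert val == pytest.approx(trapezoid_prevalence(2.58, 1.60), abs=1e-6)
        assert 0.86 < val < 0.88

    def test_antisymmetry(self):
        for e in (0.3, 1.2, 2.58):
            total = ex.marginal_prevalence(e, 1.6) + ex.marginal_prevalence(-e, 1.6)
            assert total == pytest.approx(1.0, abs=1e-10)


class TestRaschFit:
    def test_all_same_response_item_errors(self):
        ds = ex.simulate_dataset(ex.null_config(n_persons=50, seed=21))
        wide = ds.responses.to_wide().copy()
        wide["Social"] = 1
        rt = ResponseTable.from_wide(wide.reset_index())
        with pytest.raises(ValueError, match="Social"):
            ex.RaschModel(rt).fit()

    def test_item_relabeling_permutes_estimates(self, null_dataset, rasch_fit):
        wide = null_dataset.responses.to_wide().copy()
        swapped = wide.rename(columns={"Larger": "Craving", "Craving": "Larger"})
        fit2 = ex.RaschModel(ResponseTable.from_wide(swapped.reset_index())).fit()
        assert fit2.severity["Craving"] == pytest.approx(rasch_fit.severity["Larger"], abs=1e-5)
        assert fit2.severity["Larger"] == pytest.approx(rasch_fit.severity["Craving"], abs=1e-5)

    def test_score_equation_at_optimum(self, null_dataset, rasch_fit):
        obs = null_dataset.responses.to_wide().mean()
        post = rasch_fit.implied_prevalence(kind="posterior")
        assert np.allclose(post.to_numpy(), obs.to_numpy(), atol=1e-6)
        marg = rasch_fit.implied_prevalence(kind="marginal")
        assert np.allclose(marg.to_numpy(), obs.to_numpy(), atol=0.005)

    def test_quadrature_stability_default_vs_refined(self, null_dataset, rasch_fit):
        # refining the shipped 41-node rule must leave the optimum in place
        f61 = ex.RaschModel(null_dataset.responses,
                            quadrature=ex.QuadratureRule.gauss_hermite(61)).fit(compute_se=False)
        assert np.max(np.abs(rasch_fit._x - f61._x)) < 1e-3
        f21 = ex.RaschModel(null_dataset.responses,
                            quadrature=ex.QuadratureRule.gauss_hermite(21)).fit(compute_se=False)
        assert np.max(np.abs(f21._x - f61._x)) < 5e-3

    def test_recovery_unbiased_over_seeds(self):
        errors = []
        for seed in range(20):
            ds = ex.simulate_dataset(ex.null_config(n_persons=2000, seed=seed))
            fit = ex.RaschModel(ds.responses).fit(compute_se=False)
            errors.append([fit.severity[it] - ex.DEFAULT_SEVERITIES[it] for it in ITEMS])
        mean_err = np.mean(errors, axis=0)
        # pooled bias near zero; per-item averages within Monte Carlo spread
        assert abs(mean_err.mean()) < 0.03
        assert np.all(np.abs(mean_err) < 0.10)


class TestEapScores:
    def test_person_without_data_gets_prior(self, null_dataset, rasch_fit):
        rt = null_dataset.responses
        with_ghost = ResponseTable(rt.data.copy(),
                                   persons=rt.persons.append(pd.Index(["ghost"])))
        scores = ex.eap_scores(with_ghost, rasch_fit)
        assert scores.loc["ghost", "eap"] == 0.0
        assert scores.loc["ghost", "psd"] == pytest.approx(rasch_fit.person_sd)

    def test_extreme_patterns_sign(self, rasch_fit):
        ones = ResponseTable(pd.DataFrame({
            "person_id": "hi", "item_id": list(ITEMS), "response": 1}))
        zeros = ResponseTable(pd.DataFrame({
            "person_id": "lo", "item_id": list(ITEMS), "response": 0}))
        assert ex.eap_scores(ones, rasch_fit)["eap"].iloc[0] > 0
        assert ex.eap_scores(zeros, rasch_fit)["eap"].iloc[0] < 0

    def test_shrinkage_below_fitted_variance(self, rasch_fit):
        eap = rasch_fit.eap_scores()["eap"]
        assert eap.var(ddof=1) < rasch_fit.person_var


class TestIccCurve:
    def test_half_probability_at_severity(self, rasch_fit):
        sev = float(rasch_fit.severity["Craving"])
        assert ex.icc_curve(rasch_fit, "Craving", np.array([sev]))[0] == pytest.approx(0.5)

    def test_strictly_increasing(self, rasch_fit):
        curve = ex.icc_curve(rasch_fit, "Social", np.linspace(-5, 5, 101))
        assert np.all(np.diff(curve) > 0)

    def test_uniform_dif_shift_orders_curves(self, rasch_fit):
        grid = np.linspace(-5, 5, 101)
        male = ex.icc_curve(rasch_fit, "Withdrawal", grid)
        # easiness-scale DIF of -1.23 for women = severity shift +1.23
        female = ex.icc_curve(rasch_fit, "Withdrawal", grid, dif_shift=1.23)
        assert np.all(female < male)

    def test_unknown_item(self, rasch_fit):
        with pytest.raises(KeyError):
            ex.icc_curve(rasch_fit, "Nope", np.array([0.0]))
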