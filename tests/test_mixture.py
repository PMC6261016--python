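import numpy as np
import pandas as pd
import pytest

from _oracles import marginal_loglik_riemann
from conftest import make_matrix
from mdirt.cohort_io import DiagnosisMatrix
from mdirt.mixture import (
    MixtureRaschModel,
    ModelFit,
    assign_classes,
    compute_fit,
    fit_mixture,
    marginal_loglik,
    pattern_probability,
    response_probability,
    select_classes,
)
from mdirt.synthetic import generate_cohort, preset_scenario


class TestResponseProbability:
    @pytest.mark.parametrize("a", [0.5, 1.0, 1.7, 3.0])
    @pytest.mark.parametrize("loc", [-2.0, 0.0, 1.3])
    def test_half_at_item_location(self, a, loc):
        assert response_probability(loc, loc, a) == 0.5

    def test_logistic_closed_form(self):
        assert response_probability(np.log(3), 0.0, 1.0) == pytest.approx(0.75)

    def test_limits_and_stability(self):
        assert response_probability(500.0, 0.0, 1.7) == 1.0
        assert response_probability(-500.0, 0.0, 1.7) == 0.0
        assert np.isfinite(response_probability(-412.0, 0.0, 1.7))

    def test_increasing_in_theta(self):
        grid = np.linspace(-5, 5, 101)
        p = response_probability(grid, 0.3, 1.7)
        assert (np.diff(p) > 0).all()

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            response_probability(0.0, 0.0, 0.0)


class TestPatternProbability:
    def test_two_item_half_half(self):
        assert pattern_probability([1, 0], 0.0, [0.0, 0.0], 1.0) == pytest.approx(0.25)

    def test_all_missing_is_empty_product(self):
        assert pattern_probability([np.nan, np.nan], 0.0, [0.0, 1.0]) == 1.0

    def test_matches_scalar_oracle(self):
        x, theta, beta, a = [1, 1, 0], 1.0, [0.0, 1.0, 2.0], 1.7
        expected = 1.0
        for xi, bi in zip(x, beta):
            p = response_probability(theta, bi, a)
            expected *= p if xi == 1 else 1 - p
        assert pattern_probability(x, theta, beta, a) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pattern_probability([1, 0], 0.0, [0.0])


@pytest.fixture
def toy_two_class_model():
    return MixtureRaschModel(
        n_classes=2,
        mixing=[0.6, 0.4],
        difficulties=[[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
        trait_means=[-0.5, 0.5],
        trait_sds=[1.0, 1.3],
        discrimination=1.7,
        item_names=["a", "b", "c"],
        n_quadrature=41,
    )


@pytest.fixture
def four_patterns():
    return make_matrix(
        [[1, 0, 0], [1, 1, 0], [0, 0, 1], [1, 1, 1]],
        conditions=["a", "b", "c"],
    )


class TestMarginalLoglik:
    def test_matches_dense_grid_oracle(self, toy_two_class_model, four_patterns):
        ll = marginal_loglik(four_patterns, toy_two_class_model)
        oracle = marginal_loglik_riemann(
            four_patterns.values,
            toy_two_class_model.mixing,
            toy_two_class_model.difficulties,
            toy_two_class_model.trait_means,
            toy_two_class_model.trait_sds,
            toy_two_class_model.discrimination,
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_duplicating_patients_doubles_loglik(self, toy_two_class_model, four_patterns):
        doubled = DiagnosisMatrix(
            pd.concat(
                [
                    four_patterns.data,
                    four_patterns.data.set_axis([f"{i}_dup" for i in four_patterns.patient_ids]),
                ]
            )
        )
        assert marginal_loglik(doubled, toy_two_class_model) == pytest.approx(
            2 * marginal_loglik(four_patterns, toy_two_class_model), rel=1e-12
        )

    def test_degenerate_sd_single_item(self):
        # sigma -> 0, beta = mu = 0: every response has probability 1/2
        model = MixtureRaschModel(
            n_classes=1,
            mixing=[1.0],
            difficulties=[[0.0]],
            trait_means=[0.0],
            trait_sds=[1e-12],
            discrimination=1.7,
            item_names=["a"],
        )
        m = make_matrix([[1], [0]], conditions=["a"])
        assert marginal_loglik(m, model) == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_empty_matrix_rejected(self, toy_two_class_model):
        empty = DiagnosisMatrix(pd.DataFrame(columns=["a", "b", "c"], dtype=float))
        with pytest.raises(ValueError, match="empty"):
            marginal_loglik(empty, toy_two_class_model)


class TestComputeFit:
    def test_published_style_bic_row(self, toy_two_class_model, four_patterns):
        fit = ModelFit(minus2LL=1_643_788.0, k=203, n=68_400)
        assert round(fit.bic) == 1_646_048

    def test_k_zero_gives_bic_equal_deviance(self):
        assert ModelFit(minus2LL=321.5, k=0, n=10).bic == 321.5

    def test_arithmetic(self):
        assert ModelFit(minus2LL=200.0, k=5, n=100).bic == pytest.approx(223.0259, abs=1e-3)

    def test_default_parameter_count(self, toy_two_class_model, four_patterns):
        fit = compute_fit(toy_two_class_model, four_patterns)
        # C=2, I=3: 2*(3-1) + 1 + 4 = 9
        assert fit.k == 9
        assert fit.n == 4

    def test_explicit_k_override(self, toy_two_class_model, four_patterns):
        assert compute_fit(toy_two_class_model, four_patterns, k=203).k == 203


class TestFitMixture:
    def test_single_class_difficulty_recovery(self):
        spec = preset_scenario("single_class")  # n=2000, I=10
        matrix, _ = generate_cohort(spec)
        model, fit, estimates = fit_mixture(matrix, 1, seed=0)
        rmse = np.sqrt(np.mean((model.difficulties[0] - np.array(spec.difficulties[0])) ** 2))
        assert rmse <= 0.15
        assert model.converged

    def test_em_loglik_monotone_every_iteration(self):
        spec = preset_scenario("two_class_easy", n_patients=600)
        matrix, _ = generate_cohort(spec)
        model, _, _ = fit_mixture(matrix, 2, seed=1, n_starts=2)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-7).all()

    def test_identifiability_constraints(self):
        spec = preset_scenario("two_class_easy", n_patients=800)
        matrix, _ = generate_cohort(spec)
        model, _, estimates = fit_mixture(matrix, 2, seed=2, n_starts=2)
        assert np.abs(model.difficulties.sum(axis=1)).max() < 1e-8
        assert (np.diff(model.mixing) <= 1e-12).all()  # sorted descending
        posts = np.array([e.posterior for e in estimates])
        assert np.allclose(posts.sum(axis=1), 1.0)

    def test_refit_is_deterministic(self):
        spec = preset_scenario("two_class_easy", n_patients=500)
        matrix, _ = generate_cohort(spec)
        m1, f1, _ = fit_mixture(matrix, 2, seed=3, n_starts=2)
        m2, f2, _ = fit_mixture(matrix, 2, seed=3, n_starts=2)
        assert f1.minus2LL == f2.minus2LL
        assert (m1.difficulties == m2.difficulties).all()

    def test_class_count_beyond_pattern_diversity_rejected(self):
        m = make_matrix([[1, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="patterns"):
            fit_mixture(m, 3)

    def test_missing_cells_ignorable(self):
        # adding an all-missing column leaves person likelihoods unchanged
        spec = preset_scenario("single_class", n_patients=300)
        matrix, _ = generate_cohort(spec)
        model, fit, _ = fit_mixture(matrix, 1, seed=4)
        with_missing = DiagnosisMatrix(
            matrix.data.assign(ghost=np.nan)
        )
        ll_aug = marginal_loglik(
            with_missing,
            MixtureRaschModel(
                n_classes=1,
                mixing=[1.0],
                difficulties=[list(model.difficulties[0]) + [0.0]],
                trait_means=model.trait_means,
                trait_sds=model.trait_sds,
                discrimination=model.discrimination,
                item_names=with_missing.condition_names,
                n_quadrature=model.n_quadrature,
            ),
        )
        assert ll_aug == pytest.approx(model.loglik, abs=1e-9)


class TestSelectClasses:
    def test_override_contract(self):
        spec = preset_scenario("two_class_easy", n_patients=800)
        matrix, _ = generate_cohort(spec)
        sel = select_classes(
            matrix, range(1, 3), override=1, seed=0, n_starts=2, max_iter=150, tol=1e-4
        )
        assert sel.chosen == 1
        assert list(sel.table.index) == [1, 2]  # full BIC table still reported

    def test_failed_candidates_recorded(self):
        m = make_matrix([[1, 0], [0, 1], [1, 1], [0, 0]])
        sel = select_classes(m, [1, 40], seed=0, n_starts=1)
        assert 40 in sel.errors
        assert sel.chosen == 1


class TestAssignClasses:
    def test_modal_is_argmax(self, toy_two_class_model, four_patterns):
        estimates = assign_classes(toy_two_class_model, four_patterns)
        for e in estimates:
            assert e.modal_class == int(np.argmax(e.posterior)) + 1

    def test_exact_tie_breaks_to_lowest_index(self):
        model = MixtureRaschModel(
            n_classes=2,
            mixing=[0.5, 0.5],
            difficulties=[[0.0, 0.0], [0.0, 0.0]],
            trait_means=[0.0, 0.0],
            trait_sds=[1.0, 1.0],
            discrimination=1.7,
            item_names=["a", "b"],
        )
        m = make_matrix([[1, 0]], conditions=["a", "b"])
        (e,) = assign_classes(model, m)
        assert e.posterior[0] == pytest.approx(0.5)
        assert e.modal_class == 1

    def test_two_class_assignment_accuracy(self):
        spec = preset_scenario("two_class_easy", n_patients=1000)
        matrix, truth = generate_cohort(spec)
        model, _, estimates = fit_mixture(matrix, 2, seed=5, n_starts=3)
        modal = np.array([e.modal_class for e in estimates])
        acc = max(
            (modal == truth.classes).mean(), ((3 - modal) == truth.classes).mean()
        )
        assert acc >= 0.9
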