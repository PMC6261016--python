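import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import guttman_brute, loevinger_brute
from conftest import make_matrix, simulate_1pl
from mdirt.cohort_io import DiagnosisMatrix
from mdirt.mokken import (
    ScalingError,
    check_monotonicity,
    guttman_errors,
    pairwise_H,
    person_fit_filter,
    prevalence_order,
    scale_H,
    select_scale_items,
)
from mdirt.synthetic import generate_cohort, preset_scenario


def perfect_guttman(n_items=4, reps=1):
    """Triangular response patterns: strictly cumulative, no errors."""
    rows = [[1] * k + [0] * (n_items - k) for k in range(n_items + 1)] * reps
    return make_matrix(rows, patients=[f"P{i}" for i in range(len(rows))])


class TestLoevingerH:
    def test_perfect_guttman_gives_H_one(self):
        m = perfect_guttman(4, reps=3)
        result = scale_H(m)
        assert result.H_scale == pytest.approx(1.0)
        defined = result.H_pair.to_numpy()
        assert np.nanmin(defined) == pytest.approx(1.0)

    def test_hand_crosstab_toy(self):
        # patterns (1,1),(1,0),(0,0),(0,1): F=1, E = 4*(2/4)*(2/4) = 1, H = 0
        m = make_matrix([[1, 1], [1, 0], [0, 0], [0, 1]], conditions=["i", "j"])
        assert scale_H(m).H_scale == pytest.approx(0.0)
        assert pairwise_H(m).loc["i", "j"] == pytest.approx(0.0)

    def test_independent_items_near_zero(self, rng):
        X = (rng.random((10_000, 2)) < 0.5).astype(float)
        m = DiagnosisMatrix(
            pd.DataFrame(X, index=[f"P{i}" for i in range(10_000)], columns=["a", "b"])
        )
        assert abs(pairwise_H(m).loc["a", "b"]) < 0.05

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n, I = int(r.integers(2, 7)), int(r.integers(2, 6))
        vals = r.choice([0.0, 1.0, np.nan], size=(n, I), p=[0.4, 0.5, 0.1])
        m = DiagnosisMatrix(
            pd.DataFrame(vals, index=[f"P{i}" for i in range(n)], columns=[f"c{j}" for j in range(I)])
        )
        order_names = prevalence_order(m)
        order_idx = [m.condition_names.index(c) for c in order_names]
        _, H_item_o, H_scale_o = loevinger_brute(vals, order_idx)
        result = scale_H(m)
        if np.isnan(H_scale_o):
            assert np.isnan(result.H_scale)
        else:
            assert result.H_scale == pytest.approx(H_scale_o, abs=1e-12)
        for j, c in enumerate(m.condition_names):
            if np.isnan(H_item_o[j]):
                assert np.isnan(result.H_item[c])
            else:
                assert result.H_item[c] == pytest.approx(H_item_o[j], abs=1e-12)

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            pairwise_H(make_matrix([[1]]))


class TestGuttmanErrors:
    def test_rarity_order_example(self):
        # items ordered (common, rare): lacking the common one while having
        # the rare one is exactly one error
        assert guttman_errors([0, 1]) == 1
        assert guttman_errors([1, 0]) == 0

    @pytest.mark.parametrize("pattern", [[0, 0, 0, 0], [1, 1, 1, 1]])
    def test_uniform_patterns_error_free(self, pattern):
        assert guttman_errors(pattern) == 0

    def test_alternating_pattern(self):
        assert guttman_errors([1, 0, 1, 0, 1]) == 3

    def test_missing_entries_skipped(self):
        base = [1.0, 0.0, 1.0]
        assert guttman_errors(base + [np.nan, np.nan]) == guttman_errors(base)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from([0.0, 1.0, float("nan")]), min_size=2, max_size=10
        )
    )
    def test_matches_pair_enumeration_property(self, pattern):
        v = np.array(pattern)
        assert guttman_errors(v) == guttman_brute(v, list(range(len(v))))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([0.0, 1.0]), min_size=2, max_size=8),
        st.integers(min_value=1, max_value=4),
    )
    def test_appending_missing_items_invariant(self, pattern, n_extra):
        base = np.array(pattern)
        extended = np.concatenate([base, np.full(n_extra, np.nan)])
        assert guttman_errors(extended) == guttman_errors(base)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_pair_enumeration(self, seed):
        r = np.random.default_rng(100 + seed)
        v = r.choice([0.0, 1.0, np.nan], size=r.integers(2, 8), p=[0.4, 0.5, 0.1])
        assert guttman_errors(v) == guttman_brute(v, list(range(len(v))))


class TestMonotonicity:
    def test_model_conforming_item_passes(self, rng):
        m = simulate_1pl(rng, 1500, np.linspace(-1, 1, 6))
        assert check_monotonicity(m, "i2").verdict == "ok"

    def test_null_rate_across_seeds(self):
        # a 1PL item should essentially never violate monotonicity
        violations = 0
        for seed in range(12):
            m = simulate_1pl(np.random.default_rng(400 + seed), 800, np.linspace(-1, 1, 5))
            violations += check_monotonicity(m, "i1").verdict == "violation"
        assert violations == 0

    def test_constructed_decreasing_item_flagged(self, rng):
        # item probability falls from 0.9 to 0.1 as the restscore grows
        others = simulate_1pl(rng, 3000, np.linspace(-1.5, 1.5, 6))
        rest = others.values.sum(axis=1)
        p_bad = np.where(rest >= np.median(rest), 0.1, 0.9)
        bad = (rng.random(3000) < p_bad).astype(float)
        m = DiagnosisMatrix(others.data.assign(bad=bad))
        assert check_monotonicity(m, "bad").verdict == "violation"

    def test_constant_item_ok(self, rng):
        others = simulate_1pl(rng, 500, [-0.5, 0.5])
        m = DiagnosisMatrix(others.data.assign(coin=(rng.random(500) < 0.5).astype(float)))
        assert check_monotonicity(m, "coin").verdict in ("ok", "indeterminate")

    def test_too_few_groups_indeterminate(self):
        m = make_matrix([[1, 0], [0, 1], [1, 1]])
        assert check_monotonicity(m, "c0", min_group_size=50).verdict == "indeterminate"


class TestSelectScaleItems:
    def test_model_conforming_items_all_retained(self):
        retained = 0
        for seed in range(5):
            m = simulate_1pl(np.random.default_rng(500 + seed), 1200, np.linspace(-1, 1, 6))
            result = select_scale_items(m)
            retained += len(result.selected_items) == 6
        assert retained >= 4

    def test_independent_coin_removed(self, rng):
        m = simulate_1pl(rng, 1500, np.linspace(-1, 1, 5))
        noisy = DiagnosisMatrix(m.data.assign(coin=(rng.random(1500) < 0.5).astype(float)))
        result = select_scale_items(noisy)
        assert "coin" not in result.selected_items
        assert set(result.selected_items) == set(m.condition_names)
        assert any(entry["item"] == "coin" for entry in result.audit)

    def test_two_items_retained_or_error(self, rng):
        good = simulate_1pl(rng, 800, [-0.5, 0.5])
        result = select_scale_items(good)
        assert len(result.selected_items) == 2
        coins = DiagnosisMatrix(
            pd.DataFrame(
                (np.random.default_rng(0).random((600, 2)) < 0.5).astype(float),
                index=[f"P{i}" for i in range(600)],
                columns=["x", "y"],
            )
        )
        with pytest.raises(ScalingError, match="descriptive"):
            select_scale_items(coins)

    def test_deterministic(self, rng):
        m = simulate_1pl(rng, 900, np.linspace(-1, 1, 5))
        r1 = select_scale_items(m)
        r2 = select_scale_items(m)
        assert r1.selected_items == r2.selected_items
        assert r1.H_scale == r2.H_scale


class TestPersonFitFilter:
    def test_exclusion_boundary(self):
        # ordered by prevalence: errors = 2 excluded, 1 retained at max_errors=1
        m = make_matrix(
            [
                [1, 1, 1, 0],  # 0 errors
                [0, 1, 1, 0],  # 2 errors (two more-common items missing... )
                [1, 0, 1, 0],  # 1 error
            ],
            patients=["clean", "bad", "ok"],
            conditions=["w", "x", "y", "z"],
        )
        # prevalence order: w(2/3) x(2/3) y(3/3) z(0) -> y, w, x, z
        order = ["y", "w", "x", "z"]
        filtered, fits, report = person_fit_filter(m, item_order=order, max_errors=1)
        by_id = {f.patient_id: f for f in fits}
        assert by_id["clean"].guttman_errors == 0
        assert by_id["bad"].guttman_errors == 1  # pattern (1,0,1,0) under order
        assert by_id["ok"].included

    def test_counts_and_retention(self):
        m = make_matrix(
            [[0, 1, 1], [1, 1, 0], [1, 0, 1]],
            patients=["two_err", "none", "one_err"],
            conditions=["common", "mid", "rare"],
        )
        # prevalence: mid 2/3, common 1/3, rare 2/3 -> order mid, rare, common
        filtered, fits, report = person_fit_filter(
            m, item_order=["common", "mid", "rare"], max_errors=1
        )
        by_id = {f.patient_id: f for f in fits}
        assert by_id["two_err"].guttman_errors == 2
        assert not by_id["two_err"].included
        assert by_id["one_err"].guttman_errors == 1
        assert by_id["one_err"].included
        assert filtered.patient_ids == ["none", "one_err"]
        assert report.parameters["retained_fraction"] == pytest.approx(2 / 3)

    def test_guttman_perfect_scenario_fully_retained(self):
        matrix, _ = generate_cohort(preset_scenario("guttman_perfect"))
        _, fits, report = person_fit_filter(matrix)
        assert report.parameters["retained_fraction"] == 1.0
        assert max(f.guttman_errors for f in fits) == 0

    def test_retained_fraction_stable_across_seeds(self):
        fractions = []
        for seed in range(5):
            m = simulate_1pl(
                np.random.default_rng(700 + seed), 2000, np.linspace(-1.5, 1.5, 8)
            )
            _, _, report = person_fit_filter(m)
            fractions.append(report.parameters["retained_fraction"])
        assert max(fractions) - min(fractions) <= 0.06  # +/-3% band
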