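"""Core matrix-model machinery: validation, eigen-quantities, metrics."""

import numpy as np
import pytest

from mpmrisk.mpm import (
    MPMError,
    age_at_maturity,
    age_schedules,
    compute_metrics,
    demetrius_entropy,
    eigen_analysis,
    elasticity_matrix,
    fundamental_matrix,
    generation_time,
    keyfitz_entropy,
    mature_life_expectancy,
    net_reproductive_rate,
    validate_model,
    vital_rate_means,
)

from conftest import random_models


class TestValidateModel:
    def test_reproductive_stages_from_positive_F_columns(self):
        m = validate_model([[0.2, 0], [0.3, 0.5]], [[0, 1.5], [0, 0]])
        assert m.reproductive_stages == (1,)
        assert m.has_fecundity

    @pytest.mark.parametrize(
        "U, F, match",
        [
            ([[0.7, 0], [0.5, 0.5]], [[0, 1], [0, 0]], "survival column"),
            ([[0.2, 0], [0.3, 0.5]], [[0, -0.1], [0, 0]], "negative"),
            ([[0.2]], [[0, 1], [0, 0]], "dimension"),
            ([[np.inf, 0], [0, 0]], [[0, 1], [0, 0]], "non-finite"),
        ],
    )
    def test_invalid_models_rejected(self, U, F, match):
        with pytest.raises(MPMError, match=match):
            validate_model(U, F)

    def test_zero_F_flagged_not_rejected(self):
        m = validate_model([[0.5]], [[0.0]])
        assert not m.has_fecundity


class TestEigenAnalysis:
    @pytest.mark.parametrize(
        "A, lam",
        [
            ([[0, 2], [0.5, 0]], 1.0),
            ([[0.2, 1.5], [0.3, 0.5]], (0.7 + np.sqrt(1.89)) / 2),
            ([[0.5, 0], [0, 0.2]], 0.5),
        ],
    )
    def test_dominant_eigenvalue(self, A, lam):
        assert eigen_analysis(A).lam == pytest.approx(lam, rel=1e-10)

    def test_eigenvector_normalization_and_residuals(self):
        A = np.array([[0.2, 1.5], [0.3, 0.5]])
        e = eigen_analysis(A)
        assert e.w.sum() == pytest.approx(1.0)
        assert e.v @ e.w == pytest.approx(1.0)
        assert np.allclose(A @ e.w, e.lam * e.w, rtol=1e-8)
        assert np.allclose(e.v @ A, e.lam * e.v, rtol=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(MPMError):
            eigen_analysis(np.zeros((2, 2)))


class TestFundamentalMatrix:
    def test_hand_inverse(self):
        N = fundamental_matrix([[0.2, 0.0], [0.3, 0.5]])
        assert np.allclose(N, [[1.25, 0.0], [0.75, 2.0]])

    def test_no_survival_gives_identity(self):
        assert np.allclose(fundamental_matrix(np.zeros((3, 3))), np.eye(3))

    def test_immortal_chain_rejected(self):
        with pytest.raises(MPMError, match="non-absorbing"):
            fundamental_matrix([[1.0]])


class TestReproductiveRates:
    def test_r0_toy(self, toy_model):
        assert net_reproductive_rate(toy_model.U, toy_model.F) == pytest.approx(1.125)

    def test_r0_zero_without_fecundity(self):
        assert net_reproductive_rate([[0.5]], [[0.0]]) == 0.0

    def test_r0_biennial(self, biennial_model):
        assert net_reproductive_rate(
            biennial_model.U, biennial_model.F
        ) == pytest.approx(1.5)

    def test_generation_time_toy(self, toy_model):
        lam = (0.7 + np.sqrt(1.89)) / 2
        expect = np.log(1.125) / np.log(lam)
        assert generation_time(toy_model.U, toy_model.F) == pytest.approx(expect)
        assert expect == pytest.approx(3.21, abs=0.005)

    def test_generation_time_biennial_exact(self, biennial_model):
        assert generation_time(
            biennial_model.U, biennial_model.F
        ) == pytest.approx(2.0, abs=1e-12)

    def test_lambda_one_gives_missing(self):
        # single stage, survival 0.5, fecundity 0.5: lambda = 1 exactly
        assert np.isnan(generation_time([[0.5]], [[0.5]]))

    def test_sign_agreement_lambda_r0(self):
        for m in random_models(40, seed=11):
            lam = eigen_analysis(m.A).lam
            r0 = net_reproductive_rate(m.U, m.F)
            if abs(lam - 1) > 1e-9:
                assert (lam - 1) * (r0 - 1) > 0


class TestAgeSchedules:
    def test_hand_iteration(self, toy_model):
        s = age_schedules(toy_model.U, toy_model.F)
        assert np.allclose(s.lx[:3], [1.0, 0.5, 0.25])
        assert s.mx[1] == pytest.approx(0.9)
        assert s.mx[2] == pytest.approx(1.26)

    def test_lx_non_increasing_and_independent_of_F(self):
        for m in random_models(15, seed=3):
            s = age_schedules(m.U, m.F)
            assert np.all(np.diff(s.lx) <= 1e-12)
            s0 = age_schedules(m.U, np.zeros_like(m.F))
            assert np.allclose(s.lx, s0.lx)

    def test_no_survival_truncates_immediately(self):
        s = age_schedules(np.zeros((2, 2)), np.zeros((2, 2)))
        assert list(s.lx) == [1.0]

    def test_invalid_arguments(self, toy_model):
        with pytest.raises(MPMError):
            age_schedules(toy_model.U, toy_model.F, horizon=0)
        with pytest.raises(MPMError):
            age_schedules(toy_model.U, toy_model.F, tol=0)


class TestMaturityMetrics:
    def test_toy_first_passage(self, toy_model):
        assert age_at_maturity(toy_model.U, {1}) == pytest.approx(1.25)

    def test_start_inside_reproductive_set(self, toy_model):
        assert age_at_maturity(toy_model.U, {1}, start=[0, 1]) == 0.0

    def test_deterministic_chain_single_step(self):
        assert age_at_maturity([[0.0, 0.0], [1.0, 0.0]], {1}) == pytest.approx(1.0)

    def test_unreachable_maturity_missing(self):
        # stage 2 unreachable from stage 1
        assert np.isnan(age_at_maturity([[0.5, 0.0], [0.0, 0.5]], {1}))

    def test_toy_mature_life_expectancy(self, toy_model):
        assert mature_life_expectancy(toy_model.U, {1}) == pytest.approx(2.0)

    def test_adult_stasis_geometric(self):
        # 1 / (1 - 0.8) = 5 years with adult stasis 0.8
        U = np.array([[0.0, 0.0], [0.5, 0.8]])
        assert mature_life_expectancy(U, {1}) == pytest.approx(5.0)

    def test_zero_adult_survival_entry_year_only(self):
        U = np.array([[0.0, 0.0], [0.5, 0.0]])
        assert mature_life_expectancy(U, {1}) == pytest.approx(1.0)


from mpmrisk.studies import simulate_trajectories  # noqa: E402


class TestMonteCarloOracle:
    @pytest.mark.parametrize("model_seed", [0, 1, 2])
    def test_first_passage_and_lifetime_match_simulation(self, model_seed):
        (m,) = random_models(1, seed=100 + model_seed)
        repro = m.reproductive_stages
        n = 100_000
        ages, lives = simulate_trajectories(m.U, repro, n, seed=model_seed)
        assert ages.size > 1000
        for value, sample in [
            (age_at_maturity(m.U, repro), ages),
            (mature_life_expectancy(m.U, repro), lives),
        ]:
            se = sample.std(ddof=1) / np.sqrt(sample.size)
            assert abs(value - sample.mean()) < 3 * se + 1e-9


class TestEntropies:
    def test_keyfitz_hand_value(self):
        assert keyfitz_entropy([1.0, 0.5]) == pytest.approx(0.23105, abs=1e-5)

    @pytest.mark.parametrize("lx", [[1.0], [1.0, 1.0]])
    def test_keyfitz_degenerate_zero(self, lx):
        assert keyfitz_entropy(lx) == pytest.approx(0.0)

    def test_keyfitz_empty_rejected(self):
        with pytest.raises(MPMError):
            keyfitz_entropy([])

    def test_demetrius_semelparous_zero(self):
        assert demetrius_entropy([1, 0.5, 0.25], [0, 2.0, 0]) == pytest.approx(0.0)

    def test_demetrius_two_equal_atoms(self):
        # lx*mx equal at two ages -> entropy ln 2
        assert demetrius_entropy(
            [1.0, 0.5], [1.0, 2.0]
        ) == pytest.approx(np.log(2))

    def test_demetrius_matches_brute_force(self, toy_model):
        s = age_schedules(toy_model.U, toy_model.F)
        net = s.lx * s.mx
        p = net[net > 0] / net.sum()
        brute = -(p * np.log(p)).sum()
        assert demetrius_entropy(s.lx, s.mx) == pytest.approx(brute, abs=1e-8)

    def test_demetrius_no_reproduction_missing(self):
        assert np.isnan(demetrius_entropy([1, 0.5], [0.0, 0.0]))


class TestVitalRateMeans:
    def test_hand_sums(self, toy_model):
        phi, gamma, rho = vital_rate_means(toy_model.U, toy_model.F)
        assert (phi, gamma, rho) == (0.75, 0.3, 0.0)

    def test_diagonal_U_no_growth(self):
        _, gamma, rho = vital_rate_means(np.diag([0.5, 0.6]), np.zeros((2, 2)))
        assert gamma == 0.0 and rho == 0.0

    def test_zero_F_zero_reproduction(self):
        phi, _, _ = vital_rate_means(np.diag([0.5, 0.6]), np.zeros((2, 2)))
        assert phi == 0.0


class TestElasticity:
    def test_normalization_over_many_random_models(self):
        for m in random_models(100, seed=5):
            E = elasticity_matrix(m.A)
            assert abs(E.sum() - 1.0) < 1e-10
            assert np.all(E[m.A == 0] == 0)

    def test_single_stage(self):
        assert np.allclose(elasticity_matrix([[0.9]]), [[1.0]])

    def test_matches_numerical_log_derivative(self):
        A = np.array([[0.2, 1.5], [0.3, 0.5]])
        E = elasticity_matrix(A)
        h = 1e-6
        for i in range(2):
            for j in range(2):
                if A[i, j] == 0:
                    continue
                Ap, Am = A.copy(), A.copy()
                Ap[i, j] *= 1 + h
                Am[i, j] *= 1 - h
                num = (
                    np.log(eigen_analysis(Ap).lam)
                    - np.log(eigen_analysis(Am).lam)
                ) / np.log((1 + h) / (1 - h))
                assert E[i, j] == pytest.approx(num, abs=1e-6)


class TestComputeMetrics:
    def test_toy_metric_values(self, toy_model):
        m = compute_metrics(toy_model).as_dict()
        assert m["age_at_maturity"] == pytest.approx(1.25)
        assert m["mature_life_expectancy"] == pytest.approx(2.0)
        assert m["net_reproductive_rate"] == pytest.approx(1.125)
        assert m["juvenile_survival"] == pytest.approx(0.5)
        assert m["adult_survival"] == pytest.approx(0.5)
        assert m["avg_fecundity"] == pytest.approx(3.0)

    def test_no_fecundity_all_missing(self):
        m = validate_model([[0.5, 0], [0.2, 0.6]], np.zeros((2, 2)))
        res = compute_metrics(m)
        assert np.isnan(res["generation_time"])
        assert "no fecundity" in res.missing_reasons["generation_time"]

    def test_clonal_switch_changes_recruitment_metrics(self):
        U = np.array([[0.2, 0.0], [0.3, 0.5]])
        F = np.array([[0.0, 1.0], [0.0, 0.0]])
        C = np.array([[0.0, 0.8], [0.0, 0.0]])
        m = validate_model(U, F, C)
        base = compute_metrics(m)
        with_c = compute_metrics(m, include_clonal_recruitment=True)
        assert with_c["mean_reproduction"] > base["mean_reproduction"]
        assert with_c["net_reproductive_rate"] > base["net_reproductive_rate"]
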