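import numpy as np
import pytest

from sunjoint import (
    ScenarioSpec,
    SplineBasis,
    build_basis,
    estimating_function_L,
    fit_andersen_gill,
    frailty_moments,
    generate_dataset,
    predict_trajectory,
    solve_extended,
)
from sunjoint.simulate import MU0_FORMS

from conftest import make_dataset


@pytest.fixture(scope="module")
def four_subject():
    ds = make_dataset([
        ("a", [0.0], 5.0, [0.5, 2.0], [1.4, 2.2]),
        ("b", [1.0], 5.0, [1.0, 2.5, 4.0], [3.1, 4.0, 6.5]),
        ("c", [0.0], 4.0, [1.5, 3.5], [1.1, 1.9]),
        ("d", [1.0], 3.0, [0.8, 2.2], [2.9, 3.3]),
    ])
    fit = fit_andersen_gill(ds)
    mom = frailty_moments(ds, fit)
    basis = build_basis(ds.arrays().t, degree=2, n_interior_knots=1,
                        boundary=(0.0, ds.tau))
    return ds, fit, mom, basis


class TestSplineBasis:
    def test_dimension_with_intercept_and_drop_one(self):
        # degree 3 + 4 interior knots: 8 raw columns; intercept + drop-one keeps K=8
        t = np.linspace(0.1, 9.9, 200)
        basis = build_basis(t, degree=3, n_interior_knots=4, boundary=(0.0, 10.0))
        assert basis.n_raw == 8
        assert basis.dimension == 8
        assert basis.design(t).shape == (200, 8)

    def test_partition_of_unity(self):
        t = np.linspace(0.0, 10.0, 57)
        basis = build_basis(t, degree=3, n_interior_knots=4, boundary=(0.0, 10.0))
        np.testing.assert_allclose(basis.raw_design(t).sum(axis=1), 1.0, atol=1e-12)

    def test_quantile_knot_rule(self):
        # interior knots at j/(k+1) quantiles with linear interpolation
        times = np.arange(1.0, 101.0)
        basis = build_basis(times, degree=3, n_interior_knots=4,
                            boundary=(0.0, 101.0))
        np.testing.assert_allclose(basis.interior_knots, [20.8, 40.6, 60.4, 80.2])

    def test_evaluation_outside_boundary_rejected(self):
        basis = build_basis(np.linspace(1, 9, 50), 3, 2, boundary=(0.0, 10.0))
        with pytest.raises(ValueError, match="boundary"):
            basis.design([10.5])

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValueError):
            build_basis(np.array([1.0, 1.0, 2.0]), 3, 4, boundary=(0.0, 3.0))


class TestEstimatingFunctionL:
    def test_zero_visits_gives_zero_vector(self):
        ds = make_dataset([("a", [0.0], 2.0, [], []), ("b", [1.0], 3.0, [], [])])
        from sunjoint.visits import FrailtyMoments, IntensityFit, StepFunction

        lam = StepFunction(np.array([3.0]), np.array([0.0]))
        fit = IntensityFit(gamma=np.zeros(1), Lambda0=lam, converged=True, iterations=0)
        mom = FrailtyMoments(omega=np.zeros(2), Omega=np.zeros(2), m=np.zeros(2, int))
        basis = SplineBasis(degree=0, interior_knots=np.empty(0), boundary=(0.0, 3.0))
        L = estimating_function_L(np.zeros(2), ds, fit, mom, basis)
        np.testing.assert_array_equal(L, np.zeros(2))

    def test_matches_brute_force_double_loop(self, four_subject):
        ds, fit, mom, basis = four_subject
        arr = ds.arrays()
        p, K = arr.p, basis.dimension
        for eta in (np.zeros(p + K), np.linspace(-0.2, 0.3, p + K)):
            total = np.zeros(p + K)
            for i, s in enumerate(ds.subjects):
                for t, y in zip(s.times, s.y):
                    Zi = np.concatenate([arr.X[i], basis.design([t])[0]])
                    num = np.zeros(p + K)
                    den = 0.0
                    for j in range(arr.n):
                        if arr.C[j] >= t:
                            Zj = np.concatenate([arr.X[j], basis.design([t])[0]])
                            eg = np.exp(arr.X[j] @ fit.gamma)
                            num += mom.Omega[j] * eg * Zj
                            den += mom.omega[j] * eg
                    total += Zi * y * np.exp(-(Zi @ eta)) - num / den
            L = estimating_function_L(eta, ds, fit, mom, basis)
            np.testing.assert_allclose(L, total, rtol=1e-12, atol=1e-10)

    def test_inner_sum_is_eta_free(self, four_subject):
        # L(eta1) - L(eta2) must equal the difference of the outcome terms
        # alone: the risk-set term S(t) cancels exactly, proving it does
        # not depend on eta
        ds, fit, mom, basis = four_subject
        arr = ds.arrays()
        p, K = arr.p, basis.dimension
        eta1 = np.zeros(p + K)
        eta2 = np.linspace(-0.5, 0.5, p + K)
        B = basis.design(arr.t)
        Z = np.column_stack([arr.X[arr.subject_index], B])
        outcome_diff = Z.T @ (arr.y * np.exp(-(Z @ eta1))) - Z.T @ (
            arr.y * np.exp(-(Z @ eta2)))
        L_diff = (estimating_function_L(eta1, ds, fit, mom, basis)
                  - estimating_function_L(eta2, ds, fit, mom, basis))
        np.testing.assert_allclose(L_diff, outcome_diff, rtol=1e-12)


class TestSolveExtended:
    def test_intercept_only_closed_form(self):
        # no covariates, constant basis: alpha = log(sum y / sum S(t))
        rng = np.random.default_rng(5)
        subs = []
        for i in range(30):
            C = rng.uniform(2.0, 5.0)
            times = np.sort(rng.uniform(0.0, C, rng.integers(1, 5)))
            y = rng.lognormal(0.5, 0.3, len(times))
            subs.append((f"s{i}", [], C, times, y))
        from sunjoint import LongitudinalDataset, Subject

        ds = LongitudinalDataset(
            [Subject(id=i, X=np.empty(0), C=C, times=t, y=y)
             for i, x, C, t, y in subs],
            tau=5.0, covariate_names=[])
        fit = fit_andersen_gill(ds)
        mom = frailty_moments(ds, fit)
        basis = SplineBasis(degree=0, interior_knots=np.empty(0), boundary=(0.0, 5.0))
        sol = solve_extended(ds, fit, mom, basis)
        arr = ds.arrays()
        # S(t) with Z == 1: Omega-weighted over omega-weighted risk sums
        S = np.array([
            mom.Omega[arr.C >= t].sum() / mom.omega[arr.C >= t].sum()
            for t in arr.t])
        closed = np.log(arr.y.sum() / S.sum())
        assert sol.alpha[0] == pytest.approx(closed, abs=1e-10)
        # and the same scalar root from bisection of L(alpha)
        def L1(a):
            return estimating_function_L(np.array([a]), ds, fit, mom, basis)[0]
        lo, hi = -5.0, 5.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if L1(lo) * L1(mid) > 0 else (lo, mid)
        assert sol.alpha[0] == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_converges_with_small_equation_norm(self, four_subject):
        ds, fit, mom, basis = four_subject
        sol = solve_extended(ds, fit, mom, basis)
        L = estimating_function_L(sol.eta, ds, fit, mom, basis)
        assert np.max(np.abs(L)) < 1e-8
        assert sol.converged

    def test_jacobian_negative_semidefinite(self, four_subject):
        ds, fit, mom, basis = four_subject
        arr = ds.arrays()
        B = basis.design(arr.t)
        Z = np.column_stack([arr.X[arr.subject_index], B])
        for eta in (np.zeros(Z.shape[1]), np.linspace(-0.4, 0.4, Z.shape[1])):
            w = arr.y * np.exp(-(Z @ eta))
            J = -(Z * w[:, None]).T @ Z
            np.testing.assert_allclose(J, J.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(J) <= 1e-10)

    def test_covariate_shift_moves_only_intercept(self, four_subject):
        from sunjoint import LongitudinalDataset, Subject

        ds, fit, mom, basis = four_subject
        sol = solve_extended(ds, fit, mom, basis)
        c = 2.0
        shifted = LongitudinalDataset(
            [Subject(id=s.id, X=s.X + c, C=s.C, times=s.times, y=s.y)
             for s in ds.subjects],
            tau=ds.tau, covariate_names=ds.covariate_names)
        fit2 = fit_andersen_gill(shifted)
        mom2 = frailty_moments(shifted, fit2)
        sol2 = solve_extended(shifted, fit2, mom2, basis)
        np.testing.assert_allclose(sol2.beta, sol.beta, atol=1e-7)
        # trajectory at the shifted covariate value is unchanged
        t = np.linspace(0.1, 2.9, 7)
        np.testing.assert_allclose(
            predict_trajectory(sol2, t, X=np.array([1.0 + c])),
            predict_trajectory(sol, t, X=np.array([1.0])), rtol=1e-6)

    def test_rank_deficiency_detected(self, four_subject):
        from sunjoint import LongitudinalDataset, Subject

        ds, _, _, basis = four_subject
        # duplicate the covariate column -> collinear design
        from sunjoint import breslow_baseline
        from sunjoint.visits import IntensityFit

        dup = LongitudinalDataset(
            [Subject(id=s.id, X=np.array([s.X[0], s.X[0]]), C=s.C,
                     times=s.times, y=s.y) for s in ds.subjects],
            tau=ds.tau, covariate_names=["x0", "x0b"])
        # visit-model stage bypassed (it would reject collinearity itself):
        # hand it a valid intensity fit and let the solver see the defect
        gamma = np.array([0.2, 0.0])
        fit = IntensityFit(gamma=gamma, Lambda0=breslow_baseline(dup, gamma),
                           converged=True, iterations=1)
        mom = frailty_moments(dup, fit)
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            solve_extended(dup, fit, mom, basis)


class TestPredictTrajectory:
    def test_zero_alpha_gives_unit_trajectory(self, four_subject):
        from sunjoint.extended import ExtendedFit

        _, _, _, basis = four_subject
        fit = ExtendedFit(eta=np.zeros(1 + basis.dimension), basis=basis,
                          n_covariates=1, covariate_names=["x0"],
                          converged=True, equation_norm=0.0, iterations=0)
        np.testing.assert_allclose(
            predict_trajectory(fit, np.linspace(0, 3, 5), X=np.zeros(1)), 1.0)

    def test_trajectory_ratio_is_exp_beta(self, four_subject):
        ds, fit, mom, basis = four_subject
        sol = solve_extended(ds, fit, mom, basis)
        t = np.linspace(0.2, 2.8, 9)
        ratio = (predict_trajectory(sol, t, X=np.array([1.0]))
                 / predict_trajectory(sol, t, X=np.array([0.0])))
        np.testing.assert_allclose(ratio, np.exp(sol.beta[0]), rtol=1e-12)

    def test_log_trajectory_error_shrinks_with_n(self):
        # integrated squared error of the estimated log intercept against
        # the generator's truth decreases with sample size
        m0 = MU0_FORMS["loglinear"]
        grid = np.linspace(0.05, 4.5, 60)
        mise = {}
        for n in (100, 200, 500):
            errs = []
            master = np.random.SeedSequence(99 + n)
            for child in master.spawn(100):
                rng = np.random.default_rng(child)
                ds = generate_dataset(ScenarioSpec(n=n), rng)
                fit = fit_andersen_gill(ds)
                mom = frailty_moments(ds, fit)
                basis = build_basis(ds.arrays().t, 3, 4, boundary=(0.0, 5.0))
                try:
                    sol = solve_extended(ds, fit, mom, basis)
                except Exception:
                    continue
                log_traj = np.log(predict_trajectory(sol, grid))
                errs.append(np.mean((log_traj - m0(grid)) ** 2))
            mise[n] = np.mean(errs)
        assert mise[100] > mise[200] > mise[500]
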