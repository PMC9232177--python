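import numpy as np
import pytest
from hypothesis import given, strategies as st

from diffsens.branching import (
    BDMProcess,
    dominant_eigen,
    extinction_probabilities,
    extinction_sensitivities,
    generator_matrix,
    growth_rate_sensitivity,
    mean_matrix,
    offspring_matrix,
    pack_params,
    param_labels,
    progeny_gf,
    total_progeny,
    total_progeny_sensitivity,
)
from diffsens.fixtures import BDMFixtureSpec, random_bdm

CS_STEP = 1e-10


def _complex_step_columns(proc, primal, shape):
    """Complex-step derivative of a primal map over the packed rates."""
    theta = pack_params(proc)
    out = np.empty(shape + (theta.size,))
    for k in range(theta.size):
        thc = theta.astype(complex)
        thc[k] += 1j * CS_STEP
        out[..., k] = np.imag(primal(BDMProcess.from_params(proc.n, thc))) / CS_STEP
    return out


class TestGeneratorAndMeanMatrix:
    def test_two_node_hand_arithmetic(self, two_node_process):
        np.testing.assert_allclose(
            generator_matrix(two_node_process), [[0.0, 0.5], [1.0, -1.25]]
        )

    def test_single_node_scalar_exponential(self):
        p = BDMProcess(beta=[1.5], delta=[1.0], lam=[[0.0]])
        assert generator_matrix(p)[0, 0] == 0.5
        assert mean_matrix(p, 2.0)[0, 0] == pytest.approx(np.e, rel=1e-12)

    def test_balanced_rates_give_conservative_semigroup(self):
        proc = BDMProcess(
            beta=[0.4, 0.4, 0.4],
            delta=[0.4, 0.4, 0.4],
            lam=[[0.0, 0.2, 0.1], [0.3, 0.0, 0.1], [0.05, 0.15, 0.0]],
        )
        assert np.allclose(generator_matrix(proc).sum(axis=1), 0.0)
        for t in (0.0, 1.0, 7.5):
            np.testing.assert_allclose(mean_matrix(proc, t).sum(axis=1), 1.0, rtol=1e-12)

    def test_time_zero_identity(self, two_node_process):
        np.testing.assert_allclose(mean_matrix(two_node_process, 0.0), np.eye(2))

    def test_validation(self):
        with pytest.raises(ValueError, match="diagonal"):
            BDMProcess(beta=[1.0], delta=[1.0], lam=[[0.5]])
        with pytest.raises(ValueError, match="positive"):
            BDMProcess(beta=[0.0], delta=[1.0], lam=[[0.0]])


class TestDominantEigen:
    def test_single_node(self):
        trip = dominant_eigen(BDMProcess(beta=[1.5], delta=[1.0], lam=[[0.0]]))
        assert trip.rho == pytest.approx(0.5)
        assert trip.v[0] * trip.w[0] == pytest.approx(1.0)

    def test_eigen_residuals(self, two_node_process):
        trip = dominant_eigen(two_node_process)
        om = generator_matrix(two_node_process)
        assert np.max(np.abs(om @ trip.w - trip.rho * trip.w)) <= 1e-10
        assert np.max(np.abs(trip.v @ om - trip.rho * trip.v)) <= 1e-10
        assert trip.v @ trip.w == pytest.approx(1.0, abs=1e-12)
        assert np.all(trip.w > 0)

    def test_subcritical_fixture_negative_rho(self):
        proc = random_bdm(BDMFixtureSpec(criticality="subcritical", seed=1))
        assert dominant_eigen(proc).rho < 0

    def test_reducible_graph_rejected(self):
        proc = BDMProcess(
            beta=[1.0, 1.0], delta=[1.5, 1.5], lam=[[0.0, 0.3], [0.0, 0.0]]
        )
        with pytest.raises(ValueError, match="strongly connected"):
            dominant_eigen(proc)


class TestGrowthRateSensitivity:
    def test_single_node_unit_sensitivities(self):
        p = BDMProcess(beta=[1.5], delta=[1.0], lam=[[0.0]])
        assert growth_rate_sensitivity(p, ("beta", 0)) == pytest.approx(1.0)
        assert growth_rate_sensitivity(p, ("delta", 0)) == pytest.approx(-1.0)

    def test_birth_death_antisymmetry(self, two_node_process):
        for i in range(2):
            up = growth_rate_sensitivity(two_node_process, ("beta", i))
            down = growth_rate_sensitivity(two_node_process, ("delta", i))
            assert down == -up

    def test_matches_complex_step_of_eigenvalue(self, two_node_process):
        def rho_primal(proc):
            vals = np.linalg.eigvals(generator_matrix(proc))
            return np.array([vals[np.argmax(vals.real)]])

        cs = _complex_step_columns(two_node_process, rho_primal, (1,))[0]
        for k, which in enumerate(param_labels(2)):
            analytic = growth_rate_sensitivity(two_node_process, which)
            assert cs[k] == pytest.approx(analytic, rel=1e-6, abs=1e-12)

    def test_unknown_identifier_rejected(self, two_node_process):
        with pytest.raises(ValueError, match="identifier"):
            growth_rate_sensitivity(two_node_process, ("gamma", 0))


class TestProgenyGeneratingFunction:
    def test_normalization_at_one(self, two_node_process):
        np.testing.assert_allclose(progeny_gf(two_node_process, np.ones(2)), 1.0)

    def test_value_at_zero(self, two_node_process):
        s = two_node_process.beta + two_node_process.delta + two_node_process.lam_row_sums
        np.testing.assert_allclose(
            progeny_gf(two_node_process, np.zeros(2)), two_node_process.delta / s
        )

    def test_two_node_hand_fractions(self, two_node_process):
        # node 1: (1.0 + 1.5*0.25 + 0.5*0.5)/3.0; node 2: (1.75 + 1.5*0.25 + 1.0*0.5)/4.25
        out = progeny_gf(two_node_process, np.array([0.5, 0.5]))
        assert out[0] == pytest.approx((1.0 + 0.375 + 0.25) / 3.0)
        assert out[1] == pytest.approx((1.75 + 0.375 + 0.5) / 4.25)

    @given(st.integers(0, 2**31 - 1))
    def test_maps_unit_cube_into_itself(self, seed):
        rng = np.random.default_rng(seed)
        proc = random_bdm(BDMFixtureSpec(n_types=3, seed=seed % 1000))
        x = rng.uniform(0.0, 1.0, size=3)
        out = progeny_gf(proc, x)
        assert np.all((out >= 0.0) & (out <= 1.0))
        np.testing.assert_allclose(progeny_gf(proc, np.ones(3)), 1.0)


class TestExtinction:
    def test_scalar_supercritical_closed_form(self):
        p = BDMProcess(beta=[1.5], delta=[1.0], lam=[[0.0]])
        res = extinction_probabilities(p)
        assert res.converged
        assert res.e[0] == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_subcritical_goes_to_one(self):
        for seed in range(5):
            proc = random_bdm(BDMFixtureSpec(criticality="subcritical", seed=seed))
            res = extinction_probabilities(proc)
            np.testing.assert_allclose(res.e, 1.0, atol=1e-7)

    def test_supercritical_interior(self):
        for seed in range(5):
            proc = random_bdm(BDMFixtureSpec(criticality="supercritical", seed=seed))
            e = extinction_probabilities(proc).e
            assert np.all((e > 0.0) & (e < 1.0))

    def test_iterates_monotone_nondecreasing(self, two_node_process):
        x = np.zeros(2)
        for _ in range(60):
            y = progeny_gf(two_node_process, x)
            assert np.all(y >= x - 1e-15)
            x = y

    def test_maxiter_reports_not_raises(self, two_node_process):
        res = extinction_probabilities(two_node_process, maxiter=3)
        assert not res.converged
        assert res.iterations == 3


class TestExtinctionSensitivities:
    def test_scalar_closed_forms(self):
        # e = delta/beta: de/ddelta = 1/beta, de/dbeta = -delta/beta^2
        p = BDMProcess(beta=[1.5], delta=[1.0], lam=[[0.0]])
        de = extinction_sensitivities(p)
        assert de[0, 0] == pytest.approx(1.0 / 1.5, rel=1e-9)
        assert de[0, 1] == pytest.approx(-1.0 / 2.25, rel=1e-9)

    def test_subcritical_input_rejected(self):
        p = BDMProcess(beta=[1.0], delta=[1.5], lam=[[0.0]])
        with pytest.raises(ValueError, match="supercritical"):
            extinction_sensitivities(p)

    def test_matches_complex_step_fixed_point(self):
        proc = random_bdm(BDMFixtureSpec(n_types=3, criticality="supercritical", seed=5))
        analytic = extinction_sensitivities(proc)
        cs = _complex_step_columns(
            proc, lambda q: extinction_probabilities(q).e, (proc.n,)
        )
        np.testing.assert_allclose(cs, analytic, rtol=1e-6, atol=1e-10)

    def test_matches_tandem_differentiated_iteration(self):
        """Differentiating the fixed-point iteration itself converges to
        the implicit-differentiation solution."""
        proc = random_bdm(BDMFixtureSpec(n_types=2, criticality="supercritical", seed=8))
        analytic = extinction_sensitivities(proc)
        labels = param_labels(proc.n)
        theta = pack_params(proc)
        h = 1e-7
        # tandem recursion: e' <- d_eP e' + d_thetaP via directional finite diff
        e = np.zeros(proc.n)
        de = np.zeros((proc.n, theta.size))
        for _ in range(3000):
            base = progeny_gf(proc, e)
            de_new = np.empty_like(de)
            for k in range(theta.size):
                thc = theta.astype(complex)
                thc[k] += 1j * h
                pc = BDMProcess.from_params(proc.n, thc)
                # d/dtheta_k P(e(theta), theta) with e frozen plus chain term
                dP_dtheta = np.imag(progeny_gf(pc, e)) / h
                ec = e.astype(complex) + 1j * h * de[:, k]
                chain = np.imag(progeny_gf(proc, ec)) / h
                de_new[:, k] = chain + dP_dtheta
            e, de = base, de_new
        np.testing.assert_allclose(de, analytic, rtol=1e-8, atol=1e-12)


class TestTotalProgeny:
    def test_offspring_matrix_values(self):
        p = BDMProcess(beta=[1.0], delta=[2.0], lam=[[0.0]])
        assert offspring_matrix(p)[0, 0] == pytest.approx(2.0 / 3.0)
        # two-node: row normalizers 3.0 and 4.25
        q = BDMProcess(beta=[1.5, 1.5], delta=[1.0, 1.75], lam=[[0.0, 0.5], [1.0, 0.0]])
        f = offspring_matrix(q)
        np.testing.assert_allclose(
            f, [[3.0 / 3.0, 0.5 / 3.0], [1.0 / 4.25, 3.0 / 4.25]]
        )

    def test_scalar_total_progeny(self):
        p = BDMProcess(beta=[1.0], delta=[2.0], lam=[[0.0]])
        assert total_progeny(p)[0, 0] == pytest.approx(3.0, rel=1e-12)

    def test_neumann_series_oracle(self):
        proc = random_bdm(BDMFixtureSpec(n_types=3, criticality="subcritical", seed=4))
        f = offspring_matrix(proc)
        a = total_progeny(proc)
        series = np.zeros_like(f)
        term = np.eye(proc.n)
        for _ in range(3000):
            series += term
            term = term @ f
        np.testing.assert_allclose(a, series, atol=1e-10)

    def test_supercritical_rejected(self):
        p = BDMProcess(beta=[2.0], delta=[1.0], lam=[[0.0]])
        with pytest.raises(ValueError, match="spectral radius"):
            total_progeny(p)

    def test_scalar_sensitivity_chain_rule(self):
        # A = 3, dF/ddelta = -2 beta/(beta+delta)^2 = -2/9, dA = A*dF*A = -2
        p = BDMProcess(beta=[1.0], delta=[2.0], lam=[[0.0]])
        assert total_progeny_sensitivity(p, ("delta", 0))[0, 0] == pytest.approx(-2.0)

    def test_sensitivity_matches_complex_step(self):
        proc = random_bdm(BDMFixtureSpec(n_types=3, criticality="subcritical", seed=12))

        def primal(q):
            return np.linalg.inv(np.eye(q.n) - offspring_matrix(q))

        cs = _complex_step_columns(proc, primal, (proc.n, proc.n))
        for k, which in enumerate(param_labels(proc.n)):
            analytic = total_progeny_sensitivity(proc, which)
            np.testing.assert_allclose(cs[..., k], analytic, rtol=1e-6, atol=1e-10)

    def test_sensitivity_matches_central_difference(self):
        proc = random_bdm(BDMFixtureSpec(n_types=2, criticality="subcritical", seed=2))
        theta = pack_params(proc)
        h = 1e-6
        for k, which in enumerate(param_labels(proc.n)):
            up, dn = theta.copy(), theta.copy()
            up[k] += h
            dn[k] -= h
            a_up = total_progeny(BDMProcess.from_params(proc.n, up))
            a_dn = total_progeny(BDMProcess.from_params(proc.n, dn))
            fd = (a_up - a_dn) / (2 * h)
            analytic = total_progeny_sensitivity(proc, which)
            np.testing.assert_allclose(fd, analytic, rtol=1e-6, atol=1e-9)


class TestCriticalityConsistency:
    @pytest.mark.parametrize("criticality", ["subcritical", "supercritical"])
    def test_sign_of_rho_determines_extinction(self, criticality):
        for seed in range(10):
            proc = random_bdm(BDMFixtureSpec(n_types=2, criticality=criticality, seed=seed))
            rho = dominant_eigen(proc).rho
            e = extinction_probabilities(proc).e
            if criticality == "subcritical":
                assert rho < 0 and np.allclose(e, 1.0, atol=1e-7)
            else:
                assert rho > 0 and np.all(e < 1.0)
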