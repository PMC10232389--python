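import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from webpatch import (
    FoodWeb,
    ParamSet,
    assign_cc_tradeoff,
    basal_equilibrium_analytic,
    basal_rhs,
    consumer_equilibrium_analytic,
    consumer_rhs,
    effective_rates,
    generate_web,
    hierarchical_H,
    run_to_steady_state,
    steady_state_analytic,
)
from tests.conftest import basal_params, basal_web

LEVINS_C, LEVINS_E = 0.45, 0.2


def levins_occupancy(c, e, U):
    """Closed-form single-species equilibrium 1 - U - e/c (oracle)."""
    return 1.0 - U - e / c


class TestBasalRHS:
    def test_single_species_hand_value(self):
        web = basal_web(1)
        p = basal_params(LEVINS_C, LEVINS_E, U=0.0)
        rate = basal_rhs([0.5], [], web, hierarchical_H(1), p)
        assert rate == pytest.approx(0.45 * 0.5 * 0.5 - 0.2 * 0.5)  # 0.0125

    def test_extinct_species_stays_extinct(self):
        web = basal_web(3)
        p = basal_params([0.45, 0.6, 0.8])
        rate = basal_rhs([0.0, 0.2, 0.3], [], web, hierarchical_H(3), p)
        assert rate[0] == 0.0

    def test_symmetric_contests_between_twins_cancel(self):
        # identical rates and symmetric H: displacement gains equal losses
        web = basal_web(2)
        p = basal_params([0.5, 0.5])
        H = np.array([[0.0, 0.4], [0.4, 0.0]])
        rate = basal_rhs([0.3, 0.3], [], web, H, p)
        assert rate[0] == pytest.approx(rate[1])
        no_comp = basal_rhs([0.3, 0.3], [], web, np.zeros((2, 2)), p)
        assert np.allclose(rate, no_comp)  # the competition term is zero

    def test_dimension_mismatch_raises(self):
        web = basal_web(2)
        with pytest.raises(ValueError):
            basal_rhs([0.1], [], web, hierarchical_H(2),
                      basal_params([0.5, 0.6]))


class TestConsumerRHS:
    def test_starved_consumer_decays(self, pair_web):
        p = assign_cc_tradeoff(pair_web, mu=0.0, phi=0.0)
        rate = consumer_rhs([0.0], [0.4], pair_web, p)
        assert rate[0] == pytest.approx(-0.05 * 0.4)

    def test_equilibrium_is_a_fixed_point(self, pair_web):
        p = assign_cc_tradeoff(pair_web, mu=0.0, phi=0.0)
        P_star = levins_occupancy(0.8, 0.2, 0.0)  # c from upper endpoint
        A_star = 1.0 - 0.05 / (0.625 * P_star)
        rate = consumer_rhs([P_star], [A_star], pair_web, p)
        assert rate[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_vacant_patches_means_negative_growth(self, pair_web):
        p = assign_cc_tradeoff(pair_web, mu=0.0, phi=0.0, U=0.2)
        rate = consumer_rhs([0.5], [0.8], pair_web, p)  # A = 1 - U
        assert rate[0] < 0.0


class TestLotkaVolterraForm:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n_P=st.integers(1, 6), seed=st.integers(0, 2**31 - 1),
           U=st.floats(0.0, 0.9))
    def test_per_capita_growth_matches_effective_rates(self, n_P, seed, U):
        """Without predation, r_i = b_i + (M P)_i exactly."""
        rng = np.random.default_rng(seed)
        web = basal_web(n_P)
        p = ParamSet(cP=rng.uniform(0.1, 1.0, n_P),
                     eP=rng.uniform(0.05, 0.3, n_P), U=U)
        H = hierarchical_H(n_P)
        P = rng.uniform(0.01, (1.0 - U) / n_P, n_P)
        b, M = effective_rates(web, H, p)
        r_direct = basal_rhs(P, [], web, H, p) / P
        assert np.allclose(r_direct, b + M @ P, atol=1e-12)


class TestSteadyStateProtocol:
    @pytest.mark.parametrize("U", [0.0, 0.2, 0.5])
    def test_levins_limit(self, U):
        web = basal_web(1)
        p = basal_params(LEVINS_C, LEVINS_E, U=U)
        st_ = run_to_steady_state(web, hierarchical_H(1), p)
        assert st_.P[0] == pytest.approx(levins_occupancy(LEVINS_C, LEVINS_E, U),
                                         abs=1e-6)

    def test_consumer_equilibrium_oracle(self, pair_web):
        # c^P = 0.45: P* = 1 - 0.2/0.45 ~ 0.5556, A* = 1 - 0.05/(0.625 P*)
        p = ParamSet(cP=[0.45], eP=[0.2], cA=[0.625], eA=[0.05],
                     mu=np.zeros((1, 1)), phi=np.zeros((1, 1)), U=0.0)
        st_ = run_to_steady_state(pair_web, hierarchical_H(1), p)
        P_star = levins_occupancy(0.45, 0.2, 0.0)
        A_star = 1.0 - 0.05 / (0.625 * P_star)
        assert st_.P[0] == pytest.approx(P_star, abs=1e-6)
        assert st_.A[0] == pytest.approx(A_star, abs=1e-5)
        assert st_.A[0] == pytest.approx(0.856, abs=1e-3)

    def test_collapse_when_loss_exceeds_levins_point(self):
        web = basal_web(2)
        p = basal_params([0.45, 0.5], e=0.4, U=0.5)  # c(1-U) < e for both
        st_ = run_to_steady_state(web, hierarchical_H(2), p)
        assert st_.extinct.all()
        assert np.all(st_.P == 0.0)

    def test_extinct_species_flagged_and_zeroed(self):
        web = basal_web(1)
        p = basal_params(LEVINS_C, LEVINS_E, U=0.6)  # beyond 1 - e/c
        st_ = run_to_steady_state(web, hierarchical_H(1), p)
        assert st_.extinct[0]
        assert st_.P[0] == 0.0

    def test_initial_conditions_do_not_matter(self, pair_web):
        p = assign_cc_tradeoff(pair_web)  # with predation (mu > 0)
        H = hierarchical_H(1)
        a = run_to_steady_state(pair_web, H, p,
                                init=np.array([0.05, 0.05]))
        b = run_to_steady_state(pair_web, H, p,
                                init=np.array([0.45, 0.9]))
        assert np.allclose(a.occupancies, b.occupancies, atol=1e-6)

    def test_occupancy_bounds_hold(self):
        web = generate_web(3, 8, 18, seed=4)
        p = assign_cc_tradeoff(web, U=0.1)
        st_ = run_to_steady_state(web, hierarchical_H(3), p)
        assert np.all(st_.occupancies >= 0.0)
        assert np.all(st_.occupancies <= 1.0 - p.U + 1e-8)
        assert st_.P.sum() <= 1.0 - p.U + 1e-8

    def test_relative_abundances_sum_to_one(self):
        web = basal_web(3)
        p = basal_params([0.45, 0.625, 0.8], U=0.45)
        st_ = run_to_steady_state(web, hierarchical_H(3), p)
        assert st_.q.sum() == pytest.approx(1.0)


class TestAnalyticEquilibria:
    def test_single_species_reduces_to_levins(self):
        web = basal_web(1)
        p = basal_params(LEVINS_C, LEVINS_E, U=0.2)
        P = basal_equilibrium_analytic(web, hierarchical_H(1), p)
        assert P[0] == pytest.approx(levins_occupancy(LEVINS_C, LEVINS_E, 0.2))

    def test_two_species_coexistence_band(self):
        web = basal_web(2)
        p = basal_params([0.45, 0.8], U=0.3)
        P = basal_equilibrium_analytic(web, hierarchical_H(2), p)
        assert P == pytest.approx([0.25556, 0.05069], abs=5e-5)

    def test_inferior_competitor_excluded_without_loss(self):
        web = basal_web(2)
        p = basal_params([0.45, 0.8], U=0.0)
        P = basal_equilibrium_analytic(web, hierarchical_H(2), p)
        assert P[1] == 0.0
        assert P[0] == pytest.approx(levins_occupancy(0.45, 0.2, 0.0))

    def test_requires_no_predation(self, pair_web):
        p = assign_cc_tradeoff(pair_web)  # mu > 0
        with pytest.raises(ValueError):
            basal_equilibrium_analytic(pair_web, hierarchical_H(1), p)

    def test_consumer_chain_solved_bottom_up(self, chain3):
        p = assign_cc_tradeoff(chain3, mu=0.0, phi=0.0)
        P_star = np.array([levins_occupancy(0.8, 0.2, 0.0)])
        A = consumer_equilibrium_analytic(chain3, p, P_star)
        A1 = 1.0 - 0.05 / (0.625 * P_star[0])
        A2 = 1.0 - 0.05 / (0.625 * A1)
        assert A == pytest.approx([A1, A2])

    def test_consumer_with_extinct_prey_is_extinct(self, chain3):
        p = assign_cc_tradeoff(chain3, mu=0.0, phi=0.0)
        A = consumer_equilibrium_analytic(chain3, p, np.array([0.0]))
        assert np.all(A == 0.0)


class TestAnalyticNumericAgreement:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_random_webs_agree_within_tolerance(self, seed):
        """ODE protocol vs closed-form equilibria, predation-free."""
        rng = np.random.default_rng(seed)
        n_P = int(rng.integers(1, 7))
        n_A = int(rng.integers(0, 11))
        L = int(rng.integers(n_A, min(n_A + 2 * n_P + 4,
                                      n_P * n_A + n_A * (n_A - 1) // 2) + 1))
        web = generate_web(n_P, n_A, L, seed=int(rng.integers(2**31)))
        p = assign_cc_tradeoff(
            web,
            c_range=(0.3 + 0.2 * rng.random(), 0.8 + 0.2 * rng.random()),
            mu=0.0, phi=0.0,
            U=float(rng.uniform(0.0, 0.6)),
        )
        H = hierarchical_H(n_P)
        ana = steady_state_analytic(web, H, p)
        ode = run_to_steady_state(web, H, p)
        assert np.allclose(ana.occupancies, ode.occupancies, atol=1e-4)
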