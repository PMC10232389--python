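import numpy as np
import pytest

from webpatch import (
    assign_cc_tradeoff,
    count_local_maxima,
    default_U_grid,
    detect_turning_points,
    generate_web,
    hierarchical_H,
    run_sweep,
)
from tests.conftest import basal_params, basal_web


class TestRunSweep:
    def test_levins_occupancies_follow_closed_form(self):
        web = basal_web(1)
        p = basal_params(0.45, 0.2)
        res = run_sweep(web, hierarchical_H(1), p,
                        U_grid=np.array([0.0, 0.2, 0.5]))
        expected = [1 - U - 0.2 / 0.45 for U in (0.0, 0.2, 0.5)]
        assert np.allclose(res.basal_occupancy[:, 0], expected, atol=1e-9)
        assert np.all(np.diff(res.basal_occupancy[:, 0]) < 0)

    def test_two_species_richness_band_is_nonmonotone(self):
        # inferior competitor persists only on an intermediate U band
        web = basal_web(2)
        p = basal_params([0.45, 0.8], 0.2)
        res = run_sweep(web, hierarchical_H(2), p)
        rich = res.table["basal_richness"].to_numpy()
        seen = [r for i, r in enumerate(rich) if i == 0 or r != rich[i - 1]]
        assert seen == [1, 2, 1, 0]

    def test_empty_grid_gives_empty_result(self):
        web = basal_web(1)
        res = run_sweep(web, hierarchical_H(1), basal_params(0.45),
                        U_grid=np.array([]))
        assert len(res.table) == 0
        assert res.turning_points() == []

    def test_basal_only_mode_drops_consumers(self):
        web = generate_web(3, 8, 16, seed=2)
        p = assign_cc_tradeoff(web)
        res = run_sweep(web, hierarchical_H(3), p,
                        U_grid=np.array([0.0, 0.3]), mode="basal_only")
        assert res.web.n_consumers == 0
        assert res.consumer_occupancy.shape == (2, 0)

    def test_invalid_grid_rejected(self):
        web = basal_web(1)
        with pytest.raises(ValueError):
            run_sweep(web, hierarchical_H(1), basal_params(0.45),
                      U_grid=np.array([0.5, 0.2]))

    def test_analytic_path_cross_validates_against_ode(self):
        web = generate_web(3, 6, 12, seed=9)
        p = assign_cc_tradeoff(web, mu=0.0, phi=0.0)
        res = run_sweep(web, hierarchical_H(3), p,
                        U_grid=np.linspace(0, 0.9, 10),
                        cross_validate=3, seed=0)
        assert res.method == "analytic"
        assert res.cross_validation["n_checked"] == 3
        assert res.cross_validation["max_abs_diff"] < 1e-4

    def test_ode_method_forced(self):
        web = basal_web(1)
        res = run_sweep(web, hierarchical_H(1), basal_params(0.45),
                        U_grid=np.array([0.0, 0.3]), method="ode")
        assert res.method == "ode"
        assert np.allclose(res.basal_occupancy[:, 0],
                           [1 - 0.2 / 0.45, 0.7 - 0.2 / 0.45], atol=1e-6)


class TestTurningPoints:
    def test_two_species_band_events(self):
        web = basal_web(2)
        p = basal_params([0.45, 0.8], 0.2)
        res = run_sweep(web, hierarchical_H(2), p)
        events = detect_turning_points(res)
        directions = [(e.species, e.direction) for e in events]
        assert ("P2", "enter") in directions
        assert directions.count(("P1", "leave")) == 1
        assert directions.count(("P2", "leave")) == 1

    def test_monotone_levins_single_leave(self):
        web = basal_web(1)
        p = basal_params(0.45, 0.2)
        res = run_sweep(web, hierarchical_H(1), p)
        events = detect_turning_points(res)
        assert len(events) == 1
        e = events[0]
        assert e.direction == "leave"
        # closed-form extinction point U = 1 - e/c ~ 0.5556
        assert e.U_lo <= 1 - 0.2 / 0.45 <= e.U_hi + 1e-9

    def test_constant_richness_has_no_events(self):
        web = basal_web(1)
        p = basal_params(0.9, 0.1)
        res = run_sweep(web, hierarchical_H(1), p,
                        U_grid=np.linspace(0, 0.4, 20))
        assert detect_turning_points(res) == []

    def test_single_point_grid_yields_nothing(self):
        web = basal_web(2)
        res = run_sweep(web, hierarchical_H(2), basal_params([0.45, 0.8]),
                        U_grid=np.array([0.3]))
        assert detect_turning_points(res) == []

    def test_more_basal_species_give_more_turning_points(self):
        """Richer basal guilds produce more enter/leave events (over seeds)."""
        def mean_events(n_P):
            counts = []
            for seed in range(10):
                web = basal_web(n_P)
                p = assign_cc_tradeoff(web, c_range=(0.25, 1.0),
                                       spacing="irregular", seed=seed,
                                       mu=0.0, phi=0.0)
                res = run_sweep(web, hierarchical_H(n_P), p)
                counts.append(len(res.turning_points()))
            return np.mean(counts)

        assert mean_events(6) > mean_events(3)


class TestOscillationStatistic:
    def test_counts_simple_peaks(self):
        y = np.array([0, 1, 0, 2, 0, 3, 0], dtype=float)
        assert count_local_maxima(y, filter_window=1) == 3

    def test_median_filter_suppresses_grid_noise(self):
        y = np.array([0, 0, 5, 0, 0, 1, 1, 1, 0, 0], dtype=float)
        # the single-point spike disappears, the plateau counts once
        assert count_local_maxima(y, filter_window=3) == 1

    def test_monotone_profile_has_single_boundary_peak(self):
        y = np.linspace(3, 0, 20)
        assert count_local_maxima(y, filter_window=1) == 1

    def test_nan_tail_treated_as_absent(self):
        y = np.array([1.0, 2.0, 1.0, np.nan, np.nan])
        assert count_local_maxima(y, filter_window=1) == 1


class TestDiversityOscillations:
    @pytest.mark.parametrize("n_P", [3, 4, 6])
    def test_multiple_diversity_peaks_under_cc_tradeoff(self, n_P):
        """Basal diversity rises and falls repeatedly along the U gradient."""
        ok = []
        for c_range in [(0.45, 0.8), (0.25, 1.0)]:
            web = basal_web(n_P)
            p = assign_cc_tradeoff(web, c_range=c_range, mu=0.0, phi=0.0)
            res = run_sweep(web, hierarchical_H(n_P), p)
            n_peaks = res.n_diversity_peaks()
            div = res.diversity
            gmax_at_positive_U = res.U_grid[int(np.argmax(div))] > 0
            assert n_peaks >= 2
            ok.append(gmax_at_positive_U)
        # no patch loss is not the diversity optimum for at least one range
        assert any(ok)

    def test_no_tradeoff_control_is_monotone(self):
        """Equal colonization rates: richness declines monotonically."""
        n_P = 4
        web = basal_web(n_P)
        p = basal_params(np.full(n_P, 0.625), 0.2)
        res = run_sweep(web, hierarchical_H(n_P), p)
        rich = res.table["basal_richness"].to_numpy()
        assert np.all(np.diff(rich) <= 0)
        assert rich[0] == 1  # hierarchy winner only, no coexistence

    def test_full_web_complexity_is_nonmonotone(self):
        """Some web of each empirical size class shows an interior local
        maximum in richness, mean FCL and omnivory along the gradient."""
        def has_interior_rise(y):
            y = np.where(np.isnan(y), 0.0, np.asarray(y, dtype=float))
            return bool(np.any((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])))

        for n_P, n_A, L in [(3, 11, 23), (4, 11, 25)]:
            found = False
            for seed in range(5):
                web = generate_web(n_P, n_A, L, seed=seed)
                p = assign_cc_tradeoff(web, c_range=(0.25, 1.0),
                                       mu=0.0, phi=0.0)
                res = run_sweep(web, hierarchical_H(n_P), p,
                                U_grid=default_U_grid(step=0.01))
                if all(has_interior_rise(res.table[col].to_numpy())
                       for col in ("richness", "mean_fcl", "omnivory")):
                    found = True
                    break
            assert found, f"no non-monotone web found for size {(n_P, n_A, L)}"
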