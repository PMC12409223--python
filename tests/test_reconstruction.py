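import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flashqa import (DeliveryLog, GridGeometry, NoiseSettings, SimplePlan,
                     cumulative_dose, default_beam_model, detect_pauses,
                     inject_pause, pbs_average_dose_rate_map,
                     point_dose_rate_from_trace, reconstruct_dose_map,
                     segment_spots, simulate_delivery, spot_records_from_truth)
from flashqa.reconstruction import SpotRecord
from flashqa.validation import random_plan
from oracles import pbs_rate_oracle


def spot(mu_u=0.0, mu_t=0.0, sigma=3.0, mu=1.0, dose_area=None, t=(0.0, 10.0),
         index=0):
    return SpotRecord(index=index, t_start=t[0], t_end=t[1], mu_u=mu_u,
                      mu_t=mu_t, sigma_u=sigma, sigma_t=sigma, mu=mu,
                      dose_area=dose_area if dose_area is not None else mu)


class TestSegmentSpots:
    def test_noise_free_recovery(self, field_plan, model):
        log, truth = simulate_delivery(field_plan, model, seed=0)
        spots = segment_spots(log, model)
        assert len(spots) == field_plan.n_spots
        for rec, true in zip(spots, truth.spots):
            assert rec.mu == pytest.approx(true.mu, rel=1e-9)
            assert rec.mu_u == pytest.approx(true.mu_u, abs=1e-9)
            assert rec.mu_t == pytest.approx(true.mu_t, abs=1e-9)
            assert rec.t_end == pytest.approx(true.t_end, abs=1.0)

    def test_mid_spot_pause_keeps_one_record_flagged(self, field_plan, model):
        log, truth = simulate_delivery(field_plan, model, seed=0)
        paused, _ = inject_pause(log, truth, at=45.0, duration=50.0)
        spots = segment_spots(paused, model)
        assert len(spots) == field_plan.n_spots
        flagged = [s for s in spots if s.contains_pause]
        assert len(flagged) == 1
        assert flagged[0].mu == pytest.approx(field_plan.mu_per_spot, rel=1e-9)

    def test_empty_log_gives_no_spots(self, model):
        log = DeliveryLog(field_id="x", gantry_angle=0, couch_angle=0,
                          arm="CONV", t_ms=np.arange(5.0), mon1=np.zeros(5),
                          mon2=np.zeros(5), hallU=np.zeros(5), hallT=np.zeros(5))
        assert segment_spots(log, model) == []

    def test_parameter_recovery_random_plans(self, model):
        """Noise-free reconstruction recovers every spot µ and MU."""
        for seed in range(40):
            plan = random_plan(np.random.default_rng(seed))
            log, truth = simulate_delivery(plan, model, seed=seed)
            spots = segment_spots(log, model)
            assert len(spots) == plan.n_spots
            mu_err = max(abs(r.mu_u - t.mu_u) + abs(r.mu_t - t.mu_t)
                         for r, t in zip(spots, truth.spots))
            mu_rel = max(abs(r.mu - t.mu) / t.mu
                         for r, t in zip(spots, truth.spots))
            assert mu_err <= 1e-9
            assert mu_rel <= 1e-6


class TestDoseMap:
    geom = GridGeometry(origin=(-15.0, -15.0), spacing=0.5, shape=(61, 61))

    def test_single_spot_peak_closed_form(self):
        grid = reconstruct_dose_map([spot(dose_area=1.0)], self.geom)
        peak = grid.value_at(0.0, 0.0)
        assert peak == pytest.approx(1.0 / (2 * np.pi * 9.0), rel=1e-12)

    def test_linearity_duplicated_spot_doubles(self):
        one = reconstruct_dose_map([spot()], self.geom)
        two = reconstruct_dose_map([spot(), spot()], self.geom)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_superposition_of_disjoint_sets(self):
        a = [spot(mu_u=-5.0), spot(mu_u=-2.0)]
        b = [spot(mu_u=4.0, sigma=2.5)]
        ab = reconstruct_dose_map(a + b, self.geom)
        np.testing.assert_allclose(
            ab.values,
            reconstruct_dose_map(a, self.geom).values
            + reconstruct_dose_map(b, self.geom).values, rtol=1e-12)

    def test_grid_integral_conserves_dose_area(self):
        """Spots spanning 20x20 mm on a grid with >= 4-sigma margins."""
        spots = [spot(mu_u=u, mu_t=t, dose_area=2.0)
                 for u in np.linspace(-10, 10, 5)
                 for t in np.linspace(-10, 10, 5)]
        geom = GridGeometry(origin=(-30.0, -30.0), spacing=1.0, shape=(61, 61))
        grid = reconstruct_dose_map(spots, geom)
        integral = grid.values.sum() * geom.spacing ** 2
        assert integral == pytest.approx(2.0 * 25, rel=5e-3)

    def test_empty_spot_list_gives_zero_map(self):
        grid = reconstruct_dose_map([], self.geom)
        assert grid.values.sum() == 0.0

    def test_undersampled_grid_warns(self):
        coarse = GridGeometry(origin=(-10.0, -10.0), spacing=2.0, shape=(11, 11))
        with pytest.warns(UserWarning, match="spacing"):
            reconstruct_dose_map([spot()], coarse)


class TestCumulativeDose:
    geom = GridGeometry(origin=(-10.0, -10.0), spacing=1.0, shape=(21, 21))

    def test_single_spot_steps_at_termination(self):
        cum = cumulative_dose([spot(t=(0.0, 10.0))], self.geom)
        full = cum.final_map().values
        assert cum.map_at(9.9).values.sum() == 0.0
        np.testing.assert_allclose(cum.map_at(10.0).values, full)

    def test_final_equals_static_map(self, field_plan, model):
        log, _ = simulate_delivery(field_plan, model, seed=0)
        spots = segment_spots(log, model)
        geom = GridGeometry(origin=(-24.0, -24.0), spacing=1.0, shape=(49, 49))
        static = reconstruct_dose_map(spots, geom)
        for mode, lg in (("spot-termination", None), ("sample-resolved", log)):
            cum = cumulative_dose(spots, geom, mode=mode, log=lg)
            np.testing.assert_allclose(cum.final_map().values, static.values,
                                       atol=1e-12)

    def test_two_equal_spots_half_dose_between(self):
        spots = [spot(t=(0.0, 10.0)), spot(t=(20.0, 30.0), index=1)]
        cum = cumulative_dose(spots, self.geom)
        np.testing.assert_allclose(cum.map_at(20.0).values,
                                   0.5 * cum.final_map().values, atol=1e-15)

    def test_sample_resolved_requires_log(self):
        with pytest.raises(ValueError, match="log"):
            cumulative_dose([spot()], self.geom, mode="sample-resolved")


class TestPbsAverageDoseRate:
    def test_constant_rate_closed_form(self, model):
        """Uninterrupted constant-rate delivery: DR equals dose/beam-on time."""
        plan = SimplePlan(field_id="one", nu=1, nt=1, mu_per_spot=1.8,
                          intensity=10.0)  # 180 ms beam-on
        log, _ = simulate_delivery(plan, model, seed=0)
        spots = segment_spots(log, model)
        geom = GridGeometry(origin=(-6.0, -6.0), spacing=1.0, shape=(13, 13))
        cum = cumulative_dose(spots, geom, mode="sample-resolved", log=log)
        rate = pbs_average_dose_rate_map(cum, threshold_mode="interpolated")
        dose = cum.final_map()
        mask = rate.valid_mask
        np.testing.assert_allclose(rate.values[mask],
                                   dose.values[mask] / 0.180, rtol=1e-9)

    def test_paused_delivery_piecewise_closed_form(self, model):
        """Ramp, pause, ramp: the 5%-95% window spans the pause."""
        plan = SimplePlan(field_id="p", nu=1, nt=1, mu_per_spot=1.0,
                          intensity=10.0)  # 100 ms beam-on
        log, truth = simulate_delivery(plan, model, seed=0)
        log, truth = inject_pause(log, truth, at=50.0, duration=100.0)
        spots = segment_spots(log, model)
        assert len(spots) == 1 and spots[0].contains_pause
        geom = GridGeometry(origin=(-6.0, -6.0), spacing=1.0, shape=(13, 13))
        cum = cumulative_dose(spots, geom, mode="sample-resolved", log=log)
        rate = pbs_average_dose_rate_map(cum, threshold_mode="interpolated")
        dose = cum.final_map()
        mask = rate.valid_mask
        # t05 = 5 ms, t95 = 195 ms -> 0.9 D / 0.190 s
        np.testing.assert_allclose(rate.values[mask],
                                   0.9 * dose.values[mask] / 0.190, rtol=1e-9)

    @pytest.mark.parametrize("mode", ["sample-crossing", "interpolated"])
    def test_pause_never_increases_any_voxel_rate(self, field_plan, model, mode):
        log, truth = simulate_delivery(field_plan, model, seed=0)
        geom = GridGeometry(origin=(-24.0, -24.0), spacing=1.5, shape=(33, 33))

        def rates(lg):
            spots = segment_spots(lg, model)
            cum = cumulative_dose(spots, geom, mode="sample-resolved", log=lg)
            return pbs_average_dose_rate_map(cum, threshold_mode=mode)

        base = rates(log)
        paused_log, _ = inject_pause(log, truth, at=150.0, duration=80.0)
        paused = rates(paused_log)
        both = base.valid_mask & paused.valid_mask
        assert np.all(paused.values[both] <= base.values[both] + 1e-9)

    def test_pause_does_not_change_dose_map(self, field_plan, model):
        log, truth = simulate_delivery(field_plan, model, seed=0)
        geom = GridGeometry(origin=(-24.0, -24.0), spacing=1.5, shape=(33, 33))
        paused_log, _ = inject_pause(log, truth, at=150.0, duration=80.0)
        a = reconstruct_dose_map(segment_spots(log, model), geom)
        b = reconstruct_dose_map(segment_spots(paused_log, model), geom)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_oracle_equivalence_small_random_cases(self, model):
        """Vectorized rate map equals a per-voxel scan of the full series."""
        for seed in range(10):
            plan = random_plan(np.random.default_rng(100 + seed))
            log, _ = simulate_delivery(plan, model, seed=seed)
            spots = segment_spots(log, model)
            pos = plan.spot_positions()
            geom = GridGeometry.covering((pos[:, 0].min(), pos[:, 0].max()),
                                         (pos[:, 1].min(), pos[:, 1].max()),
                                         spacing=2.0, margin=5.0)
            cum = cumulative_dose(spots, geom, mode="sample-resolved", log=log)
            for interp in (False, True):
                mode = "interpolated" if interp else "sample-crossing"
                mine = pbs_average_dose_rate_map(cum, threshold_mode=mode)
                ref = pbs_rate_oracle(cum, interpolate=interp)
                np.testing.assert_allclose(mine.values[mine.valid_mask],
                                           ref[mine.valid_mask], rtol=1e-9)

    def test_degenerate_voxel_marked_invalid(self):
        geom = GridGeometry(origin=(-5.0, -5.0), spacing=1.0, shape=(11, 11))
        cum = cumulative_dose([spot(t=(0.0, 10.0))], geom)  # single step
        rate = pbs_average_dose_rate_map(cum)
        assert not rate.valid_mask.any()
        assert "degenerate" in rate.invalid_reason[5, 5]


class TestPointDoseRateFromTrace:
    def test_constant_current_closed_form(self):
        t = np.arange(500.0)
        current = np.full(500, 2e-9)           # 2 nA for 500 ms
        dose, rate = point_dose_rate_from_trace(t, current, 10.0e9)  # 10 Gy/nC
        assert dose == pytest.approx(10.0, rel=1e-12)
        assert rate == pytest.approx(20.0, rel=1e-12)

    def test_zero_trace(self):
        dose, rate = point_dose_rate_from_trace(np.arange(100.0), np.zeros(100), 1e9)
        assert dose == 0.0
        assert np.isnan(rate)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError, match="empty"):
            point_dose_rate_from_trace(np.array([]), np.array([]), 1.0)

    def test_negative_current_raises(self):
        with pytest.raises(ValueError):
            point_dose_rate_from_trace(np.arange(3.0), np.array([0.0, -1e-9, 0.0]), 1.0)

    def test_matches_voxel_rate_from_map(self, field_plan, model):
        """A trace equal to a voxel's per-sample dose reproduces its map rate."""
        log, _ = simulate_delivery(field_plan, model, seed=0)
        spots = segment_spots(log, model)
        geom = GridGeometry(origin=(-12.0, -12.0), spacing=1.0, shape=(25, 25))
        cum = cumulative_dose(spots, geom, mode="sample-resolved", log=log)
        rate_map = pbs_average_dose_rate_map(cum, threshold_mode="interpolated")
        i, j = geom.index_of(0.0, 0.0)
        times, curve = cum.voxel_curve(i, j)
        charge_to_dose = 1.0e9
        inc = np.clip(np.diff(curve, prepend=0.0), 0.0, None)  # fp dust
        current = inc / (log.sample_period_ms / 1000.0) / charge_to_dose
        dose, rate = point_dose_rate_from_trace(times, current, charge_to_dose)
        assert dose == pytest.approx(curve[-1], rel=1e-9)
        assert rate == pytest.approx(rate_map.values[i, j], rel=1e-9)


class TestDetectPauses:
    def test_clean_log_has_no_interruptions(self, field_plan, model):
        log, _ = simulate_delivery(field_plan, model, seed=0)
        report = detect_pauses(log)
        assert report.interruptions == []
        assert not report.exclusion_recommended
        # regular 4/11 ms dead times are classified as spot changes
        assert all(e.classification == "spot-change" for e in report.events)

    def test_injected_pause_found_at_its_time(self, field_plan, model):
        log, truth = simulate_delivery(field_plan, model, seed=0, arm="CONV")
        paused, _ = inject_pause(log, truth, at=150.0, duration=50.0)
        report = detect_pauses(paused)
        assert len(report.interruptions) == 1
        assert report.interruptions[0].t_start == pytest.approx(150.0, abs=2.0)
        assert report.interruptions[0].duration >= 50.0
        assert not report.exclusion_recommended  # CONV arm

    def test_uhdr_interruption_recommends_exclusion(self, field_plan, model):
        log, truth = simulate_delivery(field_plan, model, seed=0, arm="UHDR")
        paused, _ = inject_pause(log, truth, at=150.0, duration=50.0)
        assert detect_pauses(paused).exclusion_recommended
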