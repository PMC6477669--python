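"""Cycle segmentation, energy dissipation ratio, repeatability verdicts."""

import numpy as np
import pytest

from padmech import (
    CompressionRecord,
    HysteresisLoop,
    SpecimenGeometry,
    energy_dissipation_ratio,
    repeatability_check,
    segment_cycles,
)

GEOM = SpecimenGeometry(40.0, 18.0)


def triangle_record(n_cycles=5, peak=9.0, n_per_branch=50, force_fn=None):
    """Noise-free triangular displacement history with a simple force law."""
    up = np.linspace(0.0, peak, n_per_branch + 1)
    down = up[-2::-1]
    d = np.concatenate([np.concatenate([up, down]) for _ in range(n_cycles)])
    f = force_fn(d) if force_fn else 2.0 * d
    t = np.arange(len(d), dtype=float)
    return CompressionRecord(
        time=t, displacement=d, force=f, displacement_rate=1.96, geometry=GEOM
    )


def scaled_loop(q, n=100, force_fn=None):
    """Loop whose unloading force is (1−q)× the loading force pointwise."""
    d = np.linspace(0.0, 9.0, n)
    f = force_fn(d) if force_fn else d**2
    return HysteresisLoop(
        loading_displacement=d,
        loading_force=f,
        unloading_displacement=d[::-1],
        unloading_force=(1.0 - q) * f[::-1],
    )


class TestSegmentCycles:
    def test_five_triangles_give_five_loops(self):
        loops = segment_cycles(triangle_record(n_cycles=5))
        assert len(loops) == 5
        assert [lp.cycle_index for lp in loops] == list(range(5))
        assert not any(lp.loading_only for lp in loops)

    def test_single_ramp_gives_loading_only_loop(self):
        d = np.linspace(0.0, 9.0, 40)
        rec = CompressionRecord(
            time=np.arange(40.0), displacement=d, force=2 * d,
            displacement_rate=1.0, geometry=GEOM,
        )
        loops = segment_cycles(rec)
        assert len(loops) == 1
        assert loops[0].loading_only
        assert len(loops[0].unloading_displacement) == 0

    def test_flat_record_rejected(self):
        rec = CompressionRecord(
            time=np.arange(10.0), displacement=np.zeros(10), force=np.zeros(10),
            displacement_rate=1.0, geometry=GEOM,
        )
        with pytest.raises(ValueError):
            segment_cycles(rec)

    def test_branches_meet_at_peak(self):
        for loop in segment_cycles(triangle_record(n_cycles=3)):
            assert loop.loading_displacement[-1] == pytest.approx(
                loop.unloading_displacement[0]
            )

    def test_small_wiggles_do_not_split_cycles(self):
        rec = triangle_record(n_cycles=2)
        wiggled = rec.displacement + 0.002 * np.sin(np.arange(len(rec)) * 2.1)
        wiggled = np.clip(wiggled, 0.0, GEOM.height)
        rec2 = CompressionRecord(
            time=rec.time, displacement=wiggled, force=rec.force,
            displacement_rate=1.96, geometry=GEOM,
        )
        assert len(segment_cycles(rec2)) == 2


class TestEnergyDissipationRatio:
    def test_identical_branches_dissipate_nothing(self):
        assert energy_dissipation_ratio(scaled_loop(0.0)).edr == pytest.approx(0.0, abs=1e-15)

    def test_zero_unloading_force_dissipates_everything(self):
        assert energy_dissipation_ratio(scaled_loop(1.0)).edr == pytest.approx(1.0, abs=1e-15)

    def test_pointwise_scaling_sets_the_ratio(self):
        res = energy_dissipation_ratio(scaled_loop(0.22))
        assert res.edr == pytest.approx(0.22, abs=1e-12)
        assert res.hysteresis_area == pytest.approx(0.22 * res.loading_area)

    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.9])
    def test_round_trip_is_exact_for_scaled_construction(self, q):
        assert energy_dissipation_ratio(scaled_loop(q)).edr == pytest.approx(q, abs=1e-10)

    def test_area_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            res = energy_dissipation_ratio(scaled_loop(rng.uniform(0.0, 0.99)))
            assert res.hysteresis_area <= res.loading_area

    def test_refinement_convergence_on_cubic_loop(self):
        # loading F = d³, unloading F = (d³ sampled then trapezoid) — use a
        # non-scaled smooth loop with known exact EDR: load d², unload d³
        # over [0, 1]: A_load = 1/3, A_unload = 1/4, EDR = 1/4.
        def loop(n):
            d = np.linspace(0.0, 1.0, n)
            return HysteresisLoop(
                loading_displacement=d,
                loading_force=d**2,
                unloading_displacement=d[::-1],
                unloading_force=d[::-1] ** 3,
            )

        exact = 0.25
        err_n = abs(energy_dissipation_ratio(loop(50)).edr - exact)
        err_2n = abs(energy_dissipation_ratio(loop(100)).edr - exact)
        assert err_2n < err_n / 2  # trapezoid rule is O(1/n²)

    def test_loading_only_loop_rejected(self):
        loop = HysteresisLoop(
            loading_displacement=np.linspace(0, 9, 10),
            loading_force=np.linspace(0, 40, 10),
            unloading_displacement=np.empty(0),
            unloading_force=np.empty(0),
            loading_only=True,
        )
        with pytest.raises(ValueError, match="unloading"):
            energy_dissipation_ratio(loop)

    def test_zero_loading_area_rejected(self):
        loop = HysteresisLoop(
            loading_displacement=np.linspace(0, 9, 10),
            loading_force=np.zeros(10),
            unloading_displacement=np.linspace(9, 0, 10),
            unloading_force=np.zeros(10),
        )
        with pytest.raises(ValueError, match="area"):
            energy_dissipation_ratio(loop)


class TestRepeatability:
    def make_loops(self, peaks):
        out = []
        for k, p in enumerate(peaks):
            d = np.linspace(0.0, 9.0, 10)
            f = np.linspace(0.0, p, 10)
            out.append(
                HysteresisLoop(
                    loading_displacement=d, loading_force=f,
                    unloading_displacement=d[::-1], unloading_force=0.8 * f[::-1],
                    cycle_index=k,
                )
            )
        return out

    def test_tight_peaks_pass(self):
        res = repeatability_check(self.make_loops([40.0, 41.0, 39.0, 40.0, 40.0]))
        assert res.passed
        assert np.max(np.abs(res.deviations_frac_of_max)) < 0.025

    def test_wide_spread_fails(self):
        assert not repeatability_check(self.make_loops([40.0, 46.0])).passed

    def test_equal_peaks_pass_with_zero_deviation(self):
        res = repeatability_check(self.make_loops([40.0, 40.0, 40.0]))
        assert res.passed
        np.testing.assert_array_equal(res.deviations, 0.0)

    def test_single_loop_rejected(self):
        with pytest.raises(ValueError):
            repeatability_check(self.make_loops([40.0]))

    def test_both_normalizations_reported(self):
        res = repeatability_check(self.make_loops([40.0, 44.0]))
        # deviations ±2 N; vs max 44 N and vs mean 42 N
        np.testing.assert_allclose(res.deviations, [-2.0, 2.0])
        np.testing.assert_allclose(res.deviations_frac_of_max, [-2 / 44, 2 / 44])
        np.testing.assert_allclose(res.deviations_frac_of_mean, [-2 / 42, 2 / 42])
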