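"""Echogram chain: filters vs brute-force window oracles, lines, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_fan
from wcdetect import NoiseConfig, SurveyConfig, TargetSpec, generate_survey
from wcdetect.echogram import (
    StackedEchogram,
    VirtualLine,
    best_bottom_candidate,
    dilate_3x3,
    erosion_3x3,
    exclusion_mask,
    median_3x3,
    reject_bad_pings,
    select_pings_of_interest,
    smooth_fan_45,
    stack_max_intensity,
    threshold_offset_line,
)
from wcdetect.seafloor import build_and_resample_tin


def make_echogram(values, range_bin=1.0):
    values = np.asarray(values, dtype=float)
    ranges = (np.arange(values.shape[1]) + 0.5) * range_bin
    return StackedEchogram(values, np.arange(values.shape[0]), ranges)


def window_oracle(values, stat, exclude_center=False):
    """Brute-force replicate-padded 3x3 sliding-window statistic."""
    n, m = values.shape
    out = np.empty_like(values, dtype=float)
    for i in range(n):
        for j in range(m):
            win = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if exclude_center and di == 0 and dj == 0:
                        continue
                    ii = min(max(i + di, 0), n - 1)
                    jj = min(max(j + dj, 0), m - 1)
                    win.append(values[ii, jj])
            out[i, j] = stat(win)
    return out


rand_matrix = arrays(
    float, st.tuples(st.integers(3, 12), st.integers(3, 12)),
    elements=st.floats(-90, -20),
)


class TestConvolutionFilters:
    @pytest.mark.parametrize(
        "filt,stat,exclude",
        [
            (median_3x3, np.median, False),
            (erosion_3x3, np.min, False),
            (dilate_3x3, np.max, True),
        ],
        ids=["median", "erosion", "dilate"],
    )
    def test_equals_bruteforce_window_oracle_on_random_matrix(self, filt, stat, exclude):
        rng = np.random.default_rng(42)
        values = rng.uniform(-90, -30, size=(20, 20))
        out = filt(make_echogram(values)).values
        np.testing.assert_allclose(out, window_oracle(values, stat, exclude))

    @pytest.mark.parametrize("filt", [median_3x3, erosion_3x3, dilate_3x3])
    def test_constant_matrix_unchanged(self, filt):
        e = make_echogram(np.full((6, 7), -70.0))
        np.testing.assert_allclose(filt(e).values, -70.0)

    def test_single_impulse_erased_by_median_and_erosion(self):
        values = np.full((9, 9), -80.0)
        values[4, 4] = -30.0
        for filt in (median_3x3, erosion_3x3):
            np.testing.assert_allclose(filt(make_echogram(values)).values, -80.0)

    def test_dilation_impulse_spreads_to_exactly_eight_neighbours(self):
        values = np.full((9, 9), -80.0)
        values[4, 4] = -30.0
        out = dilate_3x3(make_echogram(values)).values
        hot = np.argwhere(out == -30.0)
        expected = {(i, j) for i in (3, 4, 5) for j in (3, 4, 5)} - {(4, 4)}
        assert {tuple(r) for r in hot} == expected
        assert out[4, 4] == -80.0  # centre excluded from its own window

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rand_matrix)
    def test_erosion_below_input_and_dilation_ordering(self, values):
        e = make_echogram(values)
        assert np.all(erosion_3x3(e).values <= values + 1e-12)
        assert np.all(np.maximum(values, dilate_3x3(e).values) >= values)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(rand_matrix, rand_matrix)
    def test_filters_monotone_in_input(self, a, b):
        if a.shape != b.shape:
            return
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        for filt in (median_3x3, erosion_3x3, dilate_3x3):
            assert np.all(
                filt(make_echogram(lo)).values <= filt(make_echogram(hi)).values + 1e-12
            )

    def test_nodata_propagates_through_filters(self):
        values = np.full((5, 5), -70.0)
        values[2, 2] = np.nan
        for filt in (median_3x3, erosion_3x3, dilate_3x3):
            out = filt(make_echogram(values)).values
            assert np.isnan(out[2, 2])
            assert np.isfinite(out[0, 0])


class TestStacking:
    def test_single_beam_fan_is_identity(self):
        profile = np.linspace(-90, -40, 30)
        fan = make_fan(profile[None, None, :].repeat(1, axis=0))
        out = stack_max_intensity([fan])
        np.testing.assert_allclose(out.values[0], profile)

    def test_matches_bruteforce_per_range_maximum(self):
        rng = np.random.default_rng(0)
        sv = rng.uniform(-90, -40, size=(2, 4, 25)).astype(np.float32)
        fan = make_fan(sv)
        out = stack_max_intensity([fan]).values[0]
        oracle = [max(sv[t, b, r] for t in range(2) for b in range(4))
                  for r in range(25)]
        np.testing.assert_allclose(out, oracle, rtol=1e-6)

    def test_permutation_invariant_over_beams(self):
        rng = np.random.default_rng(1)
        sv = rng.uniform(-90, -40, size=(2, 6, 10)).astype(np.float32)
        perm = rng.permutation(6)
        a = stack_max_intensity([make_fan(sv)]).values
        b = stack_max_intensity([make_fan(sv[:, perm, :])]).values
        np.testing.assert_array_equal(a, b)

    def test_all_nodata_range_bin_stays_nodata(self):
        sv = np.full((2, 3, 8), -70.0, dtype=np.float32)
        sv[:, :, 5] = np.nan
        out = stack_max_intensity([make_fan(sv)]).values
        assert np.isnan(out[0, 5]) and np.isfinite(out[0, 4])

    def test_empty_ping_set_raises(self):
        with pytest.raises(ValueError):
            stack_max_intensity([])


class TestBadPings:
    def test_background_ping_retained_and_saturated_removed(self):
        values = np.full((3, 20), -85.0)
        values[1] = -50.0  # all bins hot through the full range extent
        e = make_echogram(values)
        kept = reject_bad_pings(e, frac_threshold=0.9, sv_threshold=-70.0)
        assert list(kept) == [0, 2]

    def test_agrees_with_direct_fraction_count(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(-90, -40, size=(30, 40))
        e = make_echogram(values)
        kept = set(reject_bad_pings(e, 0.5, -65.0))
        for p in range(30):
            frac = np.mean(values[p] > -65.0)
            assert (p in kept) == (frac < 0.5)


class TestVirtualLines:
    def _flat_seabed_survey(self, depth=20.0):
        cfg = SurveyConfig(water_depth=depth, area_side=60.0, n_transects=1,
                           transect_spacing=10.0, pings_per_transect=20,
                           n_beams_per_transducer=32, seed=2)
        return cfg, generate_survey(cfg)

    def test_flat_seabed_line_within_one_range_bin(self):
        cfg, fans = self._flat_seabed_survey()
        stacked = stack_max_intensity(fans)
        line = best_bottom_candidate(stacked, 5, cfg.background_sv + 30)
        assert np.all(np.isfinite(line.ranges))
        assert np.all(np.abs(line.ranges - cfg.water_depth) <= 2 * cfg.range_bin)

    def test_midwater_blob_ignored_by_bottom_pick(self):
        cfg = SurveyConfig(water_depth=20.0, area_side=60.0, n_transects=1,
                           transect_spacing=10.0, pings_per_transect=20,
                           n_beams_per_transducer=32, seed=2)
        blob = TargetSpec("FISH", anchor=(4.0, 30.0, 10.0), dims=(6.0, 5.0, 3.0),
                          sv_offset=15.0)
        fans = generate_survey(cfg, [blob])
        stacked = stack_max_intensity(fans)
        line = best_bottom_candidate(stacked, 5, cfg.background_sv + 30)
        assert np.all(np.abs(line.ranges - cfg.water_depth) <= 2 * cfg.range_bin)

    def test_no_seabed_echo_gives_undefined_line(self):
        e = make_echogram(np.full((6, 30), -85.0))
        line = best_bottom_candidate(e, 5, -55.0)
        assert np.all(np.isnan(line.ranges))

    def test_bubble_layer_crossing_found(self):
        # layer of hot bins down to 3 m, reference at the surface
        values = np.full((4, 30), -85.0)
        values[:, :3] = -60.0  # bins 0..2 -> layer bottom boundary at 3.0 m
        e = make_echogram(values, range_bin=1.0)
        ref = VirtualLine(np.arange(4), np.zeros(4), kind="surface-exclusion")
        line = threshold_offset_line(e, ref, -70.0, offset=0.5)
        np.testing.assert_allclose(line.ranges, 4.0)  # 3.5 m crossing + offset

    def test_no_crossing_falls_back_to_reference_plus_offset(self):
        e = make_echogram(np.full((4, 30), -85.0))
        ref = VirtualLine(np.arange(4), np.full(4, 2.0), kind="surface-exclusion")
        line = threshold_offset_line(e, ref, -70.0, offset=1.0)
        np.testing.assert_allclose(line.ranges, 3.0)

    def test_monotone_profile_crossing_matches_scan_oracle(self):
        profile = np.linspace(-90, -50, 40)
        e = make_echogram(profile[None, :].repeat(3, axis=0))
        ref = VirtualLine(np.arange(3), np.zeros(3), kind="surface-exclusion")
        line = threshold_offset_line(e, ref, -70.0, offset=0.0)
        # scan oracle: first bin boundary where profile crosses -70
        j = next(j for j in range(39) if (profile[j] > -70) != (profile[j + 1] > -70))
        np.testing.assert_allclose(line.ranges, e.range_axis[j + 1])


class TestPingSelection:
    def test_empty_scene_retains_no_pings(self):
        cfg = SurveyConfig(water_depth=20.0, area_side=60.0, n_transects=1,
                           transect_spacing=10.0, pings_per_transect=15,
                           n_beams_per_transducer=32, seed=4)
        fans = generate_survey(cfg)
        stacked = stack_max_intensity(fans)
        cleaned = erosion_3x3(median_3x3(stacked))
        bottom = best_bottom_candidate(cleaned, 5, cfg.background_sv + 30)
        poi = select_pings_of_interest(cleaned, None, bottom, cfg.background_sv + 10)
        assert len(poi) == 0

    def test_fish_school_pings_selected_and_monotone_under_adding_targets(self):
        cfg = SurveyConfig(water_depth=20.0, area_side=60.0, n_transects=1,
                           transect_spacing=10.0, pings_per_transect=30,
                           n_beams_per_transducer=32, seed=4)
        blob = TargetSpec("FISH", anchor=(8.0, 30.0, 10.0), dims=(6.0, 5.0, 3.0),
                          sv_offset=18.0)
        blob2 = TargetSpec("FISH", anchor=(18.0, 25.0, 8.0), dims=(6.0, 5.0, 3.0),
                           sv_offset=18.0)

        def poi_for(targets):
            fans = generate_survey(cfg, targets)
            stacked = stack_max_intensity(fans)
            cleaned = erosion_3x3(median_3x3(stacked))
            bottom = best_bottom_candidate(cleaned, 5, cfg.background_sv + 30)
            return set(select_pings_of_interest(cleaned, None, bottom,
                                                cfg.background_sv + 10))

        one = poi_for([blob])
        truth_pings = {
            f.ping_id for f in generate_survey(cfg, [blob]) if (f.ground_truth == 1).any()
        }
        assert one and one <= {p for t in truth_pings for p in (t - 1, t, t + 1)}
        assert one <= poi_for([blob, blob2])  # superset monotonicity


class TestFanSmoothing:
    def test_constant_field_unchanged(self):
        sv = np.full((2, 8, 10), -60.0, dtype=np.float32)
        fans = [make_fan(sv, ping_id=i) for i in range(5)]
        out = smooth_fan_45(fans, 2)
        np.testing.assert_allclose(out.sv, -60.0, atol=1e-4)

    def test_impulse_spreads_over_45_cells_with_equal_weight(self):
        fans = []
        for i in range(5):
            sv = np.zeros((1, 9, 9), dtype=np.float32)  # 0 dB = power 1
            if i == 2:
                sv[0, 4, 4] = 10.0 * np.log10(46.0)  # power 46 impulse
            fans.append(make_fan(sv, ping_id=i))
        out = smooth_fan_45(fans, 2)
        power = 10 ** (out.sv[0].astype(float) / 10)
        # kernel cell count = 45: mean at the impulse = (45 + 45)/45 = 2
        np.testing.assert_allclose(power[4, 4], (46.0 + 44.0) / 45.0, rtol=1e-5)
        affected = power > 1.0 + 1e-6
        assert affected.sum() == 9  # 3x3 in (beam, range) for the centre ping

    def test_kernel_spans_three_beams_five_pings_three_bins(self):
        # an impulse two pings away still contributes; three pings away not
        fans = []
        for i in range(7):
            sv = np.zeros((1, 5, 5), dtype=np.float32)
            if i == 0:
                sv[0, 2, 2] = 30.0
            fans.append(make_fan(sv, ping_id=i))
        assert np.max(smooth_fan_45(fans, 2).sv) > 1.0
        assert np.max(smooth_fan_45(fans, 3).sv) < 0.5

    def test_short_sequences_replicate_padded(self):
        sv = np.full((1, 5, 5), -60.0, dtype=np.float32)
        out = smooth_fan_45([make_fan(sv)], 0)
        np.testing.assert_allclose(out.sv, -60.0, atol=1e-4)


class TestExclusionMask:
    def test_near_field_and_tin_offset_rules(self):
        # flat TIN at 20 m from synthetic soundings
        g = np.mgrid[0:40:5, 0:40:5].reshape(2, -1).T
        tin = build_and_resample_tin(np.column_stack([g, np.full(len(g), 20.0)]))
        sv = np.full((2, 16, 30), -70.0, dtype=np.float32)
        angles = np.stack([np.linspace(-20, -1, 16), np.linspace(1, 20, 16)])
        fan = make_fan(sv, range_bin=1.0, nav=(20.0, 20.0, 90.0), angles=angles)
        mask = exclusion_mask(fan, tin, near_field=4.0, tin_offset=2.0)
        depth = fan.geometry.depth
        ranges = fan.geometry.ranges[None, None, :].repeat(2, 0).repeat(16, 1)
        assert mask[ranges < 4.0].all()  # within 4 m of the transducer face
        mid = (ranges > 5) & (depth < 15)
        assert not mask[mid].any()  # mid-water samples retained
        near_bottom = depth > 19.0  # 1 m above a 20 m seafloor, 2 m offset
        assert mask[near_bottom].all()

    def test_undefined_tin_excludes_conservatively(self):
        g = np.mgrid[0:10:3, 0:10:3].reshape(2, -1).T
        tin = build_and_resample_tin(np.column_stack([g, np.full(len(g), 20.0)]))
        sv = np.full((2, 8, 25), -70.0, dtype=np.float32)
        fan = make_fan(sv, nav=(500.0, 500.0, 90.0))  # far outside the TIN
        mask = exclusion_mask(fan, tin, near_field=4.0, tin_offset=1.0)
        assert mask.all()
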