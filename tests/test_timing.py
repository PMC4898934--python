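"""NEBD, anaphase, duration and metaphase-length detection."""

import numpy as np
import pytest

from sirs_quant.cohorts import timing_cohort
from sirs_quant.errors import (NoAnaphaseError, NoMetaphaseError, NoNEBDError)
from sirs_quant.foci import segment_movie
from sirs_quant.synthetic import generate_movie
from sirs_quant.timing import (EventTimes, detect_anaphase, detect_nebd,
                               geminin_trace, metaphase_length,
                               nebd_to_anaphase)


class TestDetectNEBD:
    def test_linear_interpolation_of_half_max_crossing(self):
        t = detect_nebd([1.0, 0.8, 0.4, 0.1], [0, 2, 4, 6])
        assert t == pytest.approx(2 + 2 * (0.8 - 0.5) / (0.8 - 0.4))  # 3.5 min

    def test_trace_never_below_half_max_raises(self):
        with pytest.raises(NoNEBDError):
            detect_nebd([1.0, 0.9, 0.8, 0.7, 0.6], [0, 1, 2, 3, 4])

    def test_transient_dip_without_persistence_ignored(self):
        b = [1.0, 0.4, 0.9, 0.9, 0.3, 0.2, 0.1]
        t = detect_nebd(b, list(range(7)))
        assert t > 3  # the frame-1 dip recovers, the frame-4 drop persists


class TestGemininTrace:
    def test_step_trace_starts_high_and_ends_low(self, wt_movie):
        movie, _ = wt_movie
        b = geminin_trace(movie)
        assert b[0] > 0.9
        assert b[-1] < 0.1
        assert b.min() == 0.0 and b.max() == 1.0

    def test_intensity_scaling_leaves_trace_unchanged(self, wt_movie):
        movie, _ = wt_movie
        b1 = geminin_trace(movie)
        movie.pixels = movie.pixels * 3.0
        b2 = geminin_trace(movie)
        movie.pixels = movie.pixels / 3.0
        assert np.allclose(b1, b2, atol=1e-12)

    def test_geminin_and_clusteredness_decline_synchronously(self, quiet_wt_preset):
        """Half-max crossings of B_t and K_t within one frame of each other."""
        from sirs_quant.clusteredness import clusteredness_series

        def half_cross(series, times):
            for i in range(len(series) - 1):
                if series[i] >= 0.5 > series[i + 1]:
                    return times[i]
            return None

        close = 0
        n = 10
        for seed in range(n):
            movie, _ = generate_movie(quiet_wt_preset, seed)
            foci_sets = segment_movie(movie)
            b = geminin_trace(movie)
            _, k_t = clusteredness_series(movie, foci_sets)
            tb = half_cross(b, movie.times)
            tk = half_cross(k_t, movie.times)
            if tb is not None and tk is not None and abs(tb - tk) <= movie.frame_interval:
                close += 1
        assert close >= 0.9 * n


class TestDetectAnaphase:
    def test_static_movie_has_no_anaphase(self):
        movie, _ = generate_movie("pre_division", 2)
        cents = [f.centroids for f in segment_movie(movie)]
        with pytest.raises(NoAnaphaseError):
            detect_anaphase(cents, movie.times)

    def test_dispersal_without_segregation_has_no_anaphase(self):
        """Spindle-poisoned cells complete SIRS but never segregate."""
        from sirs_quant.clusteredness import clusteredness_series
        movie, _ = generate_movie("colcemid_like", 4)
        foci_sets = segment_movie(movie)
        with pytest.raises(NoAnaphaseError):
            detect_anaphase([f.centroids for f in foci_sets], movie.times)
        _, k_t = clusteredness_series(movie, foci_sets)
        assert k_t[-1] < 0.2  # clusteredness still completed its decline

    def test_detection_invariant_to_image_rotation(self, wt_movie):
        from sirs_quant.io_core import Movie
        movie, _ = wt_movie
        ana = detect_anaphase([f.centroids for f in segment_movie(movie)], movie.times)
        rot = Movie(pixels=np.rot90(movie.pixels, axes=(2, 3)).copy(),
                    pixel_size=movie.pixel_size, frame_interval=movie.frame_interval)
        ana_rot = detect_anaphase([f.centroids for f in segment_movie(rot)], rot.times)
        assert ana_rot.frame == ana.frame


class TestDurations:
    def test_duration_is_difference_of_event_times(self):
        ev = EventTimes(t_nebd=3.5, t_anaphase=20.5)
        assert nebd_to_anaphase(ev) == pytest.approx(17.0)

    def test_equal_event_times_give_zero(self):
        assert nebd_to_anaphase(EventTimes(t_nebd=5.0, t_anaphase=5.0)) == 0.0

    def test_anaphase_before_nebd_is_inconsistent(self):
        with pytest.raises(ValueError, match="inconsistent"):
            nebd_to_anaphase(EventTimes(t_nebd=10.0, t_anaphase=5.0))


class TestMetaphase:
    def test_plate_time_recovered_on_noise_free_movies(self, quiet_wt_preset):
        hits = 0
        n = 8
        for seed in range(n):
            movie, truth = generate_movie(quiet_wt_preset, seed)
            cents = [f.centroids for f in segment_movie(movie)]
            ana = detect_anaphase(cents, movie.times)
            _, t_plate = metaphase_length(cents, movie.times, ana)
            if abs(t_plate - truth.t_plate_true) <= movie.frame_interval:
                hits += 1
        assert hits >= n - 1

    def test_identical_presets_give_fold_change_near_one(self):
        a = timing_cohort("tetraploid_no_diplo", n=15, seed=5)
        b = timing_cohort("tetraploid_no_diplo", n=15, seed=6)
        ratio = np.mean(a.metaphase_lengths) / np.mean(b.metaphase_lengths)
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_no_metaphase_when_plate_never_forms(self):
        # synthetic centroid history with constant spread and a late jump
        rng = np.random.default_rng(0)
        cents = [rng.normal(0, 5, size=(6, 2)) + 24 for _ in range(10)]
        cents += [np.vstack([rng.normal(0, 1, (3, 2)) + [40, 24],
                             rng.normal(0, 1, (3, 2)) + [8, 24]]) for _ in range(4)]
        from sirs_quant.timing import AnaphaseCall
        ana = AnaphaseCall(time=10.0, frame=10, axis=np.array([1.0, 0.0]),
                           separation=np.array([]))
        with pytest.raises(NoMetaphaseError):
            metaphase_length(cents, np.arange(14.0), ana)
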