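"""Plate profiles, aggregates and anaphase-error detectors."""

import numpy as np
import pytest
from scipy.stats import ttest_ind

from sirs_quant.errors import InsufficientFootageError
from sirs_quant.foci import segment_movie
from sirs_quant.plate import (aggregate_profiles, detect_bridge,
                              detect_lagging, orient_and_profile)
from sirs_quant.synthetic import generate_movie
from sirs_quant.timing import AnaphaseCall, detect_anaphase


def _anaphase(movie):
    return detect_anaphase([f.centroids for f in segment_movie(movie)], movie.times)


class TestProfiles:
    def test_uniform_bar_gives_flat_profile(self):
        from sirs_quant.io_core import Movie
        px = np.zeros((6, 2, 64, 64))
        px[:, 0, 20:44, 20:44] = 50.0  # uniform square plate
        movie = Movie(pixels=px, frame_interval=1.0)
        ana = AnaphaseCall(time=3.0, frame=3, axis=np.array([1.0, 0.0]),
                          separation=np.array([]))
        prof = orient_and_profile(movie, ana)
        inner = prof.profile[10:90]  # away from the padded edges
        assert np.all(np.abs(inner - 0.01) < 0.0035)

    def test_profile_sums_to_one(self, wt_movie):
        movie, _ = wt_movie
        prof = orient_and_profile(movie, _anaphase(movie))
        assert prof.profile.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(prof.profile) == 100

    def test_mirror_symmetric_plate_has_high_mirror_correlation(self):
        from sirs_quant.io_core import Movie
        from sirs_quant.synthetic import render_frame
        spots = []
        for dx, amp in [(3, 120.0), (7, 90.0), (11, 60.0)]:
            spots += [(32.0 - dx, 32.0, amp), (32.0 + dx, 32.0, amp)]
        frame = render_frame(spots, (64, 64), 1.5)
        px = np.stack([np.stack([frame, np.zeros_like(frame)])] * 6)
        movie = Movie(pixels=px, frame_interval=1.0)
        ana = AnaphaseCall(time=3.0, frame=3, axis=np.array([1.0, 0.0]),
                          separation=np.array([]))
        prof = orient_and_profile(movie, ana)
        assert prof.mirror_corr > 0.99

    def test_profiles_invariant_to_90_degree_rotation(self, quiet_wt_movie):
        from sirs_quant.io_core import Movie
        movie, _ = quiet_wt_movie
        p1 = orient_and_profile(movie, _anaphase(movie))
        rot = Movie(pixels=np.rot90(movie.pixels, axes=(2, 3)).copy(),
                    pixel_size=movie.pixel_size, frame_interval=movie.frame_interval)
        p2 = orient_and_profile(rot, _anaphase(rot))
        assert np.abs(p1.profile - p2.profile).max() < 0.02 * p1.profile.max()

    def test_incomplete_dispersal_widens_plate_signal(self):
        """mad2 cells whose clusters never separated show broader plates."""
        wt_sd, mad_sd = [], []
        for seed in range(20):
            movie, _ = generate_movie("wt_timing", seed)
            wt_sd.append(orient_and_profile(movie, _anaphase(movie)).sd)
        seed = 0
        while len(mad_sd) < 20:
            movie, truth = generate_movie("mad2_timing", seed)
            seed += 1
            if truth.dispersal_complete:
                continue
            mad_sd.append(orient_and_profile(movie, _anaphase(movie)).sd)
        p = ttest_ind(mad_sd, wt_sd, alternative="greater").pvalue
        assert p < 0.05


class TestAggregation:
    def test_identical_profiles_have_zero_width_ci(self):
        prof = np.full(100, 0.01)
        mean, lo, hi = aggregate_profiles([prof] * 5, n_boot=200, seed=1)
        assert np.allclose(mean, prof)
        assert np.allclose(hi - lo, 0.0)

    def test_mean_profile_sums_to_one(self):
        rng = np.random.default_rng(0)
        profs = [p / p.sum() for p in rng.uniform(0.5, 1.5, size=(4, 100))]
        mean, _, _ = aggregate_profiles(profs, n_boot=100, seed=0)
        assert mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bootstrap_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        profs = [p / p.sum() for p in rng.uniform(0.5, 1.5, size=(6, 100))]
        a = aggregate_profiles(profs, n_boot=300, seed=7)
        b = aggregate_profiles(profs, n_boot=300, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles([np.full(100, 0.01)])


class TestErrorDetectors:
    def test_clean_divisions_are_not_flagged(self):
        false_pos = 0
        for seed in range(20):
            movie, truth = generate_movie("wt_timing", seed)
            ana = _anaphase(movie)
            assert truth.planted_error == "none"
            if detect_bridge(movie, ana) or detect_lagging(movie, ana):
                false_pos += 1
        assert false_pos <= 1

    def test_planted_bridges_and_lagging_detected(self):
        n_bridge = n_lag = hit_bridge = hit_lag = 0
        seed = 0
        while min(n_bridge, n_lag) < 10:
            movie, truth = generate_movie("mad2_diplo", seed)
            seed += 1
            ana = _anaphase(movie)
            if truth.planted_error == "bridge":
                n_bridge += 1
                hit_bridge += detect_bridge(movie, ana)
            elif truth.planted_error == "lagging":
                n_lag += 1
                hit_lag += detect_lagging(movie, ana)
        assert hit_bridge == n_bridge
        assert hit_lag == n_lag

    def test_movie_ending_before_offset_raises(self, wt_movie):
        movie, _ = wt_movie
        ana = _anaphase(movie)
        with pytest.raises(InsufficientFootageError):
            detect_bridge(movie, ana, offset_min=500.0)
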