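"""Generator tests: rendering, planted events, determinism, conservation."""

import numpy as np
import pytest

from sirs_quant.errors import ConfigurationError, OutOfBoundsError
from sirs_quant.synthetic import (DiscreteDist, NoiseParams, generate_movie,
                                  generate_spread, get_preset, render_frame)


class TestRenderFrame:
    def test_empty_spot_list_renders_black_frame(self):
        img = render_frame([], (32, 32), psf_sigma=1.5)
        assert img.shape == (32, 32)
        assert np.all(img == 0)

    def test_single_spot_peaks_at_its_centroid(self):
        img = render_frame([(20.0, 20.0, 100.0)], (40, 40), psf_sigma=1.5)
        assert np.unravel_index(img.argmax(), img.shape) == (20, 20)
        assert img[20, 20] == pytest.approx(100.0, rel=1e-6)

    def test_two_spot_render_is_sum_of_single_spot_renders(self):
        spots = [(10.0, 12.0, 80.0), (25.0, 20.0, 40.0)]
        both = render_frame(spots, (40, 40), psf_sigma=1.2)
        singles = sum(render_frame([s], (40, 40), psf_sigma=1.2) for s in spots)
        assert np.allclose(both, singles, atol=1e-12)
        assert both.sum() == pytest.approx(singles.sum(), rel=1e-12)

    def test_out_of_bounds_centroid_rejected(self):
        with pytest.raises(OutOfBoundsError):
            render_frame([(50.0, 10.0, 5.0)], (32, 32), psf_sigma=1.0)

    def test_noise_seeded_reproducibly(self):
        noise = NoiseParams(background=5.0, read_sd=2.0, poisson=True)
        a = render_frame([(16.0, 16.0, 60.0)], (32, 32), 1.0, noise=noise, seed=3)
        b = render_frame([(16.0, 16.0, 60.0)], (32, 32), 1.0, noise=noise, seed=3)
        assert np.array_equal(a, b)


class TestGenerateMovie:
    def test_identical_preset_and_seed_give_bit_identical_output(self):
        m1, t1 = generate_movie("wt_timing", 1)
        m2, t2 = generate_movie("wt_timing", 1)
        assert np.array_equal(m1.pixels, m2.pixels)
        assert t1.t_nebd_true == t2.t_nebd_true
        assert t1.planted_error == t2.planted_error

    def test_pre_division_cluster_count_in_preset_support(self):
        _, truth = generate_movie("pre_division", 2)
        assert truth.true_cluster_count in (4, 5)

    def test_preanaphase_flux_conserved_without_noise(self, quiet_wt_movie):
        movie, truth = quiet_wt_movie
        k_ana = int(round(truth.t_anaphase_true / movie.frame_interval))
        flux = movie.channel("kinetochore")[:k_ana].sum(axis=(1, 2))
        assert (flux.max() - flux.min()) / flux.mean() < 1e-6

    def test_event_ordering_nebd_before_anaphase(self):
        for seed in range(10):
            _, truth = generate_movie("wt_timing", seed)
            assert truth.t_nebd_true < truth.t_anaphase_true

    def test_movie_too_short_for_events_rejected(self):
        from dataclasses import replace
        short = replace(get_preset("wt_timing"), n_frames=10)
        with pytest.raises(ConfigurationError):
            generate_movie(short, 0)

    def test_cluster_count_distribution_recovered(self):
        dist = get_preset("pre_division").cluster_count_dist
        rng = np.random.default_rng(0)
        draws = [dist.sample(rng) for _ in range(1000)]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - dist.mean) < 3 * se + 1e-12


class TestGenerateSpread:
    def test_diploid_female_has_8_bodies_with_2_centromeres(self):
        _, truth = generate_spread("euploid_diploid", "female", 0)
        assert truth.n_bodies == 8
        assert truth.centromeres_per_body == [2] * 8

    def test_diplo_tetraploid_has_8_bodies_with_4_centromeres(self):
        _, truth = generate_spread("euploid_diplo_tetraploid", "female", 1)
        assert truth.n_bodies == 8
        assert truth.centromeres_per_body == [4] * 8

    def test_aneuploid_body_count_offset_in_range(self):
        for seed in range(8):
            _, truth = generate_spread("aneuploid_tetraploid", "female", seed)
            assert truth.n_bodies == 16 + truth.delta_pairs
            assert truth.delta_pairs in (-2, -1, 1, 2)

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_spread("octoploid", "female", 0)

    def test_male_polytene_has_5_bodies(self):
        _, truth = generate_spread("polytene", "male", 3)
        assert truth.n_bodies == 5


def test_discrete_dist_validates_probabilities():
    with pytest.raises(ValueError):
        DiscreteDist((1, 2), (0.5, 0.6))
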