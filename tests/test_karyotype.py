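"""Spread segmentation and configuration/ploidy classification."""

import numpy as np
import pytest

from sirs_quant.karyotype import classify_image, classify_spread, segment_spread
from sirs_quant.synthetic import SPREAD_CLASSES, generate_spread
from sirs_quant.synthetic.spread import SpreadImage

EXPECTED = {
    # planted class -> (ploidy_class, config_class)
    "euploid_diploid": ("euploid_diploid", "separated"),
    "euploid_tetraploid": ("euploid_tetraploid", "separated"),
    "separated": ("euploid_tetraploid", "separated"),
    "euploid_diplo_tetraploid": ("euploid_diplo_tetraploid", "separated"),
    "aneuploid_tetraploid": ("aneuploid_tetraploid", "separated"),
    "polytene": ("euploid_tetraploid", "polytene"),
    "clumped": ("euploid_tetraploid", "clumped"),
}


class TestSegmentation:
    def test_noiseless_diploid_spread_segments_exactly(self):
        image, truth = generate_spread("euploid_diploid", "female", 0, noise=None)
        seg = segment_spread(image)
        assert seg.n_bodies == 8
        assert seg.centromeres_per_body == [2] * 8
        assert seg.n_unassigned_marks == 0

    def test_polytene_female_has_haploid_number_of_bodies(self):
        image, _ = generate_spread("polytene", "female", 1, noise=None)
        assert segment_spread(image).n_bodies == 4

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segment_spread(np.zeros((2, 64, 64)))

    def test_stray_marks_left_unassigned(self):
        image, _ = generate_spread("euploid_diploid", "female", 2, noise=None)
        px = image.pixels.copy()
        from sirs_quant.synthetic.render import render_gaussian_blob
        render_gaussian_blob(px[1], 5.0, 5.0, 1.0, 300.0)  # mark in background
        seg = segment_spread(SpreadImage(pixels=px))
        assert seg.n_unassigned_marks == 1


class TestClassification:
    @pytest.mark.parametrize("planted", sorted(EXPECTED))
    def test_every_class_recovered_on_noiseless_spreads(self, planted):
        for seed in range(10):
            image, _ = generate_spread(planted, "female", seed, noise=None)
            call = classify_image(image, "female")
            assert (call.ploidy_class, call.config_class) == EXPECTED[planted], \
                f"{planted} seed {seed}"

    def test_aneuploid_body_counts_15_and_17_classified_aneuploid(self):
        seen = set()
        for seed in range(30):
            image, truth = generate_spread("aneuploid_tetraploid", "female", seed,
                                           noise=None)
            call = classify_image(image, "female")
            assert call.ploidy_class == "aneuploid_tetraploid"
            seen.add(call.n_bodies)
            if {15, 17} <= seen:
                break
        assert {15, 17} <= seen

    def test_classification_invariant_to_rotation_and_translation(self):
        image, _ = generate_spread("euploid_diplo_tetraploid", "female", 5, noise=None)
        base = classify_image(image, "female")
        rotated = SpreadImage(pixels=np.rot90(image.pixels, axes=(1, 2)).copy())
        shifted = SpreadImage(pixels=np.roll(image.pixels, (6, -9), axis=(1, 2)))
        for variant in (rotated, shifted):
            call = classify_image(variant, "female")
            assert call.ploidy_class == base.ploidy_class
            assert call.config_class == base.config_class

    def test_male_spreads_use_haploid_number_five(self):
        image, _ = generate_spread("euploid_diplo_tetraploid", "male", 0, noise=None)
        call = classify_image(image, "male")
        assert call.n_bodies == 10
        assert call.ploidy_class == "euploid_diplo_tetraploid"

    def test_unrecognized_inventory_falls_back_to_unclassified(self):
        image, _ = generate_spread("euploid_diploid", "female", 3, noise=None)
        seg = segment_spread(image)
        seg.body_areas = seg.body_areas[:5]  # simulate an implausible spread
        seg.body_centroids = seg.body_centroids[:5]
        seg.body_equiv_diameters = seg.body_equiv_diameters[:5]
        seg.marks_per_body = seg.marks_per_body[:5]
        seg.n_bodies = 5
        call = classify_spread(seg, "female")
        assert call.ploidy_class == "unclassified"

    def test_all_generator_classes_have_expectations(self):
        assert set(SPREAD_CLASSES) == set(EXPECTED)
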