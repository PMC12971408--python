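"""Generator: identity uniqueness, capture physics, quality grading."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from muzzleid.errors import ConfigurationError, GenerationError
from muzzleid.synthetic import (
    CaptureParams,
    grade_quality,
    make_individual,
    render_base_pattern,
    render_capture,
    sample_population,
)


def ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


class TestMakeIndividual:
    def test_equal_arguments_equal_specs(self):
        assert make_individual(7, "red_deer", "female") == make_individual(7, "red_deer", "female")

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            make_individual(-1)
        with pytest.raises(ConfigurationError):
            make_individual(0, species="unicorn")
        with pytest.raises(ConfigurationError):
            make_individual(0, sex="unknown")

    def test_distinct_seeds_distinct_tessellations(self):
        rendered = {
            render_base_pattern(make_individual(s), size=(64, 64)).tobytes()
            for s in range(100)
        }
        assert len(rendered) == 100

    def test_cross_identity_correlation_low(self):
        b0 = render_base_pattern(make_individual(0))
        b1 = render_base_pattern(make_individual(1))
        assert ncc(b0, b1) < 0.3


class TestBasePattern:
    def test_contrast_spans_full_scale(self):
        spec = make_individual(2)
        img = render_base_pattern(
            type(spec)(**{**spec.__dict__, "contrast": 1.0})
        )
        assert img.min() == 0.0 and img.max() == 1.0

    def test_default_contrast_span(self):
        img = render_base_pattern(make_individual(2))
        assert np.isclose(img.max() - img.min(), 0.7)

    def test_single_cell_valley_only_at_border(self):
        spec = make_individual(5)
        spec = type(spec)(**{**spec.__dict__, "n_cells": 1})
        img = render_base_pattern(spec)
        h, w = img.shape
        lo = img.min()
        interior = img[8 : h - 8, 8 : w - 8]
        # mask out the nostril ellipses, the only interior dark features
        yy, xx = np.mgrid[8 : h - 8, 8 : w - 8]
        near_nostril = np.zeros_like(interior, dtype=bool)
        for cx, cy, rx, ry in spec.nostril_geometry:
            near_nostril |= (
                ((xx - cx * w) / (rx * w + 3)) ** 2 + ((yy - cy * h) / (ry * h + 3)) ** 2 <= 1.2
            )
        assert (interior[~near_nostril] > lo + 0.2).all()
        # border ring is valley-dark
        assert (img[0] <= lo + 0.05).all() and (img[:, 0] <= lo + 0.05).all()

    def test_valley_fraction_close_to_threshold_count(self):
        spec = make_individual(6)
        img = render_base_pattern(spec)
        h, w = img.shape
        # expected valley fraction recomputed from the tessellation directly
        from muzzleid.synthetic import _tessellation_sites

        sites = _tessellation_sites(spec, (h, w))
        yy, xx = np.mgrid[0:h, 0:w]
        pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        dist, _ = cKDTree(sites).query(pix, k=2)
        expected = float(((dist[:, 1] - dist[:, 0]) < spec.valley_width).mean())
        # independent count: dark pixels of the rendered image
        lo = img.min()
        observed = float((img < lo + 0.25 * (img.max() - lo)).mean())
        assert abs(observed - expected) / expected < 0.2

    def test_degenerate_geometry_errors(self):
        spec = make_individual(1)
        bad = type(spec)(**{**spec.__dict__, "nostril_geometry": ((0.02, 0.3, 0.1, 0.1),) * 2})
        with pytest.raises(GenerationError):
            render_base_pattern(bad)
        with pytest.raises(GenerationError):
            render_base_pattern(spec, size=(32, 32))


class TestGradeQuality:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (CaptureParams(), "high"),
            (CaptureParams(occlusion_fraction=0.5), "unusable"),
            (CaptureParams(blur_sigma=1.5, occlusion_fraction=0.1), "medium"),
            (CaptureParams(blur_sigma=3.0), "unusable"),
            (CaptureParams(blur_sigma=0.8, occlusion_fraction=0.05, illumination_tilt=0.3), "high"),
            (CaptureParams(illumination_tilt=0.31), "medium"),
        ],
    )
    def test_rule_table(self, params, expected):
        assert grade_quality(params) == expected


class TestRenderCapture:
    def test_identity_capture_embeds_base_exactly(self):
        spec = make_individual(9)
        base = render_base_pattern(spec)
        record, ann = render_capture(spec, CaptureParams(), base=base)
        x0, y0, x1, y1 = (int(v) for v in ann.muzzle_rect)
        assert np.array_equal(record.image[y0:y1, x0:x1], base)

    def test_deterministic_given_seeds(self):
        spec = make_individual(9)
        p = CaptureParams(blur_sigma=1.0, noise_sd=0.02, capture_seed=3)
        r1, _ = render_capture(spec, p)
        r2, _ = render_capture(spec, p)
        assert np.array_equal(r1.image, r2.image)

    def test_capture_seeds_vary_image_not_identity(self):
        spec = make_individual(9)
        base = render_base_pattern(spec)
        r1, _ = render_capture(spec, CaptureParams(noise_sd=0.02, capture_seed=1), base=base)
        r2, _ = render_capture(spec, CaptureParams(noise_sd=0.02, capture_seed=2), base=base)
        assert r1.individual_id == r2.individual_id
        assert not np.array_equal(r1.image, r2.image)

    def test_overhead_foreshortening_shrinks_height(self):
        spec = make_individual(10)
        base = render_base_pattern(spec)
        _, ann_f = render_capture(spec, CaptureParams(), base=base)
        _, ann_o = render_capture(spec, CaptureParams(angle="overhead_45"), base=base)
        h_f = ann_f.muzzle_rect[3] - ann_f.muzzle_rect[1]
        h_o = ann_o.muzzle_rect[3] - ann_o.muzzle_rect[1]
        assert h_o < h_f


class TestSamplePopulation:
    def test_manifest_structure_and_protocol(self, small_population):
        m = small_population
        assert set(m.columns) >= {"individual_id", "image_path", "angle", "quality", "blacklisted"}
        per = m.groupby("individual_id")
        for _, grp in per:
            assert "0" in set(grp["angle"])  # at least one frontal
            assert "45" in set(grp["angle"])  # paired protocol overhead
            assert len(grp) in (2, 3)

    def test_images_per_individual_mean_matches_protocol(self, tmp_path):
        m = sample_population(60, tmp_path / "p", master_seed=1)
        mean = len(m) / 60
        assert 2.0 <= mean <= 2.5  # 2 w.p. 0.75, 3 w.p. 0.25 -> mean 2.25

    def test_reproducible_from_master_seed(self, tmp_path):
        m1 = sample_population(4, tmp_path / "a", master_seed=5)
        m2 = sample_population(4, tmp_path / "b", master_seed=5)
        assert list(m1["individual_id"]) == list(m2["individual_id"])
        assert list(m1["quality"]) == list(m2["quality"])
        img = m1["image_path"][0]
        img2 = m2["image_path"][0]
        assert open(img, "rb").read() == open(img2, "rb").read()

    def test_invalid_configuration(self, tmp_path):
        with pytest.raises(ConfigurationError):
            sample_population(1, tmp_path / "x")
        with pytest.raises(ConfigurationError):
            sample_population(3, tmp_path / "y", tier_mix={"high": 0.5, "medium": 0.2, "unusable": 0.2})

    def test_noiseless_preset_all_high(self, tmp_path):
        m = sample_population(4, tmp_path / "n", master_seed=2, noise="noiseless")
        assert (m["quality"] == "high").all()
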