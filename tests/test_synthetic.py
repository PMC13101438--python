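"""Generator: diameter law, g model, placement, rendering, determinism."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from myelinmorph.synthetic import (
    FiberTruth,
    PackingError,
    PopulationParams,
    RenderParams,
    lognormal_moment_params,
    place_fibers,
    render_sample,
    sample_population,
    truncated_lognormal_params,
    uf_reference_preset,
)


def small_pop(**over):
    base = dict(mean_diameter=0.93, sd_diameter=0.54, min_diameter=0.0,
                g_intercept=0.3591, g_slope=0.1193, g_noise_sd=0.0684,
                axis_ratio_range=(1.0, 1.7), target_density=844.36, seed=3)
    base.update(over)
    return PopulationParams(**base)


class TestDiameterLaw:
    def test_closed_form_moment_matching(self):
        # frozen from the closed form sigma^2 = ln(1+(sd/mean)^2)
        mu, sigma = lognormal_moment_params(1.0, 0.5)
        assert mu == pytest.approx(-0.1116, abs=1e-4)
        assert sigma == pytest.approx(0.4724, abs=1e-4)

    def test_closed_form_recovers_moments_monte_carlo(self):
        mu, sigma = lognormal_moment_params(1.0, 0.5)
        x = np.random.default_rng(0).lognormal(mu, sigma, 10**6)
        assert x.mean() == pytest.approx(1.0, abs=3 * 0.5 / 1000)
        assert x.std(ddof=1) == pytest.approx(0.5, abs=0.01)

    def test_truncated_params_give_requested_truncated_moments(self):
        mu, sigma = truncated_lognormal_params(0.93, 0.54, 0.37)
        x = np.random.default_rng(1).lognormal(mu, sigma, 10**6)
        x = x[x >= 0.37]
        se = 0.54 / math.sqrt(len(x))
        assert x.mean() == pytest.approx(0.93, abs=3 * se)
        assert x.std(ddof=1) == pytest.approx(0.54, abs=0.01)

    def test_truncated_reduces_to_closed_form_without_floor(self):
        assert truncated_lognormal_params(1.0, 0.5, 0.0) == pytest.approx(
            lognormal_moment_params(1.0, 0.5))

    def test_unsatisfiable_truncation_raises(self):
        with pytest.raises(ValueError):
            truncated_lognormal_params(0.5, 0.1, 3.0)
        with pytest.raises(ValueError):
            sample_population(small_pop(min_diameter=5.0), area_mm2=1.0)


class TestSamplePopulation:
    def test_moment_recovery_untruncated(self):
        # ~5.9 mm^2 gives ~5000 draws at the reference density
        truths = sample_population(small_pop(), area_mm2=5.9)
        d = np.array([t.inner_diameter for t in truths])
        assert len(d) == round(844.36 * 5.9)
        se = 0.54 / math.sqrt(len(d))
        assert d.mean() == pytest.approx(0.93, abs=3 * se)
        assert d.std(ddof=1) == pytest.approx(0.54, abs=0.03)

    def test_degenerate_population_is_identical(self):
        truths = sample_population(
            small_pop(sd_diameter=0.0, g_noise_sd=0.0), area_mm2=0.05)
        d = {t.inner_diameter for t in truths}
        g = {t.g_ratio for t in truths}
        assert len(d) == 1 and len(g) == 1

    def test_tiny_area_yields_empty_list(self):
        assert sample_population(small_pop(), area_mm2=1e-7) == []

    def test_zero_area_is_an_error(self):
        with pytest.raises(ValueError):
            sample_population(small_pop(), area_mm2=0.0)

    def test_truth_g_identity_and_qc_safe_range(self):
        truths = sample_population(small_pop(), area_mm2=0.5)
        for t in truths:
            assert t.g_ratio == pytest.approx(
                t.inner_diameter / (t.inner_diameter + 2 * t.myelin_thickness),
                abs=1e-9)
            assert 0.05 - 1e-12 <= t.g_ratio <= 0.95 + 1e-12
            assert t.eccentricity <= 0.81

    def test_determinism(self):
        a = sample_population(small_pop(), area_mm2=0.1)
        b = sample_population(small_pop(), area_mm2=0.1)
        assert a == b


class TestPlacement:
    def test_ample_space_places_all_disjoint(self):
        truths = sample_population(small_pop(), area_mm2=0.01)[:2]
        render = RenderParams()
        placed = place_fibers(truths, render, seed=5)
        assert len(placed) == 2
        (r0, c0), (r1, c1) = placed[0].center, placed[1].center
        envelopes = [
            (t.outer_diameter / 2) * math.sqrt(t.axis_ratio) / render.pixel_size
            for t in placed]
        dist = math.hypot(r0 - r1, c0 - c1)
        assert dist > sum(envelopes)

    def test_same_seed_identical_placements(self):
        truths = sample_population(small_pop(), area_mm2=0.013)
        render = RenderParams()
        assert place_fibers(truths, render, 9) == place_fibers(truths, render, 9)

    def test_impossible_density_raises(self):
        truths = sample_population(
            small_pop(target_density=150000, sd_diameter=0.1), area_mm2=0.0138)
        with pytest.raises(PackingError):
            place_fibers(truths, RenderParams(), seed=0)

    def test_oversized_fiber_raises(self):
        t = FiberTruth(fiber_id=1, center=(math.nan, math.nan),
                       inner_diameter=100.0, myelin_thickness=10.0,
                       g_ratio=100.0 / 120.0, axis_ratio=1.0, orientation=0.0)
        with pytest.raises(PackingError):
            place_fibers([t], RenderParams(), seed=0)


class TestRender:
    def test_rasterized_disk_area_matches_analytic(self):
        # d = 1.0 um at 0.166 um/px: pi * (0.5/0.166)^2 = 28.5 px
        t = FiberTruth(fiber_id=1, center=(50.2, 50.7), inner_diameter=1.0,
                       myelin_thickness=0.4, g_ratio=1.0 / 1.8,
                       axis_ratio=1.0, orientation=0.0)
        render = RenderParams(image_height=100, image_width=100,
                              psf_sigma=0, noise_sd=0, artifact_rate=0)
        sample = render_sample([t], render, seed=0)
        n_axon = int(sample.semantic_truth.axon.sum())
        assert abs(n_axon - math.pi * (0.5 / 0.166) ** 2) <= 2

    def test_empty_population_renders_background_only(self):
        render = RenderParams(psf_sigma=0, noise_sd=0, artifact_rate=0,
                              image_height=50, image_width=60)
        sample = render_sample([], render, seed=0)
        assert (sample.image == round(render.background_intensity)).all()
        assert not sample.semantic_truth.labels.any()
        assert not sample.instance_truth.labels.any()

    def test_noiseless_render_has_three_levels(self):
        t = FiberTruth(fiber_id=1, center=(25.0, 25.0), inner_diameter=1.5,
                       myelin_thickness=0.5, g_ratio=1.5 / 2.5,
                       axis_ratio=1.2, orientation=0.4)
        render = RenderParams(image_height=50, image_width=50,
                              psf_sigma=0, noise_sd=0, artifact_rate=0)
        sample = render_sample([t], render, seed=0)
        assert set(np.unique(sample.image)) == {
            round(render.background_intensity),
            round(render.axon_intensity),
            round(render.myelin_intensity)}

    def test_artifacts_touch_image_but_never_truth(self):
        t = FiberTruth(fiber_id=1, center=(60.0, 60.0), inner_diameter=1.0,
                       myelin_thickness=0.4, g_ratio=1.0 / 1.8,
                       axis_ratio=1.0, orientation=0.0)
        clean = RenderParams(image_height=120, image_width=120,
                             psf_sigma=0, noise_sd=0, artifact_rate=0)
        dirty = dataclasses.replace(clean, artifact_rate=20.0)
        a = render_sample([t], clean, seed=11)
        b = render_sample([t], dirty, seed=11)
        assert (a.semantic_truth.labels == b.semantic_truth.labels).all()
        assert (a.instance_truth.labels == b.instance_truth.labels).all()
        assert (b.image == 255).sum() > (a.image == 255).sum()

    def test_semantic_truth_is_collapse_of_instance_truth(self):
        pop, render = uf_reference_preset(seed=2)
        truths = place_fibers(
            sample_population(pop, render.image_area_mm2), render, seed=2)
        sample = render_sample(truths, render, seed=2)
        collapsed = sample.instance_truth.to_semantic()
        assert (collapsed.labels == sample.semantic_truth.labels).all()

    def test_bit_identical_given_seed(self):
        pop, render = uf_reference_preset(seed=4)
        truths = place_fibers(
            sample_population(pop, render.image_area_mm2), render, seed=4)
        a = render_sample(truths, render, seed=4)
        b = render_sample(truths, render, seed=4)
        assert (a.image == b.image).all()
        assert (a.instance_truth.labels == b.instance_truth.labels).all()


class TestPreset:
    def test_preset_is_constant(self):
        assert uf_reference_preset() == uf_reference_preset()

    def test_preset_g_model_at_mean_diameter(self):
        pop, _ = uf_reference_preset()
        g = pop.g_intercept + pop.g_slope * 0.93
        assert g == pytest.approx(0.47, abs=0.005)

    def test_preset_implied_thickness_at_mean_fiber(self):
        # d (1-g) / (2 g) at the printed means sits inside 0.48 +/- 0.14
        m = 0.93 * (1 - 0.47) / (2 * 0.47)
        assert m == pytest.approx(0.52, abs=0.01)
        assert 0.48 - 0.14 < m < 0.48 + 0.14

    def test_preset_population_mean_diameter(self):
        # ~5000 draws: sample mean within 3 SE of the 0.93 um target
        pop, _ = uf_reference_preset(seed=6)
        truths = sample_population(pop, area_mm2=5.9)
        d = np.array([t.inner_diameter for t in truths])
        assert d.mean() == pytest.approx(0.93, abs=3 * 0.54 / math.sqrt(len(d)))
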