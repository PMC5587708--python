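"""Ground-truth generator: point patterns, rendering, panels, time-lapse."""

import math

import numpy as np
import pytest

import punctaprox as pp


def _model(**kw):
    base = dict(
        cell_count=3, cell_radius_um=10.0, nucleus_fraction=0.3,
        green_density=0.1, red_density=0.05, coupling_fraction=0.0, seed=0,
    )
    base.update(kw)
    return pp.CouplingModel(**base)


class TestPointPattern:
    def test_same_seed_is_bit_identical(self):
        a = pp.simulate_point_pattern(_model(seed=9, coupling_fraction=0.5))
        b = pp.simulate_point_pattern(_model(seed=9, coupling_fraction=0.5))
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.red, cb.red)
            np.testing.assert_array_equal(ca.green, cb.green)
            np.testing.assert_array_equal(ca.coupled, cb.coupled)

    def test_different_seed_differs(self):
        a = pp.simulate_point_pattern(_model(seed=1))
        b = pp.simulate_point_pattern(_model(seed=2))
        assert not np.array_equal(a.cells[0].green, b.cells[0].green)

    def test_full_coupling_fixed_offset_distances(self):
        """With f=1 and a fixed offset law every non-fallback red punctum
        sits exactly at the offset from its recorded green partner."""
        truth = pp.simulate_point_pattern(
            _model(coupling_fraction=1.0, offset_law=pp.FixedOffset(0.3),
                   green_density=0.05, seed=4)
        )
        checked = 0
        for c in truth.cells:
            for i, coupled in enumerate(c.coupled):
                if coupled:
                    d = np.hypot(*(c.red[i] - c.green[c.partner[i]]))
                    assert d == pytest.approx(0.3, abs=1e-9)
                    checked += 1
        assert checked > 0

    def test_points_confined_to_cytoplasm(self):
        truth = pp.simulate_point_pattern(_model(seed=3, coupling_fraction=0.7,
                                                 offset_law=pp.FixedOffset(0.4)))
        for c in truth.cells:
            for pts in (c.red, c.green):
                if len(pts):
                    assert c.in_cytoplasm(pts).all()

    def test_csr_mean_nn_matches_poisson_closed_form(self):
        """f=0: mean red→nearest-green distance over many cells approaches
        1/(2 sqrt(lambda)) for the green Poisson process."""
        lam = 0.5
        dists = []
        for s in range(6):
            truth = pp.simulate_point_pattern(
                _model(cell_count=10, cell_radius_um=15, nucleus_fraction=0.2,
                       green_density=lam, red_density=0.05, seed=100 + s)
            )
            for c in truth.cells:
                if len(c.red) and len(c.green):
                    dists.append(pp.nn_distances(c.red, c.green))
        mean = float(np.concatenate(dists).mean())
        assert mean == pytest.approx(pp.csr_reference(lam).mean_nn_um, rel=0.05)

    def test_coupling_limit_offset_to_zero(self):
        truth = pp.simulate_point_pattern(
            _model(coupling_fraction=1.0, offset_law=pp.FixedOffset(1e-6), seed=5)
        )
        for c in truth.cells:
            if len(c.red) and len(c.green):
                assert pp.nn_distances(c.red, c.green).max() < 1e-5

    def test_rayleigh_offsets_scale_with_sigma(self):
        truth = pp.simulate_point_pattern(
            _model(cell_count=30, coupling_fraction=1.0,
                   offset_law=pp.RayleighOffset(0.2), green_density=0.05, seed=6)
        )
        offs = [
            np.hypot(*(c.red[i] - c.green[c.partner[i]]))
            for c in truth.cells
            for i in range(len(c.red))
            if c.coupled[i]
        ]
        # Rayleigh mean = sigma * sqrt(pi/2); rejection near borders biases
        # slightly, so compare loosely
        assert np.mean(offs) == pytest.approx(0.2 * math.sqrt(math.pi / 2), rel=0.15)

    def test_degenerate_nucleus_raises(self):
        with pytest.raises(ValueError, match="degenerate|nucleus"):
            _model(nucleus_fraction=1.0)


class TestRender:
    def test_no_points_no_noise_is_constant_background(self):
        truth = pp.simulate_point_pattern(_model(green_density=1e-9, red_density=1e-9))
        spec = pp.RenderSpec(noise_model="none")
        field = pp.render_field(truth, spec)
        for ch in ("red", "green"):
            assert np.all(field[ch].intensities == spec.background)

    def test_single_spot_centroid_matches_ground_truth(self):
        """Intensity-weighted centroid of one noiseless rendered spot lands
        within 0.25 px of the true point."""
        model = _model(cell_count=1)
        truth = pp.simulate_point_pattern(model)
        cell = truth.cells[0]
        pt = cell.cell_center + np.array([1.234, -0.777])
        cell.red = np.array([pt])
        cell.green = np.empty((0, 2))
        cell.coupled = np.array([False])
        cell.partner = np.array([-1])
        spec = pp.RenderSpec(noise_model="none")
        field = pp.render_field(truth, spec)
        img = field["red"].intensities - spec.background
        yy, xx = np.indices(img.shape)
        w = img.sum()
        cx = ((xx + 0.5) * img).sum() / w * spec.pixel_size_um
        cy = ((yy + 0.5) * img).sum() / w * spec.pixel_size_um
        assert abs(cx - pt[0]) < 0.25 * spec.pixel_size_um
        assert abs(cy - pt[1]) < 0.25 * spec.pixel_size_um

    def test_amplitude_linearity_without_noise(self):
        truth = pp.simulate_point_pattern(_model(seed=8))
        s1 = pp.RenderSpec(noise_model="none", spot_amplitude=50.0)
        s2 = pp.RenderSpec(noise_model="none", spot_amplitude=100.0)
        f1 = pp.render_field(truth, s1)
        f2 = pp.render_field(truth, s2)
        np.testing.assert_allclose(
            f2["green"].intensities - s2.background,
            2.0 * (f1["green"].intensities - s1.background),
            atol=1e-9,
        )

    def test_out_of_bounds_points_listed(self):
        truth = pp.simulate_point_pattern(_model(cell_count=1))
        truth.cells[0].red = np.array([[1e4, 1e4]])
        truth.cells[0].coupled = np.array([False])
        truth.cells[0].partner = np.array([-1])
        with pytest.raises(ValueError, match="outside image bounds"):
            pp.render_field(truth, pp.RenderSpec())

    def test_same_seed_renders_identically(self, coupled_truth):
        a = pp.render_field(coupled_truth, seed=3)
        b = pp.render_field(coupled_truth, seed=3)
        np.testing.assert_array_equal(a["red"].intensities, b["red"].intensities)


class TestPlaPanel:
    def test_zero_mean_gives_zero_puncta(self):
        panel = pp.simulate_pla_panel(
            [("none", 0.0)], n_images=3, cells_per_image=4, seed=1, render=False
        )
        assert all(c == 0 for c in panel.true_counts("none"))

    def test_total_counts_within_poisson_band(self):
        panel = pp.simulate_pla_panel(
            [("c", 10.0)], n_images=6, cells_per_image=10, seed=2, render=False
        )
        total = sum(panel.true_counts("c"))
        assert abs(total - 600) < 3 * math.sqrt(600)

    def test_condition_means_set_true_fold(self):
        panel = pp.simulate_pla_panel(
            [("lo", 2.0), ("hi", 6.0)], n_images=20, cells_per_image=10,
            seed=3, render=False,
        )
        lo = np.mean(panel.true_counts("lo"))
        hi = np.mean(panel.true_counts("hi"))
        assert hi / lo == pytest.approx(3.0, rel=0.15)


class TestTimelapse:
    def test_noiseless_normalized_step(self):
        traces = pp.simulate_timelapse(100.0, 2.0, rise_frame=4, n_frames=6,
                                       noise_sd=0.0, n_cells=2)
        rel = traces / 100.0
        np.testing.assert_allclose(rel[0], [1, 1, 1, 2, 2, 2])

    def test_flat_when_fold_is_one(self):
        traces = pp.simulate_timelapse(50.0, 1.0, 4, 10, noise_sd=0.0)
        assert np.ptp(traces) == 0

    def test_rise_frame_constraints(self):
        with pytest.raises(ValueError, match="rise_frame"):
            pp.simulate_timelapse(1.0, 2.0, rise_frame=3, n_frames=10)
        with pytest.raises(ValueError, match="n_frames"):
            pp.simulate_timelapse(1.0, 2.0, rise_frame=5, n_frames=4)


def test_regions_match_geometry(rendered_field):
    truth, field, regions = rendered_field
    p = field.pixel_size_um
    for cell, region in zip(truth.cells, regions):
        area_px = region.cell_mask.sum() * p * p
        assert area_px == pytest.approx(math.pi * cell.cell_radius_um**2, rel=0.02)
        assert not region.nucleus_mask[~region.cell_mask].any()
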