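import numpy as np
import pytest

import retinavasc as rv
from retinavasc.centerline import build_graph
from retinavasc.morphometry import (
    avr,
    average_diameter,
    box_count,
    branching_angles,
    curvature_at,
    diameter_at,
    fractal_dimension,
    sample_curvatures,
    sample_diameters,
    select_main_vessels,
    tortuosity,
    vascular_density,
)
from retinavasc.optic_disc import calibrate
from retinavasc.phantoms import PhantomSpec, bar_mask, disc_mask, generate


def bar_setup(width=11, angle=0.0, length=280, size=400):
    ph = generate(PhantomSpec(kind="bar", size=size, width=width, length=length, angle_deg=angle))
    skel, g = build_graph(ph.vessel_mask)
    return ph.vessel_mask, g


class TestDiameter:
    def test_horizontal_bar_width(self):
        mask, g = bar_setup(width=11)
        seg = next(iter(g.segments.values()))
        cs = diameter_at(mask, seg.path, seg.n_pixels // 2)
        assert cs.d_px == pytest.approx(11, abs=1)

    @pytest.mark.parametrize("angle", [0, 30, 45, 60])
    def test_rotation_invariance(self, angle):
        mask, g = bar_setup(width=11, angle=angle)
        secs = sample_diameters(mask, g)
        assert np.mean([s.d_px for s in secs]) == pytest.approx(11, abs=1)

    def test_micron_conversion_via_pd(self):
        mask, g = bar_setup(width=11)
        disc = calibrate((0.0, 0.0), 300.0)  # PD = 300 px -> 5 um/px
        secs = sample_diameters(mask, g, disc=disc)
        assert np.mean([s.d_um for s in secs]) == pytest.approx(55, abs=5)

    def test_ray_leaving_image_unmeasurable(self):
        mask = np.ones((30, 60), bool)  # "vessel" fills the frame
        path = np.column_stack([np.arange(5, 55), np.full(50, 15.0)])
        assert diameter_at(mask, path, 25) is None

    def test_sample_count_rule(self):
        # ~ (200 - 2*7)/5 samples on a 200-px path
        path = np.column_stack([np.arange(200.0), np.full(200, 50.0)])
        mask = np.zeros((100, 220), bool)
        mask[45:56, :] = True
        g = build_graph(mask, min_spur_px=0)[1]
        secs = sample_diameters(mask, g, step=5, tangent_window=7)
        assert len(secs) == pytest.approx(37, abs=3)

    def test_step_invariance_on_constant_width(self):
        mask, g = bar_setup(width=9)
        m5 = np.mean([s.d_px for s in sample_diameters(mask, g, step=5)])
        m1 = np.mean([s.d_px for s in sample_diameters(mask, g, step=1)])
        assert m5 == pytest.approx(m1, abs=0.2)

    def test_empty_graph_empty_list(self):
        from retinavasc.centerline import CenterlineGraph

        assert sample_diameters(np.zeros((10, 10), bool), CenterlineGraph()) == []


class TestAverageDiameterAndAvr:
    def _sections(self, values, label="unknown"):
        from retinavasc.morphometry import CrossSection

        return [
            CrossSection((0, 0), (1, 0), v, v, segment_id=0, av_label=label) for v in values
        ]

    def test_mean(self):
        assert average_diameter(self._sections([50, 60, 70])) == pytest.approx(60)

    def test_label_filter(self):
        secs = self._sections([50, 60], "artery") + self._sections([80, 90], "vein")
        assert average_diameter(secs, label="artery") == pytest.approx(55)

    def test_empty_is_nan(self):
        assert np.isnan(average_diameter([]))

    def test_two_width_phantom(self):
        # half-integer row centres so the even widths rasterize exactly
        m1 = bar_mask(400, (200, 100.5), 280, 8, 0)
        m2 = bar_mask(400, (200, 300.5), 280, 16, 0)
        mask = m1 | m2
        _, g = build_graph(mask)
        secs = sample_diameters(mask, g)
        assert average_diameter(secs, unit="px") == pytest.approx(12, abs=1)

    def test_avr(self):
        assert avr(49.3, 70.4) == pytest.approx(0.700, abs=5e-4)
        assert avr(60, 60) == 1.0
        assert avr(0.0, 70.0) == 0.0
        with pytest.raises(ValueError):
            avr(50.0, 0.0)


class TestCurvature:
    @pytest.mark.parametrize("radius", [50, 100])
    def test_circle_curvature(self, radius):
        size = int(2 * radius + 60)
        ph = generate(PhantomSpec(kind="arc", size=size, radius=radius, width=9,
                                  theta_range=(20, 160)))
        _, g = build_graph(ph.vessel_mask)
        samples = sample_curvatures(g)
        assert np.mean([s.curvature for s in samples]) == pytest.approx(1 / radius, rel=0.05)

    def test_straight_path_zero(self):
        path = np.column_stack([np.arange(100.0), np.zeros(100)])
        cs = curvature_at(path, 50)
        assert cs.curvature == 0.0

    def test_end_exclusion(self):
        path = np.column_stack([np.arange(100.0), np.zeros(100)])
        assert curvature_at(path, 10, arc_half=25) is None
        assert curvature_at(path, 80, arc_half=25) is None

    def test_tortuosity_pooled_mixture(self):
        # equal numbers of zero-curvature and 0.01-curvature samples
        from retinavasc.morphometry import CurvatureSample

        zeros = [CurvatureSample((0, 0), 1, 0, 0.0, 0) for _ in range(50)]
        arcs = [CurvatureSample((0, 0), 1, 1, 0.01, 1) for _ in range(50)]
        assert tortuosity(zeros + arcs) == pytest.approx(0.005)
        assert tortuosity(zeros + arcs, pooling="per_vessel_mean") == pytest.approx(0.005)

    def test_tortuosity_empty_nan(self):
        assert np.isnan(tortuosity([]))

    def test_arc_tortuosity_times_1000(self):
        ph = generate(PhantomSpec(kind="arc", size=260, radius=100, width=9,
                                  theta_range=(20, 160)))
        _, g = build_graph(ph.vessel_mask)
        t = tortuosity(sample_curvatures(g))
        assert t * 1000 == pytest.approx(10, rel=0.05)

    def test_mm_conversion(self):
        from retinavasc.morphometry import CurvatureSample

        samples = [CurvatureSample((0, 0), 1, 1, 0.01, 0)]
        assert tortuosity(samples, per_mm=0.005) == pytest.approx(2.0)  # px^-1 / (mm/px)


class TestFractalDimension:
    def test_line_dimension_one(self):
        m = np.zeros((1024, 1024), bool)
        m[512, :] = True
        assert 0.95 <= fractal_dimension(m) <= 1.10

    def test_disk_dimension_two(self):
        m = disc_mask(640, (320, 320), 600)
        assert 1.85 <= fractal_dimension(m) <= 2.00

    def test_sierpinski_carpet(self):
        ph = generate(PhantomSpec(kind="sierpinski", size=729, iterations=5))
        assert fractal_dimension(ph.vessel_mask) == pytest.approx(np.log(8) / np.log(3), abs=0.05)

    def test_translation_and_rotation_invariance(self):
        ph = generate(PhantomSpec(kind="sierpinski", size=729, iterations=5))
        base = fractal_dimension(ph.vessel_mask)
        assert fractal_dimension(np.roll(ph.vessel_mask, (37, 59), (0, 1))) == pytest.approx(
            base, abs=0.02
        )
        assert fractal_dimension(np.rot90(ph.vessel_mask)) == pytest.approx(base, abs=0.02)

    def test_box_counts_monotone_in_mask(self):
        m1 = bar_mask(400, (200, 100), 280, 8, 0)
        m2 = bar_mask(400, (200, 300), 280, 16, 0)
        both, one = box_count(m1 | m2), box_count(m1)
        assert np.all(one.counts <= both.counts)
        assert np.all(np.diff(both.counts) <= 0)  # N non-increasing in eps

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((64, 64), bool))


class TestDensity:
    def test_exact_ratio(self):
        roi = np.zeros((40, 25), bool)
        roi[:40, :25] = True  # 1000 px
        mask = np.zeros_like(roi)
        mask.ravel()[:100] = True
        assert vascular_density(mask, roi).rho == 0.1

    def test_full_and_empty(self):
        roi = disc_mask(50, (25, 25), 30)
        assert vascular_density(roi, roi).rho == 1.0
        assert vascular_density(np.zeros_like(roi), roi).rho == 0.0

    def test_mask_clipped_to_roi(self):
        roi = np.zeros((10, 10), bool)
        roi[:5] = True
        assert vascular_density(np.ones_like(roi), roi).rho == 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            vascular_density(np.zeros((5, 5), bool), np.zeros((5, 5), bool))

    def test_monotone_in_vessel_pixels(self):
        rng = np.random.default_rng(5)
        roi = np.ones((50, 50), bool)
        mask = rng.random((50, 50)) < 0.2
        more = mask | (rng.random((50, 50)) < 0.1)
        assert vascular_density(more, roi).rho >= vascular_density(mask, roi).rho


class TestMainsAndAngles:
    def _two_bar_scene(self):
        # disc at centre; 16-px and 8-px bars in the upper half
        thick = bar_mask(500, (250, 100), 300, 16, 0)
        thin = bar_mask(500, (250, 160), 300, 8, 0)
        mask = thick | thin
        _, g = build_graph(mask)
        disc = calibrate((250.0, 250.0), 80.0)
        secs = sample_diameters(mask, g, disc=disc)
        return g, secs, disc

    def test_thickest_selected_as_main(self):
        g, secs, disc = self._two_bar_scene()
        mains = select_main_vessels(g, secs, disc)
        by_seg = {}
        for s in secs:
            by_seg.setdefault(s.segment_id, []).append(s.d_px)
        main_widths = [np.mean(by_seg[sid]) for sid in mains["upper"]]
        assert main_widths and all(w > 12 for w in main_widths)

    def test_missing_half(self):
        g, secs, disc = self._two_bar_scene()
        mains = select_main_vessels(g, secs, disc)
        assert mains["lower"] == []  # no vessels below the disc centre

    @pytest.mark.parametrize("angle", [30, 45, 60, 90])
    def test_y_phantom_angles(self, angle):
        ph = generate(PhantomSpec(kind="y_junction", size=400, width=9, length=300,
                                  branch_length=130, angle_deg=angle, branch_width=7))
        _, g = build_graph(ph.vessel_mask)
        disc = calibrate((150.0, 200.0), 60.0)
        secs = sample_diameters(ph.vessel_mask, g, disc=disc)
        mains = select_main_vessels(g, secs, disc)
        angles, mean = branching_angles(g, mains, disc, mask=ph.vessel_mask)
        assert angles, "no branch angle measured"
        assert mean == pytest.approx(angle, abs=3)

    def test_no_branches_empty(self):
        mask, g = bar_setup(width=9)
        disc = calibrate((200.0, 200.0), 60.0)
        secs = sample_diameters(mask, g, disc=disc)
        mains = select_main_vessels(g, secs, disc)
        angles, mean = branching_angles(g, mains, disc, mask=mask)
        assert angles == [] and np.isnan(mean)


class TestScalingProperties:
    def test_doubling_width(self):
        ph1 = generate(PhantomSpec(kind="arc", size=360, radius=120, width=8,
                                   theta_range=(20, 160)))
        ph2 = generate(PhantomSpec(kind="arc", size=360, radius=120, width=16,
                                   theta_range=(20, 160)))
        out = []
        for ph in (ph1, ph2):
            _, g = build_graph(ph.vessel_mask)
            secs = sample_diameters(ph.vessel_mask, g)
            cur = sample_curvatures(g)
            out.append((np.mean([s.d_px for s in secs]), tortuosity(cur)))
        (d1, t1), (d2, t2) = out
        assert d2 == pytest.approx(2 * d1, rel=0.05)
        assert t2 == pytest.approx(t1, rel=0.10)
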