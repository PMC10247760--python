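"""Graf geometry: line/circle fits, alpha angle, coverage, and invariances."""

import numpy as np
import pytest
from scipy import ndimage

import hipscreen.geometry as G
from hipscreen.errors import DegenerateGeometryError, MissingLandmarkError, ValidationError
from hipscreen.phantom import LabelMask, render_frame
from conftest import clean_spec


def vertical_segment_mask(col=100, rows=(20, 120), width=3, size=256):
    m = np.zeros((size, size), dtype=np.uint8)
    half = width // 2
    m[rows[0]:rows[1], col - half:col + half + 1] = 1
    return LabelMask(m)


def disk_mask(center=(100, 120), radius=30.0, size=256, label=2):
    rr, cc = np.indices((size, size))
    m = np.zeros((size, size), dtype=np.uint8)
    m[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = label
    return LabelMask(m)


def line(point, direction):
    d = np.asarray(direction, dtype=float)
    return G.LineFit(point=np.asarray(point, float), direction=d / np.linalg.norm(d),
                     rms_residual_px=0.0, n_support_px=100)


class TestLineFits:
    def test_baseline_on_exact_vertical_segment(self):
        # add a roof stroke so the two-line decomposition has both structures
        _, truth = render_frame(clean_spec())
        fit = G.fit_baseline(truth.label_mask)
        angle_to_vertical = np.degrees(np.arccos(abs(fit.direction[0])))
        assert angle_to_vertical < 0.1
        assert fit.rms_residual_px < 1.0

    def test_empty_class1_raises(self):
        with pytest.raises(MissingLandmarkError):
            G.fit_baseline(disk_mask())  # only class 2 present

    def test_rotating_mask_rotates_baseline(self):
        _, truth = render_frame(clean_spec())
        m = truth.label_mask.labels
        base0 = G.fit_baseline(LabelMask(m))
        rot = ndimage.rotate((m == 1).astype(float), 10.0, order=0, reshape=False) > 0.5
        base1 = G.fit_baseline(LabelMask(rot.astype(np.uint8)))
        dot = abs(float(base0.direction @ base1.direction))
        assert abs(np.degrees(np.arccos(np.clip(dot, -1, 1))) - 10.0) < 0.5

    def test_roof_recovers_construction_angle(self):
        _, truth = render_frame(clean_spec(alpha=60.0))
        base = G.fit_baseline(truth.label_mask)
        roof = G.fit_roof_line(truth.label_mask, base)
        assert G.alpha_angle(base, roof) == pytest.approx(60.0, abs=1.0)

    def test_tiny_roof_segment_raises(self):
        m = vertical_segment_mask().labels.copy()
        m[130, 101:104] = 1  # 3 stray roof pixels
        with pytest.raises(MissingLandmarkError, match="roof"):
            G.fit_roof_line(LabelMask(m), line((20, 100), (1, 0)))

    def test_recovered_angles_monotone_in_alpha(self):
        recovered = []
        for alpha in (40.0, 50.0, 60.0, 70.0):
            _, truth = render_frame(clean_spec(alpha=alpha))
            hg = G.measure(truth.label_mask)
            recovered.append(hg.alpha_deg)
        assert recovered == sorted(recovered)


class TestCircleFit:
    def test_exact_disk_recovery(self):
        fit = G.fit_head_circle(disk_mask(center=(100, 120), radius=30.0))
        assert np.linalg.norm(fit.center - [100, 120]) <= 1.0
        assert abs(fit.radius_px - 30.0) <= 1.0
        assert fit.rms_residual_px < 0.7

    def test_empty_class2_raises(self):
        with pytest.raises(MissingLandmarkError):
            G.fit_head_circle(vertical_segment_mask())


class TestAlphaAngle:
    def test_perpendicular_lines(self):
        b = line((0, 0), (1, 0))
        r = line((0, 0), (0, 1))
        assert G.alpha_angle(b, r) == pytest.approx(90.0)

    def test_identical_lines_degenerate(self):
        b = line((0, 0), (1, 0))
        with pytest.raises(DegenerateGeometryError):
            G.alpha_angle(b, line((5, 0), (1, 0)))

    def test_analytic_construction(self):
        a = np.deg2rad(57.3)
        b = line((0, 0), (1, 0))
        r = line((0, 0), (np.cos(a), np.sin(a)))
        assert G.alpha_angle(b, r) == pytest.approx(57.3, abs=1e-6)

    def test_sign_flip_invariance(self):
        a = np.deg2rad(57.3)
        b = line((0, 0), (-1, 0))
        r = line((0, 0), (-np.cos(a), -np.sin(a)))
        assert G.alpha_angle(b, r) == pytest.approx(57.3, abs=1e-6)


class TestCoverage:
    baseline = staticmethod(lambda col=100: line((0, col), (1, 0)))

    def circle(self, s, r=30.0, col=100):
        return G.CircleFit(center=np.array([120.0, col + s]), radius_px=r,
                           rms_residual_px=0.0, n_support_px=100)

    def test_center_on_line(self):
        assert G.femoral_head_coverage(self.circle(0.0), self.baseline()) == 0.5

    def test_fully_lateral(self):
        assert G.femoral_head_coverage(self.circle(-30.0), self.baseline()) == 0.0

    def test_half_radius_medial(self):
        assert G.femoral_head_coverage(self.circle(15.0), self.baseline()) == 0.75

    def test_formula_matches_rasterized_oracle(self, rng):
        for _ in range(20):
            r = float(rng.uniform(20, 40))
            s = float(rng.uniform(-r, r))
            head = self.circle(s, r=r)
            analytic = G.femoral_head_coverage(head, self.baseline())
            oracle = G.coverage_pixel_oracle(head.center, r, self.baseline())
            assert abs(analytic - oracle) < 0.01


class TestMeasure:
    def test_complete_mask_recovers_truth(self):
        spec = clean_spec(alpha=62.0, fhc=0.62)
        _, truth = render_frame(spec)
        hg = G.measure(truth.label_mask)
        assert hg.alpha_deg == pytest.approx(62.0, abs=2.0)
        assert hg.fhc == pytest.approx(0.62, abs=0.05)
        assert not hg.quality_flags

    def test_missing_head_sets_flag_not_exception(self):
        hg = G.measure(vertical_segment_mask())
        assert G.MISSING_CLASS in hg.quality_flags
        assert hg.fhc is None

    def test_high_residual_flagged(self):
        # 9-px-thick bands: the best line through either has rms ~2.6 px
        m = np.zeros((256, 256), dtype=np.uint8)
        m[20:120, 96:105] = 1
        rr = np.arange(120, 190)
        for w in range(-4, 5):
            m[rr, (100 + (rr - 120) + w).clip(0, 255)] = 1
        hg = G.measure(LabelMask(m))
        assert G.HIGH_LINE_RESIDUAL in hg.quality_flags

    def test_parameter_recovery_50_phantoms(self, rng):
        errs_a, errs_f = [], []
        for i in range(50):
            alpha = float(rng.uniform(40, 75))
            fhc = float(rng.uniform(0.2, 0.8))
            _, truth = render_frame(clean_spec(alpha=alpha, fhc=fhc,
                                               radius=float(rng.uniform(24, 34))))
            hg = G.measure(truth.label_mask)
            errs_a.append(abs(hg.alpha_deg - alpha))
            errs_f.append(abs(hg.fhc - fhc))
        assert np.mean(errs_a) <= 2.0
        assert np.mean(errs_f) <= 0.05

    def test_to_json_roundtrip(self):
        import json
        _, truth = render_frame(clean_spec())
        payload = json.loads(G.measure(truth.label_mask).to_json())
        assert set(payload) == {"alpha_deg", "fhc", "baseline", "roof", "head",
                                "quality_flags"}


class TestInvariances:
    @pytest.mark.parametrize("theta", [-10.0, -5.0, 5.0, 10.0])
    def test_rotation_equivariance_of_indices(self, theta):
        _, truth = render_frame(clean_spec(alpha=60.0, fhc=0.6))
        hg0 = G.measure(truth.label_mask)
        rot = ndimage.rotate(truth.label_mask.labels, theta, order=0, reshape=False)
        hg1 = G.measure(LabelMask(rot))
        assert abs(hg1.alpha_deg - hg0.alpha_deg) < 1.0
        assert abs(hg1.fhc - hg0.fhc) < 0.02

    def test_scale_invariance_2x(self):
        _, truth = render_frame(clean_spec(alpha=58.0, fhc=0.55, size=128, radius=15.0))
        hg0 = G.measure(truth.label_mask)
        up = np.kron(truth.label_mask.labels, np.ones((2, 2), dtype=np.uint8))
        hg1 = G.measure(LabelMask(up))
        assert abs(hg1.alpha_deg - hg0.alpha_deg) < 0.5
        assert abs(hg1.fhc - hg0.fhc) < 0.01
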