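import math

import numpy as np
import pytest

from cellvol3d.dna_quant import (CalibrationCurve, ThresholdModel,
                                 estimate_ploidy, fit_threshold_curve,
                                 histogram_center_of_mass, segment_nucleus,
                                 stromal_baseline, sweep_dilation,
                                 sweep_threshold, target_content,
                                 target_dilation, target_threshold)


def make_curve(beta_t=1000.0, beta_l=800.0, m_t=20.0, m_l=50.0, I=30.0):
    return CalibrationCurve(I=I, beta_t=beta_t, m_t=m_t, beta_l=beta_l, m_l=m_l)


class TestCalibrationAlgebra:
    def test_target_content_worked_example(self):
        assert target_content(make_curve(beta_t=1000, beta_l=800)) == pytest.approx(980.0)

    def test_target_content_degenerate_equal_betas(self):
        curve = CalibrationCurve(I=1.0, beta_t=1.0, m_t=1.0, beta_l=1.0 - 1e-9,
                                 m_l=1.0)
        assert target_content(curve) == pytest.approx(1.0)

    def test_target_content_zero_beta_l(self):
        curve = CalibrationCurve(I=1.0, beta_t=1.0, m_t=1.0, beta_l=0.0, m_l=1.0)
        assert target_content(curve) == pytest.approx(0.9)

    def test_target_threshold_algebra(self):
        # 0.1*(1000-800)/20 = 1.0
        assert target_threshold(make_curve()) == pytest.approx(1.0)

    def test_doubling_slope_halves_threshold(self):
        t1 = target_threshold(make_curve(m_t=20.0))
        t2 = target_threshold(make_curve(m_t=40.0))
        assert t2 == pytest.approx(t1 / 2)

    def test_target_dilation(self):
        assert target_dilation(make_curve()) == pytest.approx(0.9 * 200 / 50)

    def test_consistency_identity(self, rng):
        # content model evaluated at t90 equals d90, for random valid curves
        for _ in range(200):
            beta_l = rng.uniform(10, 1000)
            beta_t = beta_l + rng.uniform(1, 1000)
            curve = CalibrationCurve(I=rng.uniform(1, 100), beta_t=beta_t,
                                     m_t=rng.uniform(0.1, 100), beta_l=beta_l,
                                     m_l=rng.uniform(0.1, 100))
            d_at_t90 = curve.content_at_threshold(target_threshold(curve))
            assert abs(d_at_t90 - target_content(curve)) < 1e-9 * curve.beta_t

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(I=1, beta_t=100, m_t=1, beta_l=200, m_l=1)
        with pytest.raises(ValueError):
            CalibrationCurve(I=1, beta_t=300, m_t=-1, beta_l=200, m_l=1)


class TestSweeps:
    def test_linear_threshold_sweep(self):
        # constant-intensity nucleus: content falls linearly once smoothing-free
        dna = np.zeros((10, 12, 12))
        mask = np.zeros_like(dna, dtype=bool)
        mask[3:7, 3:9, 3:9] = True
        # synthetic intensities: uniform grid of values 1..N so content(t) is
        # close to linear in t
        vals = np.linspace(10, 50, mask.sum())
        dna[mask] = vals
        thresholds = np.linspace(12, 45, 6)
        beta_t, m_t = sweep_threshold(dna, mask, thresholds)
        # oracle least squares on directly measured contents
        d = [dna[mask & (dna >= t)].sum() for t in thresholds]
        slope, intercept = np.polyfit(thresholds, d, 1)
        assert beta_t == pytest.approx(intercept)
        assert m_t == pytest.approx(-slope)

    def test_constant_content_rejected(self):
        dna = np.zeros((6, 6, 6))
        mask = np.zeros_like(dna, dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        dna[mask] = 100.0
        with pytest.raises(ValueError, match="does not decrease"):
            sweep_threshold(dna, mask, [1.0, 2.0, 3.0])

    def test_too_few_thresholds(self):
        with pytest.raises(ValueError):
            sweep_threshold(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool),
                            [1.0, 2.0])

    def test_dilation_zero_gives_beta_l(self):
        dna = np.zeros((16, 16, 16))
        lamin = np.zeros_like(dna, dtype=bool)
        lamin[6:10, 6:10, 6:10] = True
        dna[4:12, 4:12, 4:12] = 5.0
        dilations = [0.0, 1.0, 2.0]
        beta_l, m_l = sweep_dilation(dna, lamin, dilations)
        content_inside = dna[lamin].sum()
        # intercept of the fit should be close to the undilated content
        assert beta_l == pytest.approx(content_inside, rel=0.25)
        assert m_l > 0

    def test_dilation_plateaus_at_total(self):
        dna = np.zeros((16, 16, 16))
        lamin = np.zeros_like(dna, dtype=bool)
        lamin[6:10, 6:10, 6:10] = True
        dna[5:11, 5:11, 5:11] = 3.0
        big = [6.0, 7.0, 8.0]
        d_big = []
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~lamin)
        for l in big:
            d_big.append(dna[dist <= l].sum())
        assert np.allclose(d_big, dna.sum())


class TestThresholdCurve:
    def test_recovery_of_printed_coefficients(self):
        k1, k2 = 0.219, 0.0665
        I = np.array([10, 20, 30, 40, 50, 60], dtype=float)
        t90 = 0.6 + k1 * np.exp(k2 * I)
        model = fit_threshold_curve(np.column_stack([I, t90]))
        assert model.k1 == pytest.approx(k1, rel=0.01)
        assert model.k2 == pytest.approx(k2, rel=0.01)

    def test_evaluation_at_I40(self):
        model = ThresholdModel(k1=0.219, k2=0.0665)
        assert model.threshold(40.0) == pytest.approx(0.6 + 0.219 * math.exp(2.66),
                                                      abs=0.01)
        assert model.threshold(40.0) == pytest.approx(3.73, abs=0.01)

    def test_zero_brightness_gives_base_plus_k1(self):
        model = ThresholdModel(k1=0.219, k2=0.0665)
        assert model.threshold(0.0) == pytest.approx(0.6 + 0.219)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_threshold_curve([(10.0, 1.0), (20.0, 2.0)])


class TestSegmentNucleus:
    def _phantom(self, has_cavity, brightness=1.0):
        from cellvol3d.phantoms import CellTruth, PhantomSpec, generate_phantom_stack
        spec = PhantomSpec(
            stack_shape=(36, 36, 36), voxel_size=(0.5, 0.5, 0.5),
            cells=[CellTruth(center=(9.0, 9.0, 9.0), cell_volume=1500.0,
                             nuclear_volume=600.0, has_cavity=has_cavity)])
        stack, cells, nuclei = generate_phantom_stack(spec)
        stack.data = stack.data * brightness
        return stack, cells, nuclei

    def test_cavity_filled_volume_near_truth(self):
        stack, cells, nuclei = self._phantom(has_cavity=True)
        dna = stack.channel("DNA")
        model = ThresholdModel(k1=0.219, k2=0.0665)
        filled, volume, fill_delta = segment_nucleus(
            dna, cells == 1, model, voxel_size=stack.voxel_size)
        truth = (nuclei == 1).sum() * stack.voxel_volume
        assert volume == pytest.approx(truth, rel=0.05)
        assert fill_delta > 0

    def test_cavity_free_fill_delta_near_zero(self):
        stack, cells, nuclei = self._phantom(has_cavity=False)
        dna = stack.channel("DNA")
        model = ThresholdModel(k1=0.219, k2=0.0665)
        _, volume, fill_delta = segment_nucleus(dna, cells == 1, model,
                                                voxel_size=stack.voxel_size)
        assert fill_delta <= 0.02 * volume

    def test_center_of_mass_requires_signal(self):
        with pytest.raises(ValueError):
            histogram_center_of_mass(np.zeros((4, 4, 4)))


class TestStromalBaseline:
    def test_constant_totals(self):
        base = stromal_baseline(np.full(25, 1e6))
        assert base.gaussian_mode == pytest.approx(1e6)

    def test_contaminated_mixture_mode_within_5pct(self, rng):
        totals = np.concatenate([rng.normal(1e6, 5e4, 180),
                                 rng.normal(2e6, 1e5, 20)])
        base = stromal_baseline(totals)
        assert base.gaussian_mode == pytest.approx(1e6, rel=0.05)

    def test_few_nuclei_warns(self):
        with pytest.warns(UserWarning, match="at least 20"):
            stromal_baseline(np.array([1e6, 1.1e6, 0.9e6, 1.05e6, 0.95e6]))

    def test_background_subtraction_applied(self):
        base = stromal_baseline(np.full(25, 1.2e6),
                                backgrounds=np.full(25, 2.0),
                                voxel_counts=np.full(25, 1e5))
        assert base.gaussian_mode == pytest.approx(1e6)


class TestEstimatePloidy:
    @pytest.fixture()
    def baseline(self):
        return stromal_baseline(np.full(25, 1e6))

    @pytest.mark.parametrize("mult,ploidy,near", [
        (2.0, 4.0, True),
        (0.7, 1.4, False),
        (2.2, 4.4, True),     # inclusive upper bound
        (0.8, 1.6, True),     # inclusive lower bound
    ])
    def test_examples(self, baseline, mult, ploidy, near):
        est = estimate_ploidy(mult * 1e6, baseline)
        assert est.estimated_ploidy == pytest.approx(ploidy)
        assert est.near_euploid is near

    def test_dna_number_is_half_ploidy(self, baseline):
        est = estimate_ploidy(3e6, baseline)
        assert est.dna_number == pytest.approx(est.estimated_ploidy / 2)
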