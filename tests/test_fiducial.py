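"""Landmark detection and time-domain feature computation."""

import math

import numpy as np
import pytest

from pulsewave.exceptions import DetectionError, ParameterError, WidthError
from pulsewave.fiducial import (
    TD_FEATURE_NAMES,
    FiducialPoints,
    aggregate_recording,
    compute_features,
    detect_fiducials,
    width_at_fraction,
)
from pulsewave.synthetic_data import CycleParams, generate_cycle

FS = 720.0


def triangle(n_rise=100, n_fall=200, apex=1.0):
    return np.concatenate(
        [np.linspace(0, apex, n_rise + 1), np.linspace(apex, 0, n_fall + 1)[1:]]
    )


class TestDetectFiducials:
    def test_recovers_analytic_truth_on_clean_cycle(self, clean_cycle):
        wave, truth = clean_cycle
        fp = detect_fiducials(wave, FS)
        for det, ref in [(fp.t1, truth.t1), (fp.t2, truth.t2), (fp.t3, truth.t3),
                         (fp.t4, truth.t4), (fp.t5, truth.t5)]:
            assert abs(det - ref) * FS <= 2
        for det, ref in [(fp.h1, truth.h1), (fp.h2, truth.h2), (fp.h3, truth.h3),
                         (fp.h4, truth.h4), (fp.h5, truth.h5)]:
            assert abs(det - ref) <= 0.02 * truth.h1
        assert abs(fp.w1 - truth.w1) * FS <= 2
        assert abs(fp.w2 - truth.w2) * FS <= 2

    def test_triangle_pulse_has_no_tidal_or_notch(self):
        fp = detect_fiducials(triangle(), FS)
        assert not fp.tidal_present and not fp.notch_present
        assert math.isnan(fp.t4) and math.isnan(fp.h5)

    def test_amplitude_scaling_equivariance(self, clean_cycle):
        wave, _ = clean_cycle
        a = detect_fiducials(wave, FS)
        b = detect_fiducials(wave * 2.5, FS)
        for name in ("h1", "h2", "h3", "h4", "h5"):
            assert getattr(b, name) == pytest.approx(2.5 * getattr(a, name))
        for name in ("t1", "t2", "t3", "t4", "t5", "w1", "w2"):
            assert getattr(b, name) == getattr(a, name)

    def test_fused_tidal_falls_back_to_inflection(self):
        wave, truth = generate_cycle(CycleParams(amp_tidal=0.0), FS)
        fp = detect_fiducials(wave, FS)
        assert not fp.tidal_present and fp.notch_present
        assert abs(fp.t4 - truth.t4) * FS <= 2

    def test_peak_at_cycle_edge_is_an_error(self):
        ramp = np.linspace(0, 1, 400)  # maximum at the last sample
        with pytest.raises(DetectionError):
            detect_fiducials(ramp, FS)

    def test_resampling_invariance_of_features(self, default_params):
        wave1, _ = generate_cycle(default_params, FS)
        wave2, _ = generate_cycle(default_params, 2 * FS)
        f1 = compute_features(detect_fiducials(wave1, FS))
        f2 = compute_features(detect_fiducials(wave2, 2 * FS))
        for name in TD_FEATURE_NAMES:
            a, b = getattr(f1, name), getattr(f2, name)
            tol = 1.5 / FS if name.endswith("_s") else 1.5 / FS / 0.85
            assert abs(a - b) <= tol, name

    def test_tidal_amplitude_sweep_raises_h3_ratio(self, default_params):
        from scipy.stats import spearmanr

        amps = np.linspace(3.0, 8.0, 8)
        ratios = []
        for a in amps:
            wave, _ = generate_cycle(
                CycleParams(amp_tidal=float(a)), FS
            )
            ratios.append(compute_features(detect_fiducials(wave, FS)).h3_h1)
        rho = spearmanr(amps, ratios).statistic
        assert rho > 0.9


class TestWidthAtFraction:
    def test_isoceles_triangle_closed_form(self):
        # apex at sample n, base 2n samples: width at height fraction f is
        # (1 - f) * base
        n = 150
        tri = triangle(n_rise=n, n_fall=n)
        t1 = n / FS
        w = width_at_fraction(tri, 1.0, t1, 1.0 / 3.0, FS)
        assert w == pytest.approx((2.0 / 3.0) * (2 * n) / FS, rel=1e-6)

    def test_width_shrinks_to_zero_near_apex(self):
        tri = triangle()
        t1 = 100 / FS
        widths = [width_at_fraction(tri, 1.0, t1, f, FS) for f in (0.5, 0.9, 0.99)]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 10 / FS

    def test_gaussian_component_closed_form(self):
        # a single Gaussian bump of spread sigma has width
        # 2 * sigma * sqrt(2 ln(1/f)) at height fraction f
        sigma = 0.05
        t = np.arange(int(0.8 * FS)) / FS
        bump = np.exp(-((t - 0.4) ** 2) / (2 * sigma**2))
        bump -= bump[0]
        for f in (1.0 / 3.0, 2.0 / 3.0):
            expected = 2 * sigma * math.sqrt(2 * math.log(1 / f))
            w = width_at_fraction(bump, bump.max(), 0.4, f, FS)
            assert abs(w - expected) <= 1.0 / FS

    def test_uncrossed_level_is_an_error(self):
        # plateau signal never drops below 2/3 of its height on the flanks
        x = np.full(300, 1.0)
        x[0] = 0.0
        with pytest.raises(WidthError):
            width_at_fraction(x, 1.0, 150 / FS, 2.0 / 3.0, FS)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            width_at_fraction(triangle(), 1.0, 0.1, 1.5, FS)


class TestComputeFeatures:
    def test_arithmetic_example(self):
        fp = FiducialPoints(
            h1=10, h2=8, h3=7, h4=4, h5=5,
            t1=0.15, t2=0.2, t3=0.25, t4=0.35, t5=0.45,
            t=0.85, w1=0.2, w2=0.15,
        )
        f = compute_features(fp)
        assert f.h2_h1 == pytest.approx(0.8)
        assert f.h3_h1 == pytest.approx(0.7)
        assert f.h4_h1 == pytest.approx(0.4)
        assert f.h5_h1 == pytest.approx(0.5)
        assert f.t1_t == pytest.approx(0.15 / 0.85)
        assert f.t1_t4 == pytest.approx(0.15 / 0.35)
        assert (f.t_s, f.w1_s, f.w2_s) == (0.85, 0.2, 0.15)

    def test_feature_vector_has_nine_named_entries_in_order(self):
        assert TD_FEATURE_NAMES == (
            "h2_h1", "h3_h1", "h4_h1", "h5_h1", "t1_t", "t1_t4",
            "t_s", "w1_s", "w2_s",
        )

    def test_zero_h1_is_an_error(self):
        fp = FiducialPoints(h1=0, h2=0, h3=0, h4=0, h5=0,
                            t1=0.1, t2=0.2, t3=0.3, t4=0.4, t5=0.5,
                            t=0.8, w1=0.2, w2=0.1)
        with pytest.raises(ParameterError):
            compute_features(fp)

    def test_missing_notch_yields_sentinels_not_fabrications(self):
        fp = FiducialPoints(h1=10, h2=8, h3=7, h4=math.nan, h5=math.nan,
                            t1=0.15, t2=0.2, t3=0.25, t4=math.nan, t5=math.nan,
                            t=0.85, w1=0.2, w2=0.15, notch_present=False)
        f = compute_features(fp)
        assert math.isnan(f.h4_h1) and math.isnan(f.h5_h1) and math.isnan(f.t1_t4)
        assert f.h2_h1 == pytest.approx(0.8)


class TestAggregateRecording:
    def _features(self, **overrides):
        base = dict(h2_h1=0.8, h3_h1=0.7, h4_h1=0.4, h5_h1=0.5,
                    t1_t=0.18, t1_t4=0.43, t_s=0.85, w1_s=0.2, w2_s=0.15)
        base.update(overrides)
        from pulsewave.fiducial import TimeDomainFeatures

        return TimeDomainFeatures(**base)

    def test_identical_cycles_aggregate_to_themselves(self):
        agg = aggregate_recording([self._features()] * 12, min_cycles=10)
        assert agg.as_dict() == self._features().as_dict()
        assert agg.n_cycles == 12

    def test_median_is_robust_to_one_outlier(self):
        cycles = [self._features() for _ in range(49)]
        cycles.append(self._features(h2_h1=5.0, t_s=3.0))
        agg = aggregate_recording(cycles, min_cycles=10)
        assert agg.h2_h1 == pytest.approx(0.8, rel=0.01)
        assert agg.t_s == pytest.approx(0.85, rel=0.01)

    def test_missing_values_excluded_per_feature(self):
        cycles = [self._features() for _ in range(8)]
        cycles += [self._features(h4_h1=math.nan, t1_t4=math.nan) for _ in range(4)]
        agg = aggregate_recording(cycles, min_cycles=10)
        assert agg.h4_h1 == pytest.approx(0.4)

    def test_all_missing_feature_stays_missing(self):
        cycles = [self._features(h5_h1=math.nan) for _ in range(12)]
        agg = aggregate_recording(cycles, min_cycles=10)
        assert math.isnan(agg.h5_h1)

    def test_too_few_cycles_is_an_error(self):
        with pytest.raises(ParameterError):
            aggregate_recording([self._features()] * 3, min_cycles=10)
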