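"""Vascular hysteresis loop, signed area (MTI), Q_max, MVD and VSI."""

import numpy as np
import pytest

from physiomap.bolus import gamma_variate
from physiomap.vam import (HysteresisLoop, build_vhl, compute_mti, compute_mvd,
                           compute_qmax, compute_vsi)

TIMES = np.linspace(0, 40, 80)


def _triangulation_area(x, y):
    """Independent polygon-area oracle: fan triangulation from the centroid."""
    cx, cy = x.mean(), y.mean()
    total = 0.0
    n = len(x)
    for i in range(n):
        j = (i + 1) % n
        total += 0.5 * ((x[i] - cx) * (y[j] - cy) - (x[j] - cx) * (y[i] - cy))
    return total  # positive for counter-clockwise


class TestBuildVhl:
    def test_pointwise_power_relation_degenerates_to_line(self):
        se = gamma_variate(TIMES, 1.0, 5.0, 3.0, 1.5)
        loop = build_vhl(se**1.5, se)
        assert compute_mti(loop) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_curves_make_simple_loop(self):
        ge = gamma_variate(TIMES, 1.0, 5.0, 3.0, 1.5)
        se = gamma_variate(TIMES, 0.3, 5.5, 3.0, 1.5)
        loop = build_vhl(ge, se)
        # non-self-intersecting: consecutive-edge cross products keep one sign
        assert abs(compute_mti(loop)) > 0

    def test_negative_se_floored(self):
        ge = np.abs(np.sin(TIMES))
        se = np.sin(TIMES) - 0.5
        loop = build_vhl(ge, se)
        assert np.all(loop.x >= 0)

    def test_mismatched_time_bases_rejected(self):
        with pytest.raises(ValueError):
            build_vhl(np.ones(20), np.ones(20), times_ge=np.arange(20),
                      times_se=np.arange(20) * 2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            HysteresisLoop(np.ones(5), np.ones(5))


class TestQmax:
    def test_ratio_of_maxima(self):
        ge = np.array([0, 2, 10, 4, 0], dtype=float)
        se = np.array([0, 1, 4**(2 / 3), 1, 0], dtype=float)  # max(se^1.5) = 4
        q, valid = compute_qmax(ge, se)
        assert q == pytest.approx(2.5) and valid

    def test_homogeneous_in_ge_scale(self):
        ge = gamma_variate(TIMES, 1.0, 5.0, 3.0, 1.5)
        se = gamma_variate(TIMES, 0.4, 5.0, 3.0, 1.5)
        q1, _ = compute_qmax(ge, se)
        q2, _ = compute_qmax(2 * ge, se)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_identical_subunit_curves_exceed_one(self):
        c = 0.5 * gamma_variate(TIMES, 1.0, 5.0, 3.0, 1.5)
        c = c / c.max() * 0.8  # peak < 1, so peak^1.5 < peak
        q, _ = compute_qmax(c, c)
        assert q > 1.0

    def test_zero_se_flagged(self):
        q, valid = compute_qmax(np.ones(10), np.zeros(10))
        assert not valid


class TestMti:
    def test_clockwise_ellipse_signed_positive(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        loop = HysteresisLoop(2 * np.cos(t), np.sin(-t))
        assert compute_mti(loop) == pytest.approx(2 * np.pi, rel=5e-3)

    def test_reversal_flips_sign_exactly(self, rng):
        x, y = rng.random(12), rng.random(12)
        loop = HysteresisLoop(x, y)
        rev = HysteresisLoop(x[::-1], y[::-1])
        assert compute_mti(rev) == pytest.approx(-compute_mti(loop), abs=1e-14)

    def test_matches_triangulation_oracle_on_random_simple_polygons(self, rng):
        # 100 star-shaped (hence simple) polygons with random radii
        for _ in range(100):
            n = rng.integers(8, 30)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(0.5, 2.0, n)
            x, y = rad * np.cos(ang), rad * np.sin(ang)  # counter-clockwise
            loop = HysteresisLoop(x, y)
            assert compute_mti(loop) == pytest.approx(-_triangulation_area(x, y), abs=1e-9)

    def test_additive_over_subloop_decomposition(self):
        # a square split into two rectangles: areas add
        sq = HysteresisLoop(np.array([0, 2, 2, 0, 0, 0, 0, 0]),
                            np.array([0, 0, 2, 2, 1.5, 1.0, 0.5, 0.25]))
        left = HysteresisLoop(np.array([0, 1, 1, 0, 0, 0, 0, 0]),
                              np.array([0, 0, 2, 2, 1.5, 1.0, 0.5, 0.25]))
        right = HysteresisLoop(np.array([1, 2, 2, 1, 1, 1, 1, 1]),
                               np.array([0, 0, 2, 2, 1.5, 1.0, 0.5, 0.25]))
        assert compute_mti(sq) == pytest.approx(compute_mti(left) + compute_mti(right))


class TestMvdVsi:
    def test_mvd_hand_value(self):
        mvd, valid = compute_mvd(2.5, 0.04, 1.0e-3)
        assert valid
        assert mvd == pytest.approx(2.18e3, rel=0.01)

    def test_mvd_linear_in_qmax(self):
        m1, _ = compute_mvd(1.0, 0.04, 1.0e-3)
        m2, _ = compute_mvd(3.0, 0.04, 1.0e-3)
        assert m2 == pytest.approx(3 * m1, rel=1e-12)

    def test_mvd_cbv_cube_root_scaling(self):
        m1, _ = compute_mvd(2.0, 0.01, 1.0e-3)
        m2, _ = compute_mvd(2.0, 0.08, 1.0e-3)
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_mvd_nonpositive_adc_flagged(self):
        _, valid = compute_mvd(2.0, 0.04, 0.0)
        assert not valid

    def test_vsi_hand_value(self):
        vsi, valid = compute_vsi(0.04, 1.0e-3, 2.5)
        assert valid
        assert vsi == pytest.approx(1.39e-3, rel=0.01)

    def test_vsi_qmax_power_scaling(self):
        v1, _ = compute_vsi(0.04, 1.0e-3, 1.0)
        v2, _ = compute_vsi(0.04, 1.0e-3, 4.0)
        assert v2 == pytest.approx(v1 * 4.0 ** (-1.5), rel=1e-12)

    def test_vsi_cbv_square_root_scaling(self):
        v1, _ = compute_vsi(0.01, 1.0e-3, 2.0)
        v2, _ = compute_vsi(0.04, 1.0e-3, 2.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_vsi_zero_qmax_flagged(self):
        _, valid = compute_vsi(0.04, 1.0e-3, 0.0)
        assert not valid


class TestSignRecovery:
    def test_orientation_matches_mti_sign_everywhere_noise_free(self):
        from physiomap import phantom as ph
        from physiomap.perfusion import fit_first_pass_many, signal_to_delta_r2
        from physiomap.vam import mti_from_curves
        for label, sign in (("IDHwt", 1), ("IDHmut", -1)):
            spec = ph.PhantomSpec(grid_shape=(24, 24, 24), tumor_radii=(4, 5, 4),
                                  seed=3, class_label=label)
            p = ph.make_phantom(spec)
            dsc = ph.simulate_dsc(p.gt, ph.SITE_A)
            m = p.tumor_mask
            ge = signal_to_delta_r2(dsc["ge"], m)
            se = signal_to_delta_r2(dsc["se"], m)
            tf = np.linspace(0, ge.times[-1], 4 * ge.times.size)
            ge_f = np.stack([f(tf) for f in fit_first_pass_many(ge.curves, ge.times)])
            se_f = np.stack([f(tf) for f in fit_first_pass_many(se.curves, se.times)])
            mti = mti_from_curves(ge_f, se_f)
            assert (np.sign(mti) == sign).all()
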