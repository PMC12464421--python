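"""Morphometrics: thinning census, fractal spectra, elliptic Fourier
descriptors and radial asymmetry, each against an independent oracle."""

import numpy as np
import pytest
from skimage.draw import disk, polygon
from skimage.morphology import skeletonize

from nevusnet import morphology as mo
from nevusnet import synthgen as sg


def circle_contour(r=20.0, c=(50.0, 50.0), n=400, fn=None):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rad = np.ones_like(phi) if fn is None else fn(phi)
    return np.stack([c[0] + r * rad * np.cos(phi),
                     c[1] + r * rad * np.sin(phi)], axis=1)


def koch_snowflake_mask(depth=5):
    def koch(p0, p1, d):
        if d == 0:
            return [p0]
        p0, p1 = np.asarray(p0), np.asarray(p1)
        a = p0 + (p1 - p0) / 3
        b = p0 + 2 * (p1 - p0) / 3
        rot = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])
        c = a + rot @ (b - a)
        return (koch(p0, a, d - 1) + koch(a, c, d - 1)
                + koch(c, b, d - 1) + koch(b, p1, d - 1))

    tri = [np.array([100.0, 500.0]), np.array([700.0, 500.0]),
           np.array([400.0, 500.0 - 600.0 * np.sqrt(3) / 2])]
    pts = []
    for i in range(3):
        pts += koch(tri[i], tri[(i + 1) % 3], depth)
    pts = np.asarray(pts)
    m = np.zeros((820, 820), dtype=bool)
    rr, cc = polygon(pts[:, 1] + 160, pts[:, 0] + 10, shape=m.shape)
    m[rr, cc] = True
    return m


class TestZhangSuen:
    def test_thin_line(self):
        m = np.zeros((9, 30), dtype=bool)
        m[4, 2:28] = True
        st = mo.zhang_suen(m)
        assert st.terminal_points == 2
        assert st.branch_points == 0
        np.testing.assert_array_equal(st.skeleton, m)

    def test_filled_disk_collapses_to_centre(self):
        m = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 20)
        m[rr, cc] = True
        st = mo.zhang_suen(m)
        ys, xs = np.nonzero(st.skeleton)
        assert np.hypot(ys - 32, xs - 32).max() <= 2.0
        assert st.branch_points == 0

    def test_plus_sign_census(self):
        m = np.zeros((21, 21), dtype=bool)
        m[10, 3:18] = True
        m[3:18, 10] = True
        st = mo.zhang_suen(m)
        assert st.branch_points == 1
        assert st.terminal_points == 4

    def test_skeleton_subset_and_connectivity(self, rng):
        from scipy import ndimage
        for seed in range(4):
            r = np.random.default_rng(seed)
            blob = ndimage.gaussian_filter(r.normal(size=(60, 60)), 6)
            m = blob > np.quantile(blob, 0.8)
            m = mo.largest_component(m)
            st = mo.zhang_suen(m)
            assert np.all(m[st.skeleton])       # subset of the mask
            _, n = ndimage.label(st.skeleton, structure=np.ones((3, 3)))
            assert n == 1                       # connectivity preserved

    def test_agrees_with_reference_thinning(self):
        """Independent cross-check: scikit-image's thinning of the same
        mask yields a skeleton of comparable size and identical topology
        class for a simple blob."""
        m = np.zeros((50, 70), dtype=bool)
        rr, cc = polygon([10, 10, 40, 40], [5, 60, 60, 5])
        m[rr, cc] = True
        ours = mo.zhang_suen(m).skeleton
        ref = skeletonize(m, method="zhang")
        assert abs(int(ours.sum()) - int(ref.sum())) <= \
            0.25 * max(ours.sum(), ref.sum())

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            mo.zhang_suen(np.zeros((5, 5), dtype=bool))


class TestFractalDimension:
    def test_straight_boundary_near_one(self):
        m = np.zeros((300, 300), dtype=bool)
        m[:150, :] = True  # boundary = horizontal line
        fd = mo.local_fd_spectrum(m, (16, 32, 64))
        assert np.all(np.abs(fd.fd - 1.0) < 0.05)

    def test_circle_near_one(self):
        m = np.zeros((256, 256), dtype=bool)
        rr, cc = disk((128, 128), 100)
        m[rr, cc] = True
        fd = mo.local_fd_spectrum(m, (16, 32))
        assert np.all(fd.fd < 1.15)

    def test_koch_snowflake_dimension(self):
        # triadic Koch boundary: D = log 4 / log 3 ~ 1.2619
        fd = mo.local_fd_spectrum(koch_snowflake_mask(), (16, 32, 64))
        assert np.all(np.abs(fd.fd - np.log(4) / np.log(3)) < 0.1)

    def test_values_clipped_to_theory_range(self, rng):
        spec = sg.random_spec("malignant", rng, canvas=128)
        s = sg.make_sample(spec, 128, seed=0)
        fd = mo.local_fd_spectrum(s.mask, (16, 32, 64, 128, 256))
        assert np.all((fd.fd >= 1.0) & (fd.fd <= 2.0))
        assert np.all(fd.windows <= 128)        # oversized windows skipped


class TestEFD:
    def test_circle_single_harmonic(self):
        e = mo.efd_magnitudes(circle_contour())
        assert e.magnitudes[0] == 1.0
        assert np.all(e.magnitudes[1:] < 1e-3)

    def test_ellipse_first_harmonic_dominates(self):
        # under arc-length parameterisation an eccentric ellipse leaks a
        # few percent into odd harmonics; harmonic 1 still dominates by 10x
        phi = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        ell = np.stack([30 * np.cos(phi), 10 * np.sin(phi)], axis=1)
        e = mo.efd_magnitudes(ell)
        assert np.all(e.magnitudes[1:] < 0.1)
        # a mildly eccentric ellipse is near single-harmonic
        ell2 = np.stack([22 * np.cos(phi), 18 * np.sin(phi)], axis=1)
        assert np.all(mo.efd_magnitudes(ell2).magnitudes[1:] < 0.03)

    def test_five_lobed_rose_sidebands(self):
        """r = 1 + 0.2 cos(5 phi): the x/y projections mix the rose
        frequency with the base rotation, so elliptic-Fourier energy lands
        in harmonics 4 and 6 (the sidebands), verified against direct
        numerical integration of the coefficient formulas."""
        cont = circle_contour(n=2000, fn=lambda p: 1 + 0.2 * np.cos(5 * p))
        e = mo.efd_magnitudes(cont, 12)
        side = e.magnitudes[[3, 5]]             # harmonics 4 and 6
        others = np.delete(e.magnitudes[1:], [2, 4])
        assert side.min() > 2 * others.max()
        # oracle: trapezoidal integration of the Fourier integrals
        pts = np.vstack([cont, cont[:1]])
        d = np.diff(pts, axis=0)
        dt = np.hypot(d[:, 0], d[:, 1])
        t = np.concatenate([[0], np.cumsum(dt)])
        T = t[-1]
        for h in (4, 6):
            w = 2 * np.pi * h / T
            mid = (t[1:] + t[:-1]) / 2
            a = np.sum(d[:, 0] * np.cos(w * mid)) * 2 / T / w
            b = np.sum(d[:, 0] * np.sin(w * mid)) * 2 / T / w
            c = np.sum(d[:, 1] * np.cos(w * mid)) * 2 / T / w
            dd = np.sum(d[:, 1] * np.sin(w * mid)) * 2 / T / w
            mag_oracle = np.hypot(np.hypot(a, b), np.hypot(c, dd))
            coeffs = mo.efd_coefficients(cont, 12)[h - 1]
            assert np.sqrt(np.sum(coeffs ** 2)) == pytest.approx(
                mag_oracle, rel=0.05)

    def test_start_point_and_rotation_invariance(self):
        cont = circle_contour(n=500, fn=lambda p: 1 + 0.1 * np.cos(3 * p))
        base = mo.efd_magnitudes(cont, 10).magnitudes
        rolled = mo.efd_magnitudes(np.roll(cont, 123, axis=0),
                                   10).magnitudes
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = mo.efd_magnitudes(cont @ rot.T, 10).magnitudes
        np.testing.assert_allclose(rolled, base, atol=1e-6)
        np.testing.assert_allclose(rotated, base, atol=1e-6)

    def test_open_contour_rejected(self):
        arc = circle_contour(n=400)[:100]
        with pytest.raises(ValueError):
            mo.efd_magnitudes(arc)


class TestRadialProfile:
    def test_circle_flat(self):
        rp = mo.radial_profile(circle_contour(n=1000))
        assert rp.mean_radius == pytest.approx(20.0, rel=1e-3)
        assert rp.oscillation < 0.01
        assert rp.frac_over(0.10) == 0.0

    def test_two_lobe_oscillation_32_percent(self):
        cont = circle_contour(r=30, n=2000,
                              fn=lambda p: 1 + 0.16 * np.cos(2 * p))
        rp = mo.radial_profile(cont)
        assert rp.oscillation == pytest.approx(0.32, abs=0.005)

    def test_frac_over_arccos_measure(self):
        # |0.2 cos(2 phi)| > 0.1 on a set of angular measure 2/3
        cont = circle_contour(r=30, n=3000,
                              fn=lambda p: 1 + 0.2 * np.cos(2 * p))
        rp = mo.radial_profile(cont)
        assert rp.frac_over(0.10) == pytest.approx(2 / 3, abs=0.02)

    def test_frac_over_monotone(self, rng):
        cont = circle_contour(r=30, n=800,
                              fn=lambda p: 1 + 0.2 * np.cos(3 * p))
        rp = mo.radial_profile(cont)
        vals = [rp.frac_over(t) for t in (0.02, 0.05, 0.1, 0.15, 0.3)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_rotation_shifts_bins(self):
        fn = lambda p: 1 + 0.15 * np.cos(2 * p)
        a = mo.radial_profile(circle_contour(r=30, n=3600, fn=fn), 360)
        b = mo.radial_profile(
            circle_contour(r=30, n=3600,
                           fn=lambda p: fn(p - np.pi / 2)), 360)
        np.testing.assert_allclose(np.roll(a.radii, 90), b.radii, rtol=0.02)

    def test_degenerate_contour(self):
        with pytest.raises(ValueError):
            mo.radial_profile(np.array([[0, 0], [1, 1]]))


class TestBenignCriteriaReport:
    def test_benign_fixture_within_bounds(self, benign_sample):
        rep = mo.benign_criteria_report(benign_sample.mask,
                                        benign_sample.image)
        assert rep["radial"]["frac_over_10pct"] < 0.15
        assert rep["colour_variance"] < 0.10

    def test_malignant_fixture_violates(self, malignant_sample):
        rep = mo.benign_criteria_report(malignant_sample.mask,
                                        malignant_sample.image)
        assert rep["radial"]["frac_over_10pct"] > 0.15

    def test_fields_finite_on_random_fixtures(self, rng):
        for i in range(10):
            cls = "benign" if i % 2 else "malignant"
            s = sg.make_sample(sg.random_spec(cls, rng, canvas=96), 96,
                               seed=i)
            rep = mo.benign_criteria_report(s.mask, s.image)
            flat = [rep["radial"]["oscillation"], rep["colour_variance"],
                    rep["border_gradient"],
                    *rep["efd_magnitudes"],
                    *rep["fractal_dimension"].values()]
            assert np.all(np.isfinite(flat))
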