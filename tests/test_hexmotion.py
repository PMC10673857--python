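"""Hexagonal sampling, directional Weber contrast, and radial motion sums."""

import warnings

import numpy as np
import pytest

from chromamotion import hexmotion as hx
from chromamotion import synthetic as sy

# Frozen neighborhood template (pixel-frame offsets in units of the
# horizontal pitch 3w/4 and half-height h/2), used by the brute-force
# oracle below so a regression in the package constants is caught.
_HOME = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))
_BG = {
    "right": ((2, -2), (2, -1), (2, 0)),
    "left": ((-2, 0), (-2, 1), (-2, 2)),
    "up": ((0, -2), (-1, -1), (1, -2)),
    "down": ((0, 2), (-1, 2), (1, 1)),
}
_UNIT = {"left": (-1.0, 0.0), "up": (0.0, -1.0), "right": (1.0, 0.0), "down": (0.0, 1.0)}


def _toy_lattice(nq=7, nr=7, seed=0, hex_width=120.0, hex_height=104.0):
    """Synthetic full lattice with random site intensities (no image)."""
    rng = np.random.default_rng(seed)
    qs, rs = np.meshgrid(np.arange(nq) - nq // 2, np.arange(nr) - nr // 2, indexing="ij")
    qs, rs = qs.ravel(), rs.ravel()
    a = hex_width / 2
    centers = np.stack([1.5 * a * qs, hex_height * (rs + qs / 2.0)], axis=1)
    centers -= centers.min(axis=0) - 10.0
    counts = np.full(qs.size, int(0.75 * hex_width * hex_height))
    rgb = rng.uniform(0.1, 1.0, size=(qs.size, 3))
    span = centers.max(axis=0) + 10.0
    return hx.HexLattice(qs, rs, centers, counts, rgb, hex_width, hex_height,
                         (int(span[1]) + 1, int(span[0]) + 1))


def _oracle_radial(lattice, focus, mode, on_w, off_w):
    """Direct per-site summation, no vectorization: the independent oracle."""
    on_w, off_w = np.asarray(on_w, float), np.asarray(off_w, float)
    index = {(int(q), int(r)): i for i, (q, r) in enumerate(zip(lattice.q, lattice.r))}
    full = lattice.counts >= 0.98 * 0.75 * lattice.hex_width * lattice.hex_height

    def group_mean(wts, q0, r0, offsets):
        vals = []
        for dq, dr in offsets:
            i = index.get((q0 + dq, r0 + dr))
            if i is None or not full[i]:
                return None
            vals.append(float(lattice.mean_rgb[i] @ wts))
        return sum(vals) / len(vals)

    combined = np.full(lattice.n_sites, np.nan)
    for i in range(lattice.n_sites):
        q0, r0 = int(lattice.q[i]), int(lattice.r[i])
        vec_on = [0.0, 0.0]
        vec_off = [0.0, 0.0]
        ok = True
        for d in ("left", "up", "right", "down"):
            for wts, vec, sign in ((on_w, vec_on, 1.0), (off_w, vec_off, -1.0)):
                ih = group_mean(wts, q0, r0, ((0, 0),) + _HOME)
                ib = group_mean(wts, q0, r0, _BG[d])
                if ih is None or ib is None or ib <= 0:
                    ok = False
                    continue
                c = (ih - ib) / ib
                mag = max(sign * c, 0.0)
                vec[0] += _UNIT[d][0] * mag
                vec[1] += _UNIT[d][1] * mag
        if not ok:
            continue
        rx = lattice.centers[i, 0] - focus[0]
        ry = lattice.centers[i, 1] - focus[1]
        norm = np.hypot(rx, ry)
        if norm == 0:
            combined[i] = 0.0
            continue
        rx, ry = rx / norm, ry / norm
        if mode == "recede":
            rx, ry = -rx, -ry
        combined[i] = (vec_on[0] + vec_off[0]) * rx + (vec_on[1] + vec_off[1]) * ry
    return combined


class TestHexSample:
    def test_interior_hexagons_have_9360_pixels(self):
        img = np.zeros((540, 700))
        lat = hx.hex_sample(img)
        interior = lat.interior()
        assert interior.sum() > 0
        assert set(lat.counts[interior]) == {9360}

    def test_every_pixel_assigned_once(self):
        img = np.zeros((300, 400))
        lat = hx.hex_sample(img)
        assert lat.counts.sum() == 300 * 400

    def test_constant_image_means(self):
        img = np.full((300, 400, 3), 0.625)
        lat = hx.hex_sample(img)
        np.testing.assert_allclose(lat.mean_rgb, 0.625)

    def test_too_small_image(self):
        with pytest.raises(ValueError, match="smaller"):
            hx.hex_sample(np.zeros((50, 50)))

    def test_bad_dimensions(self):
        with pytest.raises(ValueError):
            hx.hex_sample(np.zeros((300, 400)), hex_width=-1)


class TestWeberContrast:
    @pytest.mark.parametrize("ih, ib, expected", [(100, 100, 0.0), (150, 100, 0.5),
                                                  (50, 100, -0.5)])
    def test_values(self, ih, ib, expected):
        assert hx.weber_contrast(ih, ib) == pytest.approx(expected)

    def test_nonpositive_background(self):
        with pytest.raises(ValueError):
            hx.weber_contrast(1.0, 0.0)


class TestDirectionalContrast:
    def test_constant_lattice_zero_everywhere(self):
        lat = _toy_lattice()
        lat.mean_rgb[:] = 0.5
        center = lat.site_index(0, 0)
        for d in hx.DIRECTIONS:
            assert hx.directional_contrast(lat, center, d) == pytest.approx(0.0)

    def test_vertical_step_edge_sign_logic(self):
        lat = _toy_lattice(nq=9, nr=9)
        mid_x = np.median(lat.centers[:, 0])
        lat.mean_rgb[:] = np.where(lat.centers[:, [0]] > mid_x, 0.9, 0.1)
        left_site = None
        for i in np.argsort(lat.centers[:, 0]):
            if (np.isfinite(hx.directional_contrast(lat, i, "right"))
                    and np.isfinite(hx.directional_contrast(lat, i, "left"))
                    and lat.centers[i, 0] < mid_x):
                left_site = i
        # For a site left of a bright right half: home dimmer than the
        # rightward background, brighter than the leftward background.
        assert hx.directional_contrast(lat, left_site, "right") < 0
        assert hx.directional_contrast(lat, left_site, "left") >= -1e-12

    def test_hand_computed_value(self):
        lat = _toy_lattice(seed=3)
        i = lat.site_index(0, 0)
        lum = lat.mean_rgb @ np.array([1 / 3, 1 / 3, 1 / 3])
        home = [lat.site_index(dq, dr) for dq, dr in ((0, 0),) + _HOME]
        back = [lat.site_index(dq, dr) for dq, dr in _BG["up"]]
        ih = np.mean([lum[j] for j in home])
        ib = np.mean([lum[j] for j in back])
        assert hx.directional_contrast(lat, i, "up") == pytest.approx((ih - ib) / ib)

    def test_edge_site_flagged_nan(self):
        lat = _toy_lattice()
        corner = int(np.argmin(lat.centers.sum(axis=1)))
        assert np.isnan(hx.directional_contrast(lat, corner, "left"))


class TestRadialMotion:
    def test_constant_image_all_zero(self):
        lat = _toy_lattice()
        lat.mean_rgb[:] = 0.4
        est = hx.radial_motion(lat, (lat.centers[:, 0].mean(), lat.centers[:, 1].mean()))
        assert est.valid.any()
        np.testing.assert_allclose(est.combined[est.valid], 0.0, atol=1e-14)

    def test_bright_disc_rim_positive_approach(self):
        img = sy.make_test_image((540, 700), (270, 350), 140,
                                 (0.9, 0.9, 0.9), (0.1, 0.1, 0.1))
        lat = hx.hex_sample(img)
        est = hx.radial_motion(lat, (350, 270), "approach")
        dist = np.hypot(lat.centers[:, 0] - 350, lat.centers[:, 1] - 270)
        rim = est.valid & (np.abs(dist - 140) < 80)
        assert rim.any()
        assert np.all(est.combined[rim] > 0)

    @pytest.mark.parametrize("mode", ["approach", "recede"])
    @pytest.mark.parametrize("weights", [("R", "B"), ((0.2, 0.5, 0.3), (0.6, 0.1, 0.3))])
    def test_vectorized_matches_bruteforce_oracle(self, mode, weights):
        lat = _toy_lattice(nq=9, nr=9, seed=17)
        focus = (lat.centers[:, 0].mean() + 13.0, lat.centers[:, 1].mean() - 7.0)
        on_w = hx.CHANNEL_WEIGHTS[weights[0]] if isinstance(weights[0], str) else weights[0]
        off_w = hx.CHANNEL_WEIGHTS[weights[1]] if isinstance(weights[1], str) else weights[1]
        est = hx.radial_motion(lat, focus, mode, weights[0], weights[1])
        oracle = _oracle_radial(lat, focus, mode, on_w, off_w)
        assert np.isfinite(oracle).sum() == est.valid.sum() >= 9
        np.testing.assert_allclose(est.combined[est.valid], oracle[est.valid], atol=1e-10)

    def test_combined_is_on_plus_off(self):
        lat = _toy_lattice(seed=5)
        est = hx.radial_motion(lat, (200, 200), "approach", "R", "B")
        v = est.valid
        np.testing.assert_allclose(est.combined[v], est.on_component[v] + est.off_component[v])

    def test_focus_outside_image_rejected(self):
        lat = _toy_lattice()
        with pytest.raises(ValueError, match="focus"):
            hx.radial_motion(lat, (-50, 0))


class TestCompareModes:
    def test_identical_estimates(self):
        lat = _toy_lattice(seed=2)
        est = hx.radial_motion(lat, (200, 200))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_ = hx.compare_modes(est, est)
        assert cmp_.result.p_value == pytest.approx(1.0)
        np.testing.assert_allclose(cmp_.differences, 0.0)

    def test_mismatched_sites_rejected(self):
        a = hx.radial_motion(_toy_lattice(), (200, 200))
        b = hx.radial_motion(_toy_lattice(nq=5, nr=5), (150, 150))
        with pytest.raises(ValueError, match="site"):
            hx.compare_modes(a, b)
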