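"""Dot detection and characterization: maxima, DoG, FWHM, CNR, matching,
auto-thresholding."""

import numpy as np
import pandas as pd
import pytest

from wfdecon import (
    DetectParams,
    VolumeImage,
    auto_threshold,
    cnr,
    default_dog_sigma,
    detect,
    dog_filter,
    fwhm_lateral,
    local_maxima_6,
    match_dots,
    ncr,
)
from wfdecon.simulate import SimulationSpec, render_ground_truth

VOX = (130.0, 130.0, 130.0)


def brute_force_maxima(d: np.ndarray) -> set:
    """Exhaustive all-voxel check of strict 6-connectivity maxima."""
    out = set()
    nz, ny, nx = d.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = d[z, y, x]
                neigh = []
                if z > 0:
                    neigh.append(d[z - 1, y, x])
                if z < nz - 1:
                    neigh.append(d[z + 1, y, x])
                if y > 0:
                    neigh.append(d[z, y - 1, x])
                if y < ny - 1:
                    neigh.append(d[z, y + 1, x])
                if x > 0:
                    neigh.append(d[z, y, x - 1])
                if x < nx - 1:
                    neigh.append(d[z, y, x + 1])
                if all(v > n for n in neigh):
                    out.add((z, y, x))
    return out


def gaussian_blob_image(shape=(9, 21, 21), center=(4, 10, 10), sigma=0.9, amp=100.0,
                        offset=0.0):
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = amp * np.exp(
        -((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
        / (2 * sigma**2)
    ) + offset
    return VolumeImage(d.astype(np.float32), VOX)


class TestLocalMaxima6:
    def test_single_blob_single_maximum(self):
        img = gaussian_blob_image()
        peaks = local_maxima_6(img)
        assert peaks.shape == (1, 3)
        assert tuple(peaks[0]) == (4, 10, 10)

    def test_constant_image_has_no_maxima(self):
        img = VolumeImage(np.full((5, 6, 6), 3.0, np.float32), VOX)
        assert local_maxima_6(img).size == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_images_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 1, (10, 20, 20)).astype(np.float32)
        got = {tuple(p) for p in local_maxima_6(d)}
        assert got == brute_force_maxima(d)

    def test_border_voxels_compare_existing_neighbors_only(self):
        d = np.zeros((3, 3, 3), np.float32)
        d[0, 0, 0] = 5.0  # corner brighter than its 3 existing neighbors
        got = {tuple(p) for p in local_maxima_6(d)}
        assert (0, 0, 0) in got


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        d = np.full((6, 12, 12), 42.0, np.float32)
        assert np.allclose(dog_filter(d, 1.0, 1.6), 0.0, atol=1e-4)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 10, (6, 14, 14)).astype(np.float64)
        a = dog_filter(7.0 * d, 1.0, 1.6)
        b = 7.0 * dog_filter(d, 1.0, 1.6)
        assert np.allclose(a, b, rtol=1e-5, atol=1e-5)

    def test_scale_selectivity(self):
        # the band-pass is scale selective: for unit-amplitude 3D blobs the
        # center response R(b) = (b^2/(b^2+s1^2))^{3/2} - (b^2/(b^2+s2^2))^{3/2}
        # has an interior maximum; the oracle argmax comes from solving
        # dR/db = 0 numerically on the closed form
        s1, k = 2.0, 1.6
        s2 = k * s1
        b_dense = np.linspace(0.5, 8.0, 4000)
        closed = (b_dense**2 / (b_dense**2 + s1**2)) ** 1.5 - (
            b_dense**2 / (b_dense**2 + s2**2)
        ) ** 1.5
        expected = b_dense[closed.argmax()]
        blob_sigmas = np.linspace(0.8, 6.0, 27)
        responses = []
        for bs in blob_sigmas:
            img = gaussian_blob_image(shape=(25, 41, 41), center=(12, 20, 20),
                                      sigma=bs, amp=1.0)
            dog = dog_filter(img.data, s1, s2)
            responses.append(dog[12, 20, 20])
        responses = np.array(responses)
        best = blob_sigmas[int(np.argmax(responses))]
        assert best == pytest.approx(expected, abs=0.3)
        # selectivity: response falls off on both sides of the match
        assert responses[0] < responses.max() * 0.9
        assert responses[-1] < responses.max() * 0.9

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((4, 4, 4), np.float32), 2.0, 1.0)


class TestDetect:
    def test_high_snr_dots_recovered_one_to_one(self, gauss_psf):
        # isolated bright dots (enforced minimum separation, no crowding)
        # must be recovered 1:1 within a pixel by the ranked table
        from wfdecon.simulate import corrupt

        rng = np.random.default_rng(21)
        pos = []
        while len(pos) < 40:
            cand = rng.uniform([4, 4, 3], [91, 91, 16])
            if not pos or np.linalg.norm(np.array(pos) - cand, axis=1).min() > 7.0:
                pos.append(cand)
        pos = np.array(pos)
        spec = SimulationSpec(shape=(96, 96, 20), n_dots=0, amplitude=2e5,
                              sensor_sigma=10.0, seed=21)
        gt = render_ground_truth(spec)
        from wfdecon.simulate import _axis_mass

        img = gt.image.data.astype(np.float64)
        for x, y, z in pos:
            sx, wx = _axis_mass(x, 96, 0.7)
            sy, wy = _axis_mass(y, 96, 0.7)
            sz, wz = _axis_mass(z, 20, 0.7)
            img[sz, sy, sx] += 2e5 * (wz[:, None, None] * wy[None, :, None] * wx[None, None, :])
        gt = type(gt)(image=VolumeImage(img.astype(np.float32), VOX), positions=pos)
        noisy = corrupt(gt, gauss_psf, spec)
        tab = detect(noisy, mode="dog", params=DetectParams(voxel=VOX))
        top = tab.positions()[:40]
        d_det = np.linalg.norm(top[:, None, :] - pos[None, :, :], axis=-1)
        assert np.all(d_det.min(axis=1) < 1.0)  # every detection near a truth
        assert np.all(d_det.min(axis=0) < 1.0)  # every truth found

    def test_modes_agree_on_isolated_dot(self):
        img = gaussian_blob_image(shape=(11, 25, 25), center=(5, 12, 12), sigma=1.2,
                                  amp=500.0, offset=10.0)
        ti = detect(img, mode="intensity", params=DetectParams(voxel=VOX))
        td = detect(img, mode="dog", params=DetectParams(voxel=VOX))
        assert np.allclose(ti.positions()[0], td.positions()[0], atol=0.3)

    def test_deterministic_tables(self):
        rng = np.random.default_rng(5)
        img = VolumeImage(rng.uniform(0, 100, (8, 16, 16)).astype(np.float32), VOX)
        a = detect(img, mode="dog", params=DetectParams(voxel=VOX))
        b = detect(img, mode="dog", params=DetectParams(voxel=VOX))
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_empty_image_empty_table(self):
        img = VolumeImage(np.zeros((4, 6, 6), np.float32), VOX)
        assert len(detect(img, mode="intensity")) == 0

    def test_default_dog_sigma_from_optics(self):
        # lambda/(4 NA) in pixels
        assert default_dog_sigma(1.45, 460.0, 130.0) == pytest.approx(0.61, abs=0.01)


class TestFwhm:
    def _rasterized_blob(self, sigma_px, amp=1000.0, offset=50.0, n=25):
        # sampled (not pixel-integrated) Gaussian: the fitted sigma then
        # matches the closed form exactly instead of the integration-
        # broadened sqrt(sigma^2 + 1/12)
        c = (n - 1) / 2
        x = np.arange(n) - c
        w = np.exp(-0.5 * (x / sigma_px) ** 2)
        plane = np.outer(w, w)
        d = np.tile(plane, (5, 1, 1)) * amp + offset
        return VolumeImage(d.astype(np.float64), VOX)

    def test_closed_form_sigma(self):
        img = self._rasterized_blob(0.7)
        dot = {"x": 12.0, "y": 12.0, "z": 2.0}
        got = fwhm_lateral(img, dot, dxy=130.0)
        assert got == pytest.approx(2.3548 * 0.7 * 130.0, rel=0.02)

    def test_fwhm_scales_with_sigma(self):
        a = fwhm_lateral(self._rasterized_blob(0.8), {"x": 12, "y": 12, "z": 2}, dxy=130.0)
        b = fwhm_lateral(self._rasterized_blob(1.6), {"x": 12, "y": 12, "z": 2}, dxy=130.0)
        assert b == pytest.approx(2 * a, rel=0.02)

    def test_invariant_under_intensity_scaling(self):
        img = self._rasterized_blob(1.0)
        bright = VolumeImage(img.data * 10.0, VOX)
        a = fwhm_lateral(img, {"x": 12, "y": 12, "z": 2}, dxy=130.0)
        b = fwhm_lateral(bright, {"x": 12, "y": 12, "z": 2}, dxy=130.0)
        assert b == pytest.approx(a, rel=0.01)

    def test_border_dot_rejected(self):
        img = self._rasterized_blob(1.0)
        with pytest.raises(ValueError):
            fwhm_lateral(img, {"x": 1.0, "y": 12.0, "z": 2.0}, dxy=130.0)


class TestCnr:
    def test_flat_ring_flags_infinite(self):
        d = np.full((3, 21, 21), 100.0, np.float32)
        d[1, 10, 10] = 300.0
        img = VolumeImage(d, VOX)
        assert cnr(img, {"x": 10.0, "y": 10.0, "z": 1.0, "value": 300.0}) == np.inf

    def test_matches_hand_computed_ring_statistics(self):
        # image with a known analytic lateral pattern: value = x coordinate
        ny = nx = 24
        plane = np.tile(np.arange(nx, dtype=np.float64), (ny, 1))
        img = VolumeImage(np.stack([plane] * 3), VOX)
        x0, y0, r = 11.3, 12.1, 5.0
        theta = 2 * np.pi * np.arange(100) / 100
        samples = x0 + r * np.cos(theta)  # bilinear interp of f(x,y)=x is exact
        want_bg, want_sd = samples.mean(), samples.std()
        got = cnr(img, {"x": x0, "y": y0, "z": 1.0, "value": 50.0})
        assert got == pytest.approx((50.0 - want_bg) / want_sd, rel=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(50, 150, (3, 24, 24))
        dot = {"x": 11.0, "y": 12.0, "z": 1.0, "value": float(d[1, 12, 11])}
        a = cnr(VolumeImage(d, VOX), dot)
        dot_c = dict(dot, value=dot["value"] + 77.0)
        b = cnr(VolumeImage(d + 77.0, VOX), dot_c)
        assert b == pytest.approx(a, rel=1e-9)

    def test_ring_must_fit(self):
        img = VolumeImage(np.zeros((3, 24, 24), np.float32), VOX)
        with pytest.raises(ValueError):
            cnr(img, {"x": 2.0, "y": 12.0, "z": 1.0, "value": 1.0})


class TestNcr:
    def test_basic_values(self):
        assert ncr(500.0, 500.0) == 1.0
        assert ncr(2000.0, 500.0) == 4.0
        assert ncr(2000.0 * 3, 500.0 * 3) == 4.0

    def test_nonpositive_nucleus_rejected(self):
        with pytest.raises(ValueError):
            ncr(10.0, 0.0)


class TestMatchDots:
    def test_identical_tables_all_match(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 50, (30, 3))
        m = match_dots(pos, pos.copy(), radius_nm=260.0, voxel=VOX)
        assert m.n_matched_a == m.n_matched_b == 30
        assert m.n_lost == m.n_new == 0

    def test_threshold_at_260nm(self):
        a = np.array([[10.0, 10.0, 5.0], [30.0, 10.0, 5.0]])
        b = np.array([[11.0, 10.0, 5.0], [33.0, 10.0, 5.0]])  # 130 nm / 390 nm apart
        m = match_dots(a, b, radius_nm=260.0, voxel=VOX)
        assert list(m.a_matched) == [True, False]
        assert m.n_lost == 1 and m.n_new == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 40, (200, 3))
        b = rng.uniform(0, 40, (200, 3))
        m = match_dots(a, b, radius_nm=260.0, voxel=VOX)
        scale = np.array(VOX)
        d = np.linalg.norm((a * scale)[:, None, :] - (b * scale)[None, :, :], axis=-1)
        assert np.array_equal(m.a_matched, d.min(axis=1) < 260.0)
        assert np.array_equal(m.b_matched, d.min(axis=0) < 260.0)
        assert np.array_equal(m.a_nn, d.argmin(axis=1))

    def test_mutual_mode_symmetric_counts(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 20, (80, 3))
        b = rng.uniform(0, 20, (90, 3))
        m = match_dots(a, b, radius_nm=400.0, voxel=VOX, mutual=True)
        assert m.n_matched_a == m.n_matched_b

    def test_empty_tables(self):
        m = match_dots(np.empty((0, 3)), np.empty((0, 3)))
        assert m.n_matched_a == 0 and m.n_new == 0


class TestAutoThreshold:
    def test_bimodal_lognormal_mixture(self):
        rng = np.random.default_rng(4)
        lo = np.exp(rng.normal(0.0, 0.3, 1500))
        hi = np.exp(rng.normal(3.0, 0.3, 1500))
        thr = auto_threshold(np.concatenate([lo, hi]))
        assert thr is not None
        assert np.median(lo) < thr < np.median(hi)

    def test_unimodal_returns_sentinel(self):
        rng = np.random.default_rng(5)
        vals = np.exp(rng.normal(1.0, 0.4, 2000))
        assert auto_threshold(vals) is None

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate(
            [np.exp(rng.normal(0, 0.3, 1000)), np.exp(rng.normal(2.5, 0.3, 1000))]
        )
        t1 = auto_threshold(vals)
        t2 = auto_threshold(vals * 100.0)
        assert t2 == pytest.approx(100.0 * t1, rel=0.05)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold(np.ones(50))


class TestFwhmFilter:
    def test_plausible_size_window(self):
        from wfdecon import fwhm_filter
        from wfdecon.dots import DotTable, DetectParams
        import pandas as pd

        df = pd.DataFrame({
            "x": [1.0, 2.0, 3.0, 4.0], "y": [1.0] * 4, "z": [0.0] * 4,
            "value": [10.0] * 4, "dog": [1.0] * 4,
            "fwhm": [30.0, 200.0, 900.0, np.nan],  # nm at 130 nm pixels
            "cnr": [np.nan] * 4, "label": [""] * 4,
        })
        table = DotTable(df, ranking="dog", params=DetectParams())
        kept = fwhm_filter(table, dxy=130.0)  # window 65-650 nm
        assert list(kept.records.fwhm) == [200.0]
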