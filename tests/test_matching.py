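"""Fourier weighting, bandpass, the constrained-CC scan and its oracles."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from tomomatch import (
    AngleList,
    BandpassSpec,
    Orientation,
    Volume,
    bandpass_mask,
    build_fourier_weight,
    cc_to_loglik,
    generate_angle_list,
    make_phantom,
    make_wedge_list,
    tm_scan,
    zscore_transform,
)
from tomomatch.errors import DegenerateMapError, DomainError, ShapeError
from tomomatch.matching import correlate_raw
from tomomatch.synthetic import PhantomSpec, plant_particles

IDENTITY_ONLY = AngleList(np.zeros((1, 3)), step=360.0)


def spatial_cc_oracle(f, t, mask):
    """Masked locally-normalized CC by direct sliding windows (no FFT).

    Windows wrap circularly, matching the periodic boundary of the FFT route.
    """
    L = t.shape[0]
    c = L // 2
    n = f.shape[0]
    fp = np.pad(f, ((0, L),) * 3, mode="wrap")
    win = sliding_window_view(fp, (L, L, L))[:n, :n, :n]
    N = mask.sum()
    mu_t = (t * mask).sum() / N
    s = np.sqrt((mask * (t - mu_t) ** 2).sum())
    tn = mask * (t - mu_t) / s
    out = np.zeros((n, n, n))
    ys = (np.arange(n) - c) % n
    for x in range(n):
        w = win[(x - c) % n][np.ix_(ys, ys)]  # (n, n, L, L, L)
        num = np.einsum("yzabc,abc->yz", w, tn)
        m1 = np.einsum("yzabc,abc->yz", w, mask) / N
        m2 = np.einsum("yzabc,abc->yz", w * w, mask) / N
        var = m2 - m1 * m1
        out[x] = num / np.sqrt(N * var)
    return out


class TestFourierWeight:
    def test_full_coverage_is_all_pass(self):
        wl = make_wedge_list(-90.0, 90.0, 1.0)
        w = build_fourier_weight(wl, 24, ctf=False, exposure=False)
        np.testing.assert_array_equal(w.weights, 1.0)

    def test_wedge_fraction_matches_analytic(self, wedge_list_60):
        w = build_fourier_weight(wedge_list_60, 48, ctf=False, exposure=False)
        # area fraction equals the angular fraction inside the Nyquist
        # sphere (the square corners overweight the wedge)
        import scipy.fft as sfft

        fr = sfft.fftfreq(48)
        fx, fy, fz = np.meshgrid(fr, fr, fr, indexing="ij")
        ball = fx**2 + fy**2 + fz**2 <= 0.25**2
        frac = w.weights[ball].mean()
        assert frac == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_wedge_off_is_identity(self, wedge_list_60):
        w = build_fourier_weight(wedge_list_60, 16, wedge_on=False)
        np.testing.assert_array_equal(w.weights, 1.0)
        assert not w.wedge_on

    def test_ctf_and_dose_attenuate(self, wedge_list_60):
        plain = build_fourier_weight(wedge_list_60, 24, ctf=False,
                                     exposure=False)
        weighted = build_fourier_weight(wedge_list_60, 24)
        assert weighted.weights.sum() < plain.weights.sum()
        assert weighted.weights.min() >= 0
        assert weighted.weights.max() <= 1

    def test_empty_wedge_list_rejected(self):
        import pandas as pd

        from tomomatch.io import WedgeList

        with pytest.raises(Exception):
            WedgeList(pd.DataFrame())


class TestBandpass:
    def test_identity_band(self):
        w = bandpass_mask(16, BandpassSpec(0, None))
        np.testing.assert_array_equal(w.weights, 1.0)

    def test_dc_retained_without_highpass(self):
        w = bandpass_mask(16, BandpassSpec(0, 4.0))
        assert w.weights[0, 0, 0] == 1.0

    def test_annulus_count_matches_enumeration(self):
        import scipy.fft as sfft

        spec = BandpassSpec(3.0, 6.0)
        w = bandpass_mask(16, spec)
        fr = sfft.fftfreq(16)
        fx, fy, fz = np.meshgrid(fr, fr, fr, indexing="ij")
        r = np.sqrt(fx**2 + fy**2 + fz**2) * 16
        expected = ((r >= 3.0) & (r <= 6.0)).sum()
        assert w.weights.sum() == expected

    def test_inverted_band_rejected(self):
        with pytest.raises(DomainError):
            BandpassSpec(6.0, 3.0)


class TestScan:
    def test_planted_perfect_match_scores_one(self, two_lobe_template):
        al = generate_angle_list(30.0)
        sub = AngleList(al.eulers[123:124], 30.0)
        vol, truth = plant_particles(
            64, two_lobe_template, 1, seed=2, orientation_grid=sub
        )
        maps = tm_scan(vol, two_lobe_template, sub, dtype=np.float64)
        pos = tuple(int(v) for v in truth.positions[0])
        assert maps.cc_max.data[pos] == pytest.approx(1.0, abs=1e-4)
        peak = np.unravel_index(maps.cc_max.data.argmax(), maps.cc_max.shape)
        assert peak == pos
        assert maps.angle_index[pos] == 0

    def test_anticorrelated_scores_minus_one(self, two_lobe_template):
        al = generate_angle_list(30.0)
        sub = AngleList(al.eulers[123:124], 30.0)
        vol, truth = plant_particles(
            64, two_lobe_template, 1, seed=2, orientation_grid=sub
        )
        maps = tm_scan(
            vol.with_data(-vol.data), two_lobe_template, sub,
            dtype=np.float64,
        )
        pos = tuple(int(v) for v in truth.positions[0])
        assert maps.cc_max.data[pos] == pytest.approx(-1.0, abs=1e-4)

    def test_fft_equals_spatial_oracle(self, rng, simple_template):
        """FFT route vs direct sliding-window route, 4 orientations."""
        f = rng.normal(size=(32, 32, 32))
        tomo = Volume(f.astype(np.float32), 1.0)
        angles = AngleList(
            np.array([[0, 0, 0], [90, 0, 0], [0, 90, 0], [90, 90, 0]],
                     dtype=float),
            step=90.0,
        )
        maps = tm_scan(tomo, simple_template, angles, dtype=np.float64)
        mask = simple_template.mask.data.astype(np.float64)
        oracle = np.full(f.shape, -np.inf)
        from tomomatch.geometry import rotate_array

        for eul in angles.eulers:
            t_rot = rotate_array(
                simple_template.map.data.astype(np.float64),
                Orientation(*eul),
            )
            oracle = np.maximum(oracle, spatial_cc_oracle(f, t_rot, mask))
        np.testing.assert_allclose(maps.cc_max.data, oracle, atol=1e-6)

    def test_monotone_angular_refinement(self):
        """Refining the grid never lowers cc_max at a planted particle
        (noise-free phantom, off-grid planted orientation)."""
        tpl = make_phantom(PhantomSpec(kind="two_lobe", dims=16))
        probe = AngleList(np.array([[47.0, 33.0, 211.0]]), 10.0)
        vol, truth = plant_particles(
            32, tpl, 1, seed=5, orientation_grid=probe
        )
        pos = tuple(int(v) for v in truth.positions[0])
        prev = -np.inf
        for step in (30.0, 20.0, 10.0):
            maps = tm_scan(vol, tpl, generate_angle_list(step))
            cc = maps.cc_max.data[pos]
            assert cc >= prev - 1e-6
            prev = cc

    def test_zero_variance_tomogram_rejected(self, simple_template):
        flat = Volume(np.zeros((16, 16, 16), np.float32), 1.0)
        with pytest.raises(DegenerateMapError):
            tm_scan(flat, simple_template, IDENTITY_ONLY)

    def test_template_larger_than_tomogram_rejected(self, simple_template):
        tiny = Volume(np.random.default_rng(0).normal(size=(4, 4, 4))
                      .astype(np.float32), 1.0)
        with pytest.raises(ShapeError):
            tm_scan(tiny, simple_template, IDENTITY_ONLY)

    def test_border_marked_invalid(self, rng, simple_template):
        tomo = Volume(rng.normal(size=(24, 24, 24)).astype(np.float32), 1.0)
        maps = tm_scan(tomo, simple_template, IDENTITY_ONLY)
        assert not maps.valid[0, 0, 0]
        assert not maps.valid[3, 12, 12]
        assert maps.valid[12, 12, 12]


class TestZScore:
    def test_mean_zero_std_one(self, rng):
        z, mu, sigma = zscore_transform(rng.normal(2.0, 3.0, (20, 20, 20)))
        assert abs(z.mean()) <= 1e-9
        assert z.std() == pytest.approx(1.0, rel=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(12, 12, 12))
        z1, _, _ = zscore_transform(x)
        z2, _, _ = zscore_transform(5.0 * x + 3.0)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateMapError):
            zscore_transform(np.full((8, 8, 8), 3.0))


class TestLogLikelihood:
    def test_zero_cc_maps_to_zero(self):
        assert cc_to_loglik(0.0, 2.0) == 0.0

    def test_quarter_scaling_with_noise(self):
        assert cc_to_loglik(1.0, 2.0) == pytest.approx(
            cc_to_loglik(1.0, 1.0) / 4.0
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DomainError):
            cc_to_loglik(1.0, 0.0)

    def test_ml_argmax_equals_cc_argmax(self, rng):
        """Brute-force Gaussian log-likelihood argmax over rotations and
        circular shifts coincides with the argmax of the raw correlation.

        Lattice-commensurate rotations keep sum((RT)^2) exactly constant,
        which is the dropped-term condition for the equivalence."""
        L = 8
        t = np.zeros((L,) * 3)
        t[2:6, 3:5, 4:7] = 1.0
        t[4, 4, 2] = 2.0
        tpl = Volume(t.astype(np.float32), 1.0)
        rots = [Orientation.identity(), Orientation(phi=90.0),
                Orientation(phi=180.0), Orientation(theta=180.0)]
        # map = rotated template planted at a shift + Gaussian noise
        from tomomatch.geometry import rotate_array

        true_shift = (5, 2, 7)
        planted = np.roll(rotate_array(t, rots[2]),
                          true_shift, axis=(0, 1, 2))
        f = planted + rng.normal(scale=0.4, size=planted.shape)

        best_ll, arg_ll = -np.inf, None
        best_cc, arg_cc = -np.inf, None
        for ri, o in enumerate(rots):
            rt = rotate_array(t, o)
            cc_map = correlate_raw(Volume(f.astype(np.float32), 1.0),
                                   tpl, o)
            for sx in range(L):
                for sy in range(L):
                    for sz in range(L):
                        shifted = np.roll(rt, (sx, sy, sz), axis=(0, 1, 2))
                        ll = -((f - shifted) ** 2).sum()
                        if ll > best_ll:
                            best_ll, arg_ll = ll, (ri, sx, sy, sz)
            idx = np.unravel_index(cc_map.argmax(), cc_map.shape)
            if cc_map[idx] > best_cc:
                best_cc = cc_map[idx]
                # correlate_raw centers the template at the peak voxel;
                # np.roll by s places the template center (L//2) at
                # (L//2 + s) mod L
                c = L // 2
                arg_cc = (ri, *(int((i - c) % L) for i in idx))
        assert arg_ll == arg_cc
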