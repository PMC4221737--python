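"""PIV engine: correlation, subpixel fitting, deformation passes, validation."""

import numpy as np
import pytest

from actinflow import (
    CellMask,
    ConfigurationError,
    FlowSpec,
    PIVSettings,
    TextureSpec,
    VelocityField,
    compute_piv,
    correlate_windows,
    generate_sequence,
    mask_from_array,
    validate_vectors,
)
from actinflow.piv import run_pass


def brute_force_integer_argmax(a, b):
    """Independent oracle: circular correlation argmax over all integer lags."""
    a = a - a.mean()
    b = b - b.mean()
    n = a.shape[0]
    best, best_lag = -np.inf, None
    for dy in range(-n // 2, n // 2):
        for dx in range(-n // 2, n // 2):
            # roll(b, -d) aligns b(x + d) with a(x): score(d) = sum a(x) b(x+d)
            score = (a * np.roll(b, (-dy, -dx), axis=(0, 1))).sum()
            if score > best:
                best, best_lag = score, (dx, dy)
    return best_lag


def fourier_shift(img, dx, dy):
    """Subpixel circular shift via the Fourier shift theorem."""
    F = np.fft.fft2(img)
    ky = np.fft.fftfreq(img.shape[0])[:, None]
    kx = np.fft.fftfreq(img.shape[1])[None, :]
    return np.fft.ifft2(F * np.exp(-2j * np.pi * (kx * dx + ky * dy))).real


class TestCorrelateWindows:
    @pytest.mark.parametrize("shift", [(3, -2), (0, 4), (-4, -4), (1, 0)])
    def test_integer_shift_exact(self, speckle_window_bank, shift):
        dx, dy = shift
        for win in speckle_window_bank[:6]:
            shifted = np.roll(win, (dy, dx), axis=(0, 1))
            disp, q = correlate_windows(win, shifted)
            assert (round(disp[0]), round(disp[1])) == shift
            assert brute_force_integer_argmax(win, shifted) == shift

    def test_identity_zero_displacement(self, speckle_window_bank):
        win = speckle_window_bank[0]
        disp, quality = correlate_windows(win, win)
        assert np.allclose(disp, 0.0, atol=1e-9)
        assert quality > 1.0  # primary peak clearly dominates

    def test_half_pixel_shift_recovered(self, speckle_window_bank):
        hits = 0
        for win in speckle_window_bank[:10]:
            shifted = fourier_shift(win, 0.5, 0.0)
            disp, _ = correlate_windows(win, shifted)
            if 0.35 <= disp[0] <= 0.65 and abs(disp[1]) < 0.2:
                hits += 1
        assert hits >= 9

    def test_zero_variance_flagged_not_raised(self):
        flat = np.ones((16, 16))
        disp, quality = correlate_windows(flat, flat + 1.0)
        assert np.isnan(disp).all() and quality == 0.0

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            correlate_windows(np.zeros((16, 16)), np.zeros((32, 32)))

    def test_oracle_equivalence_noisy_shifts(self, speckle_window_bank):
        """Integer part of the FFT displacement equals the brute-force
        all-lags correlation argmax on noisy shifted windows."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            win = speckle_window_bank[rng.integers(len(speckle_window_bank))]
            shift = tuple(rng.integers(-4, 5, 2))
            noisy = np.roll(win, (shift[1], shift[0]), axis=(0, 1))
            noisy = noisy + rng.normal(0, noisy.std() * 0.1, noisy.shape)
            disp, _ = correlate_windows(win, noisy)
            oracle = brute_force_integer_argmax(win, noisy)
            assert (round(disp[0]), round(disp[1])) == oracle


class TestRunPass:
    def test_uniform_two_pass_recovery(self, full_mask, default_texture):
        flow = FlowSpec("uniform", {"dx": 2.4, "dy": 0.0}, seed=21)
        seq = generate_sequence(flow, default_texture, full_mask, 2)
        settings = PIVSettings(pass_window_sizes=(32, 16))
        f1 = run_pass(seq.frames[0], seq.frames[1], settings, 0, None, full_mask)
        f1 = validate_vectors(f1, settings)
        f2 = run_pass(seq.frames[0], seq.frames[1], settings, 1, f1, full_mask)
        use = f2.valid
        assert abs(np.nanmean(f2.u[use]) - 2.4) < 0.1
        assert abs(np.nanmean(f2.v[use])) < 0.1

    def test_all_background_windows_invalid(self, default_texture):
        raster = np.zeros((96, 96), dtype=bool)
        raster[40:56, 40:56] = True
        mask = mask_from_array(raster)
        flow = FlowSpec("zero", seed=1)
        seq = generate_sequence(flow, default_texture, mask, 2)
        settings = PIVSettings(pass_window_sizes=(16,))
        fld = run_pass(seq.frames[0], seq.frames[1], settings, 0, None, mask)
        X, Y = fld.grid
        outside = ~((X > 32) & (X < 64) & (Y > 32) & (Y < 64))
        assert not fld.valid[outside].any()

    def test_exact_predictor_gives_small_corrections(self, full_mask,
                                                     noise_free_texture):
        # noise-free so the residual isolates the deformation machinery
        flow = FlowSpec("uniform", {"dx": 2.0, "dy": 1.0}, seed=8)
        seq = generate_sequence(flow, noise_free_texture, full_mask, 2)
        settings = PIVSettings(pass_window_sizes=(32, 16))
        _, _, xs, ys = _grid(full_mask.shape, 32, 16)
        truth = VelocityField(
            x=xs, y=ys,
            u=np.full((ys.size, xs.size), 2.0),
            v=np.full((ys.size, xs.size), 1.0),
            valid=np.ones((ys.size, xs.size), dtype=bool),
        )
        fld = run_pass(seq.frames[0], seq.frames[1], settings, 1, truth, full_mask)
        corr_u = fld.u[fld.valid] - 2.0
        corr_v = fld.v[fld.valid] - 1.0
        assert np.abs(np.hypot(corr_u, corr_v)).mean() < 0.1


def _grid(shape, window, step):
    from actinflow.piv import _grid_for

    return _grid_for(shape, window, step)


class TestValidateVectors:
    def _uniform_field(self, value=(1.0, 0.5), shape=(6, 6)):
        ny, nx = shape
        return VelocityField(
            x=np.arange(nx) * 8.0 + 7.5, y=np.arange(ny) * 8.0 + 7.5,
            u=np.full(shape, value[0]), v=np.full(shape, value[1]),
            valid=np.ones(shape, dtype=bool),
        )

    def test_single_spike_replaced(self):
        fld = self._uniform_field()
        fld.u[3, 3] = 10.0
        fld.v[3, 3] = 5.0
        out = validate_vectors(fld, PIVSettings())
        assert out.interpolated[3, 3] and out.interpolated.sum() == 1
        assert out.u[3, 3] == pytest.approx(1.0)
        assert out.v[3, 3] == pytest.approx(0.5)
        assert out.valid.all()

    def test_smooth_field_untouched(self):
        fld = self._uniform_field()
        out = validate_vectors(fld, PIVSettings())
        assert not out.interpolated.any()
        assert np.array_equal(out.u, fld.u)

    def test_checkerboard_marked_unreliable(self):
        ny = nx = 6
        u = np.indices((ny, nx)).sum(axis=0) % 2 * 8.0 - 4.0
        fld = VelocityField(
            x=np.arange(nx) * 8.0, y=np.arange(ny) * 8.0,
            u=u, v=-u, valid=np.ones((ny, nx), dtype=bool),
        )
        out = validate_vectors(fld, PIVSettings())
        assert out.unreliable


class TestComputePIV:
    def test_zero_flow_noise_free(self, full_mask, noise_free_texture):
        seq = generate_sequence(FlowSpec("zero", seed=3), noise_free_texture,
                                full_mask, 3)
        for fld in compute_piv(seq, full_mask):
            assert fld.valid.all()
            assert np.abs(fld.u).max() < 1e-6
            assert np.abs(fld.v).max() < 1e-6

    def test_uniform_rms_error(self, full_mask, default_texture):
        flow = FlowSpec("uniform", {"dx": 2.0, "dy": 1.0}, seed=17)
        seq = generate_sequence(flow, default_texture, full_mask, 3)
        fields = compute_piv(seq, full_mask)
        err = np.concatenate(
            [np.hypot(f.u - 2.0, f.v - 1.0)[f.valid & ~f.interpolated]
             for f in fields]
        )
        assert np.sqrt((err ** 2).mean()) < 0.2

    def test_rotation_rate_recovered(self, full_mask, default_texture):
        omega, c = 0.02, 63.5
        flow = FlowSpec("rotation", {"omega": omega, "center": (c, c)}, seed=5)
        seq = generate_sequence(flow, default_texture, full_mask, 4)
        A, b = [], []
        for f in compute_piv(seq, full_mask):
            X, Y = f.grid
            use = f.valid & ~f.interpolated
            A.append(np.concatenate([-(Y[use] - c), X[use] - c]))
            b.append(np.concatenate([f.u[use], f.v[use]]))
        A, b = np.concatenate(A), np.concatenate(b)
        estimate = (A @ b) / (A @ A)
        assert abs(estimate - omega) / omega < 0.10

    def test_shift_equivariance(self, full_mask, default_texture):
        """Translating both frames by the same integer offset leaves interior
        vectors unchanged."""
        flow = FlowSpec("uniform", {"dx": 1.5, "dy": -0.5}, seed=23)
        seq = generate_sequence(flow, default_texture, full_mask, 2)
        # single pass: no deformation, so windows are strictly comparable
        settings = PIVSettings(pass_window_sizes=(16,))
        f = compute_piv(seq, full_mask, settings)[0]
        shifted = np.roll(seq.frames, (8, 8), axis=(1, 2))
        seq2 = type(seq)(frames=shifted, pixel_size_um=seq.pixel_size_um,
                         frame_interval_s=seq.frame_interval_s)
        g = compute_piv(seq2, full_mask, settings)[0]
        # node (x+8, y+8) in the shifted stack sees the same physical window
        both = g.valid[2:-1, 2:-1] & f.valid[1:-2, 1:-2]
        both &= ~g.interpolated[2:-1, 2:-1] & ~f.interpolated[1:-2, 1:-2]
        np.testing.assert_allclose(
            g.u[2:-1, 2:-1][both], f.u[1:-2, 1:-2][both], atol=1e-9
        )
        np.testing.assert_allclose(
            g.v[2:-1, 2:-1][both], f.v[1:-2, 1:-2][both], atol=1e-9
        )

    def test_antisymmetry_under_frame_reversal(self, full_mask, default_texture):
        flow = FlowSpec("uniform", {"dx": 2.0, "dy": 1.0}, seed=29)
        seq = generate_sequence(flow, default_texture, full_mask, 2)
        fwd = compute_piv(seq, full_mask)[0]
        rev_seq = type(seq)(frames=seq.frames[::-1].copy(),
                            pixel_size_um=seq.pixel_size_um,
                            frame_interval_s=seq.frame_interval_s)
        rev = compute_piv(rev_seq, full_mask)[0]
        use = (fwd.valid & rev.valid & ~fwd.interpolated & ~rev.interpolated)[1:-1, 1:-1]
        du = (fwd.u + rev.u)[1:-1, 1:-1][use]
        dv = (fwd.v + rev.v)[1:-1, 1:-1][use]
        assert np.abs(np.hypot(du, dv)).mean() < 0.2

    def test_rotation_90_equivariance(self, full_mask, default_texture):
        """Rotating the stack by 90 deg rotates the recovered uniform flow."""
        flow = FlowSpec("uniform", {"dx": 2.0, "dy": 0.5}, seed=31)
        seq = generate_sequence(flow, default_texture, full_mask, 2)
        base = compute_piv(seq, full_mask)[0]
        rot_frames = np.rot90(seq.frames, k=1, axes=(1, 2)).copy()
        seq_r = type(seq)(frames=rot_frames, pixel_size_um=seq.pixel_size_um,
                          frame_interval_s=seq.frame_interval_s)
        rot = compute_piv(seq_r, full_mask)[0]
        # np.rot90 maps (x, y) -> (y, H-1-x); vectors map (u, v) -> (v, -u)
        u0 = np.nanmean(base.u[base.valid])
        v0 = np.nanmean(base.v[base.valid])
        ur = np.nanmean(rot.u[rot.valid])
        vr = np.nanmean(rot.v[rot.valid])
        assert ur == pytest.approx(v0, abs=0.1)
        assert vr == pytest.approx(-u0, abs=0.1)

    def test_mask_shape_mismatch_rejected(self, full_mask, noise_free_texture):
        seq = generate_sequence(FlowSpec("zero", seed=1), noise_free_texture,
                                full_mask, 2)
        bad_mask = mask_from_array(np.ones((64, 64), dtype=bool))
        with pytest.raises(ConfigurationError):
            compute_piv(seq, bad_mask)

    def test_settings_validation(self):
        with pytest.raises(ConfigurationError):
            PIVSettings(pass_window_sizes=(16, 32))
        with pytest.raises(ConfigurationError):
            PIVSettings(pass_window_sizes=(16, 4))
        with pytest.raises(ConfigurationError):
            PIVSettings(overlap_fraction=1.5)
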