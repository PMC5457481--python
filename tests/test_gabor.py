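"""Gabor construction, bandwidth conversions, fitting, and encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binodepth.gabor import (
    BinocularRF,
    GaborParams1D,
    GaborParams2D,
    bandwidth_octaves,
    classify_encoding,
    fft_bandwidth_octaves,
    fit_gabor_1d,
    load_rf,
    make_binocular_gabor,
    make_gabor_1d,
    pixel_grid,
    save_rf,
    sigma_from_bandwidth,
    wrap_phase,
)


class TestGaborProfiles:
    def test_center_value_is_amplitude_at_zero_phase(self):
        p = GaborParams1D(amplitude=1.0, center=0.0, sigma=4.0, frequency=0.1, phase=0.0)
        assert make_gabor_1d(p, np.array([-1.0, 0.0, 1.0]))[1] == pytest.approx(1.0)

    def test_quadrature_phase_zeroes_the_center(self):
        p = GaborParams1D(1.0, 0.0, 4.0, 0.1, np.pi / 2)
        assert make_gabor_1d(p, np.array([-1.0, 0.0, 1.0]))[1] == pytest.approx(0.0, abs=1e-12)

    def test_even_symmetry_at_zero_phase(self):
        p = GaborParams1D(2.0, 3.0, 5.0, 0.08, 0.0)
        x = np.linspace(-10, 16, 53)
        prof = make_gabor_1d(p, x)
        assert np.allclose(prof, prof[::-1], atol=1e-12)  # grid symmetric about x0=3

    @pytest.mark.parametrize("sigma,freq", [(0.0, 0.1), (-1.0, 0.1), (3.0, 0.0), (3.0, -0.2)])
    def test_invalid_parameters_rejected(self, sigma, freq):
        with pytest.raises(ValueError):
            GaborParams1D(1.0, 0.0, sigma, freq, 0.0)

    def test_phase_is_wrapped_on_construction(self):
        p = GaborParams1D(1.0, 0.0, 3.0, 0.1, 3 * np.pi / 2)
        assert -np.pi <= p.phase <= np.pi
        assert p.phase == pytest.approx(-np.pi / 2)


class TestPhaseWrapping:
    @given(st.floats(-50, 50))
    @settings(max_examples=200, deadline=None)
    def test_wrap_is_idempotent_and_in_range(self, phi):
        w = wrap_phase(phi)
        assert -np.pi <= w <= np.pi
        assert wrap_phase(w) == pytest.approx(w, abs=1e-12)

    def test_branch_point_is_canonical(self):
        # -pi and +pi denote the same phase and map to one endpoint
        assert wrap_phase(np.pi) == pytest.approx(wrap_phase(-np.pi))


class TestBandwidth:
    def test_printed_envelope_width(self):
        # f = 0.0625 cyc/px at 1.5 octaves gives a 6.27 px envelope
        assert sigma_from_bandwidth(0.0625, 1.5) == pytest.approx(6.27, abs=0.01)

    @given(st.floats(0.02, 0.3), st.floats(0.5, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, f, b):
        assert bandwidth_octaves(f, sigma_from_bandwidth(f, b)) == pytest.approx(b, abs=1e-10)

    @pytest.mark.parametrize("b", [1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
    def test_parametric_matches_fft_bandwidth(self, b):
        # the measured FWHM of the synthesized Gabor's amplitude spectrum
        # agrees with the parametric octave bandwidth within 2%; the
        # quadrature profile suppresses the mirrored carrier lobe that
        # otherwise biases broadly tuned profiles
        f = 0.0625
        sigma = sigma_from_bandwidth(f, b)
        x = pixel_grid(4 * int(6 * sigma) + 1)
        prof = make_gabor_1d(GaborParams1D(1.0, 0.0, sigma, f, 0.0), x)
        quad = make_gabor_1d(GaborParams1D(1.0, 0.0, sigma, f, -np.pi / 2), x)
        assert fft_bandwidth_octaves(prof, quadrature=quad) == pytest.approx(b, rel=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sigma_from_bandwidth(-0.1, 1.5)
        with pytest.raises(ValueError):
            sigma_from_bandwidth(0.1, 0.0)


class TestBinocularConstruction:
    def test_zero_offsets_give_identical_eyes(self):
        base = GaborParams2D(1.0, 0.0, 3.0, 0.1, 0.3)
        rf = make_binocular_gabor(base, 0.0, 0.0, (19, 19))
        assert np.array_equal(rf.w_left, rf.w_right)

    def test_pure_position_shift_translates_the_field(self):
        base = GaborParams2D(1.0, 0.0, 3.0, 0.1, 0.0)
        rf = make_binocular_gabor(base, 4.0, 0.0, (21, 21))
        # interior pixels of the right field equal the left field shifted 4 px
        assert np.allclose(rf.w_right[:, 4:], rf.w_left[:, :-4], atol=1e-12)

    def test_pi_phase_shift_inverts_polarity(self):
        base = GaborParams2D(1.0, 0.0, 3.0, 0.1, 0.0)
        rf = make_binocular_gabor(base, 0.0, np.pi, (21, 21))
        assert np.allclose(rf.w_right, -rf.w_left, atol=1e-9)

    def test_mismatched_eye_shapes_rejected(self):
        with pytest.raises(ValueError):
            BinocularRF(np.zeros((5, 5)), np.zeros((5, 6)))


class TestFitting:
    def test_noiseless_recovery(self):
        x = pixel_grid(41)
        truth = GaborParams1D(1.7, 2.0, 5.0, 0.11, 0.8)
        params, r2 = fit_gabor_1d(make_gabor_1d(truth, x), x)
        assert r2 > 0.999
        assert params.amplitude == pytest.approx(truth.amplitude, rel=0.01)
        assert params.center == pytest.approx(truth.center, abs=0.05)
        assert params.sigma == pytest.approx(truth.sigma, rel=0.01)
        assert params.frequency == pytest.approx(truth.frequency, rel=0.01)
        assert params.phase == pytest.approx(truth.phase, abs=0.05)

    def test_noisy_recovery_stays_in_frequency_band(self):
        rng = np.random.default_rng(42)
        x = pixel_grid(41)
        truth = GaborParams1D(1.0, -1.0, 5.0, 0.1, -0.4)
        prof = make_gabor_1d(truth, x) + rng.normal(0, 0.1, x.shape)
        params, r2 = fit_gabor_1d(prof, x)
        assert r2 > 0.9
        assert abs(params.frequency - truth.frequency) / truth.frequency < 0.15

    def test_all_zero_profile_is_degenerate(self):
        x = pixel_grid(32)
        with pytest.raises(ValueError, match="degenerate"):
            fit_gabor_1d(np.zeros(32), x)

    def test_synthesis_fit_round_trip(self):
        x = pixel_grid(51)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            truth = GaborParams1D(
                amplitude=float(rng.uniform(0.5, 2)),
                center=float(rng.uniform(-5, 5)),
                sigma=float(rng.uniform(3, 8)),
                frequency=float(rng.uniform(0.06, 0.15)),
                phase=float(rng.uniform(-3, 3)),
            )
            prof = make_gabor_1d(truth, x)
            params, r2 = fit_gabor_1d(prof, x)
            assert r2 > 0.999
            assert np.allclose(make_gabor_1d(params, x), prof, atol=0.02)


class TestEncodingClassification:
    @pytest.mark.parametrize(
        "dx,dphi",
        [(3.0, 0.0), (0.0, np.pi / 2), (2.0, 0.7), (0.0, 0.9 * np.pi)],
    )
    def test_recovers_generating_offsets(self, dx, dphi):
        base = GaborParams2D(1.0, 0.0, 3.0, 0.1, 0.2)
        rf = make_binocular_gabor(base, dx, dphi, (21, 21))
        enc = classify_encoding(rf)
        assert enc.valid
        assert enc.position_disparity == pytest.approx(dx, abs=0.25)
        assert abs(wrap_phase(enc.phase_disparity - dphi)) < 0.15
        assert -np.pi <= enc.phase_disparity <= np.pi

    def test_non_gabor_filter_flagged(self):
        rng = np.random.default_rng(0)
        rf = BinocularRF(rng.normal(size=(21, 21)), rng.normal(size=(21, 21)))
        enc = classify_encoding(rf, min_r2=0.5)
        assert not enc.valid


def test_rf_serialization_round_trip(tmp_path):
    base = GaborParams2D(1.0, 0.0, 3.0, 0.1, 0.5)
    rf = make_binocular_gabor(base, 2.0, 0.3, (19, 19))
    path = str(tmp_path / "rf.npz")
    save_rf(path, rf)
    loaded = load_rf(path)
    assert np.array_equal(loaded.w_left, rf.w_left)
    assert np.array_equal(loaded.w_right, rf.w_right)
    assert loaded.bias == rf.bias
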