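"""OCE signal chain: phase conversion, surface extraction, filters, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitiwave.fields import Spectrum2D, XTField
from nitiwave.processing import (
    OCTParams,
    bandpass_filter,
    directional_filter,
    extract_surface,
    phase_to_velocity,
    spectrum2d,
)


def plane_wave_field(m_f=6, m_k=8, nt=256, nx=128, dt=1 / 46500.0, dx=54.7e-6,
                     sign=+1):
    """cos(2π(f0 t − sign·k0 x)) with f0, k0 on exact DFT bins (no leakage)."""
    t = np.arange(nt) * dt
    x = np.arange(nx) * dx
    f0 = m_f / (nt * dt)
    k0 = m_k / (nx * dx)
    vz = np.cos(2 * np.pi * (f0 * t[:, None] - sign * k0 * x[None, :]))
    return XTField(x=x, t=t, vz=vz)


class TestPhaseToVelocity:
    def test_zero_and_linearity(self):
        p = OCTParams()
        assert phase_to_velocity(0.0, p) == 0.0
        a = phase_to_velocity(0.3, p)
        assert phase_to_velocity(0.6, p) == pytest.approx(2 * a, rel=1e-12)

    def test_doppler_constant(self):
        # pi rad at 1310 nm, n = 1.38, 46.5 kHz -> 11.036 mm/s
        p = OCTParams(lambda_bar=1310e-9, n_bar=1.38, fs=46500.0)
        v = phase_to_velocity(np.pi, p)
        assert v == pytest.approx(1.1036e-2, rel=1e-4)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.5, 2.0), st.floats(-3.0, 3.0))
    def test_units_consistency(self, scale, dphi):
        # scaling wavelength and sampling period together leaves v_z fixed
        p1 = OCTParams(lambda_bar=1310e-9, n_bar=1.38, fs=46500.0)
        p2 = OCTParams(lambda_bar=1310e-9 * scale, n_bar=1.38, fs=46500.0 / scale)
        assert phase_to_velocity(dphi, p1) == pytest.approx(
            phase_to_velocity(dphi, p2), rel=1e-12, abs=1e-18
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            OCTParams(lambda_bar=-1e-9)
        with pytest.raises(ValueError):
            OCTParams(n_bar=0.5)
        with pytest.raises(ValueError):
            phase_to_velocity(np.nan, OCTParams())


class TestExtractSurface:
    def test_constant_volume_passes_through(self):
        vol = np.full((16, 10, 12), 3.7)
        xt = extract_surface(vol, 0, dz=20e-6, x=np.arange(12) * 1e-4,
                             t=np.arange(16) * 1e-4)
        assert np.allclose(xt.vz, 3.7, rtol=1e-14)

    def test_three_depth_toy_weights(self):
        # values 1, 2, 4 at depths 0, 90, 180 um; weights 1, 0.5, 0.0625
        vol = np.zeros((4, 3, 2))
        vol[:, 0, :], vol[:, 1, :], vol[:, 2, :] = 1.0, 2.0, 4.0
        xt = extract_surface(vol, 0, dz=90e-6, x=np.arange(2) * 1e-4,
                             t=np.arange(4) * 1e-4, window_depth=183e-6, hwhm=90e-6)
        expected = (1 + 2 * 0.5 + 4 * 0.0625) / (1 + 0.5 + 0.0625)
        assert np.allclose(xt.vz, expected, rtol=1e-12)
        assert expected == pytest.approx(1.44)

    def test_truncation_warns_once(self):
        vol = np.random.default_rng(0).normal(size=(8, 4, 6))
        with pytest.warns(UserWarning, match="truncating"):
            extract_surface(vol, 2, dz=50e-6, x=np.arange(6) * 1e-4,
                            t=np.arange(8) * 1e-4)

    def test_depth_resampling_invariance(self):
        # smooth depth profile: halving dz changes the average < 0.5%
        t = np.arange(8) * 1e-4
        x = np.arange(6) * 1e-4
        def volume(dz, ndepth):
            d = np.arange(ndepth) * dz
            profile = 1.0 + 0.5 * np.sin(d / 500e-6)
            return np.broadcast_to(profile[None, :, None], (8, ndepth, 6)).copy()
        a = extract_surface(volume(30e-6, 10), 0, 30e-6, x, t)
        b = extract_surface(volume(15e-6, 20), 0, 15e-6, x, t)
        assert np.abs(a.vz / b.vz - 1).max() < 0.005

    def test_surface_index_bounds(self):
        vol = np.zeros((4, 5, 3))
        with pytest.raises(ValueError, match="surface_index"):
            extract_surface(vol, 7, dz=50e-6, x=np.arange(3.0), t=np.arange(4.0))


class TestDirectionalFilter:
    def test_forward_wave_retained(self):
        xt = plane_wave_field(sign=+1)
        kept = directional_filter(xt, "+x")
        assert kept.energy >= 0.99 * xt.energy

    def test_forward_wave_rejected_in_reverse(self):
        xt = plane_wave_field(sign=+1)
        assert directional_filter(xt, "-x").energy <= 0.01 * xt.energy

    def test_superposition_splits_energy(self):
        fwd = plane_wave_field(sign=+1).vz + plane_wave_field(sign=-1).vz
        xt = XTField(x=np.arange(128) * 54.7e-6, t=np.arange(256) / 46500.0, vz=fwd)
        frac = directional_filter(xt, "+x").energy / xt.energy
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_direction_validation(self):
        with pytest.raises(ValueError):
            directional_filter(plane_wave_field(), "up")


class TestBandpassFilter:
    def test_in_band_amplitude_preserved(self):
        # long tapered in-band tone: interior amplitude change < 1%
        t = np.arange(2048) / 46500.0
        x = np.arange(16) * 54.7e-6
        env = np.hanning(2048)
        vz = (env * np.cos(2 * np.pi * 1000 * t))[:, None] * np.ones((1, 16))
        out = bandpass_filter(XTField(x=x, t=t, vz=vz), 100.0, 4000.0)
        mid = slice(512, 1536)
        ratio = np.abs(out.vz[mid, 0]).max() / np.abs(vz[mid, 0]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_dc_removed(self):
        xt = plane_wave_field()
        shifted = XTField(x=xt.x, t=xt.t, vz=xt.vz + 5.0)
        out = bandpass_filter(shifted, 100.0, 4000.0)
        interior = out.vz[64:192]
        assert abs(interior.mean()) < 1e-3 * 5.0  # DC suppressed
        assert abs(interior.mean()) < 1e-2 * abs(shifted.vz.mean())

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(512) / 46500.0
        x = np.arange(16) * 54.7e-6
        vz = (np.cos(2 * np.pi * 500 * t)[:, None]
              + np.cos(2 * np.pi * 8000 * t)[:, None]) * np.ones((1, 16))
        out = bandpass_filter(XTField(x=x, t=t, vz=vz), 100.0, 4000.0)
        F_in = np.abs(np.fft.rfft(out.vz[:, 0]))
        freqs = np.fft.rfftfreq(512, 1 / 46500.0)
        amp_at = lambda f: F_in[np.argmin(np.abs(freqs - f))]
        assert amp_at(8000.0) < amp_at(500.0) * 10 ** (-40 / 20)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            bandpass_filter(plane_wave_field(), 100.0, 40000.0)


class TestSpectrum2D:
    def test_plane_wave_peak_bin(self):
        xt = plane_wave_field(m_f=6, m_k=8)
        f0 = 6 * 46500.0 / 256
        k0 = 8 / (128 * 54.7e-6)
        spec = spectrum2d(xt)
        fi, ki = np.unravel_index(np.argmax(spec.raw), spec.raw.shape)
        assert abs(spec.freqs[fi] - f0) <= spec.df
        assert abs(spec.wavenumbers[ki] - k0) <= spec.dk

    def test_column_normalization(self, spec_aniso):
        col_max = spec_aniso.power.max(axis=1)
        signal = col_max > 0
        assert np.allclose(col_max[signal], 1.0)
        assert signal.any() and (~signal).any()

    def test_parseval_energy(self, xt_aniso, spec_aniso):
        assert spec_aniso.full_energy == pytest.approx(xt_aniso.energy, rel=1e-6)

    def test_minimum_size(self):
        small = XTField(x=np.arange(4) * 1e-4, t=np.arange(32) * 1e-4,
                        vz=np.zeros((32, 4)))
        with pytest.raises(ValueError, match="at least 8"):
            spectrum2d(small)

    def test_synthesized_ridge_argmax_tracks_branch(self, a0_aniso, spec_aniso):
        cols = (spec_aniso.freqs > 500) & (spec_aniso.freqs < 3500)
        k_br = a0_aniso.k_at(spec_aniso.freqs[cols]) / (2 * np.pi)
        k_pk = spec_aniso.wavenumbers[np.argmax(spec_aniso.power[cols], axis=1)]
        match = np.abs(k_pk - k_br) <= spec_aniso.dk * 1.01
        assert match.mean() >= 0.9

    def test_invariants(self):
        with pytest.raises(ValueError):
            Spectrum2D(freqs=np.arange(4.0), wavenumbers=np.arange(3.0),
                       power=-np.ones((4, 3)))
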