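"""Hologram processing: demodulation round trips, unwrapping, flat-fielding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from conftest import make_bead
from holotomo.forward import (ComplexField2D, RytovPropagator, form_hologram,
                              make_schedule)
from holotomo.holography import (DemodulationError, demodulate,
                                 normalize_background, process_hologram,
                                 unwrap_phase)
from holotomo.phantoms import PhantomSpec, generate_phantom


def _flat_field(n=96, pitch=0.1):
    return ComplexField2D(amplitude=np.ones((n, n)), phase=np.zeros((n, n)),
                          angle_deg=0.0, pixel_pitch_um=pitch)


def _reference_holo(h):
    return form_hologram(_flat_field(h.intensity.shape[0], h.pixel_pitch_um),
                         carrier_cyc_per_um=h.carrier_frequency_cyc_per_um)


def test_zero_object_demodulates_to_flat_phase():
    h = form_hologram(_flat_field())
    out = process_hologram(h, _reference_holo(h))
    b = 8
    assert np.allclose(out.phase[b:-b, b:-b], 0.0, atol=1e-6)
    assert np.allclose(out.amplitude[b:-b, b:-b], 1.0, atol=1e-6)


@pytest.mark.parametrize("state,angle", [("normal", 0.0), ("normal", 45.0),
                                         ("apoptosis", -45.0),
                                         ("autophagy", 0.0)])
def test_roundtrip_recovers_rytov_field(state, angle):
    """form_hologram -> demodulate -> unwrap is the identity on noise-free
    fields (interior RMS below 1e-2 rad)."""
    spec = PhantomSpec.for_state(state, scale=0.45, rng_seed=3)
    tomo = generate_phantom(spec, (128, 128, 128), 0.1)
    f = RytovPropagator(tomo, make_schedule(3)).field(angle)
    h = form_hologram(f)
    out = process_hologram(h, _reference_holo(h))
    b = 8
    rms = np.sqrt(np.mean((out.phase[b:-b, b:-b] - f.phase[b:-b, b:-b]) ** 2))
    assert rms < 1e-2
    cerr = np.sqrt(np.mean(np.abs(out.complex() - f.complex())[b:-b, b:-b]
                           ** 2))
    assert cerr < 1e-2


def test_misspecified_carrier_raises():
    f = _flat_field()
    h = form_hologram(f)
    h.carrier_frequency_cyc_per_um = (0.3, -2.2)
    with pytest.raises(DemodulationError):
        demodulate(h)


def test_no_sideband_raises():
    h = form_hologram(_flat_field())
    h.intensity = np.ones_like(h.intensity)
    with pytest.raises(DemodulationError):
        demodulate(h)


class TestUnwrap:
    def test_planar_ramp_recovered_exactly(self):
        x = np.linspace(0, 6 * np.pi, 128)
        ramp = np.broadcast_to(x, (64, 128)).copy()
        wrapped = np.angle(np.exp(1j * ramp))
        un = unwrap_phase(wrapped)
        # equal up to one global 2 pi multiple
        diff = un - ramp
        assert np.allclose(diff, np.round(diff[0, 0] / (2 * np.pi))
                           * 2 * np.pi, atol=1e-9)

    def test_all_zero_input(self):
        assert np.array_equal(unwrap_phase(np.zeros((32, 32))),
                              np.zeros((32, 32)))

    def test_sphere_phase_beyond_2pi_matches_optical_path(self):
        tomo = make_bead(9.0, 1.334 + 0.04, 168, 0.12)
        f = RytovPropagator(tomo, make_schedule(3)).field(0.0)
        wrapped = np.angle(np.exp(1j * f.phase))
        un = unwrap_phase(wrapped)
        expected = 2 * np.pi * 0.04 * 18.0 / 0.6328
        assert un.max() > 2 * np.pi  # genuinely wrapped input
        assert un.max() == pytest.approx(expected, rel=0.02)

    @given(seed=st.integers(0, 1000), scale=st.floats(1.0, 8.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_congruence_mod_2pi(self, seed, scale):
        """(unwrapped - wrapped) is an integer multiple of 2 pi everywhere."""
        rng = np.random.default_rng(seed)
        smooth = ndi.gaussian_filter(rng.standard_normal((48, 48)), 4) * scale
        wrapped = np.angle(np.exp(1j * smooth))
        un = unwrap_phase(wrapped)
        k = (un - wrapped) / (2 * np.pi)
        assert np.allclose(k, np.round(k), atol=1e-9)


class TestNormalizeBackground:
    def test_identity(self):
        f = _flat_field(48)
        f2 = ComplexField2D(amplitude=f.amplitude * 1.7,
                            phase=f.phase + 0.4, angle_deg=0.0,
                            pixel_pitch_um=0.1)
        out = normalize_background(f2, f2)
        assert np.allclose(out.amplitude, 1.0)
        assert np.allclose(out.phase, 0.0)

    def test_common_tilt_cancels(self):
        n = 48
        tilt = np.linspace(0, 2.0, n)[None, :] * np.ones((n, 1))
        a = ComplexField2D(amplitude=np.ones((n, n)), phase=tilt + 0.2,
                           angle_deg=0.0, pixel_pitch_um=0.1)
        b = ComplexField2D(amplitude=np.ones((n, n)), phase=tilt,
                           angle_deg=0.0, pixel_pitch_um=0.1)
        out = normalize_background(a, b)
        assert np.allclose(out.phase, 0.2, atol=1e-12)

    def test_zero_amplitude_reference_masked(self):
        f = _flat_field(32)
        ref = ComplexField2D(amplitude=np.zeros((32, 32)),
                             phase=np.zeros((32, 32)), angle_deg=0.0,
                             pixel_pitch_um=0.1)
        out = normalize_background(f, ref)
        assert np.all(np.isfinite(out.amplitude))

    def test_noisy_no_sample_pair_residual_phase(self):
        """1% hologram noise leaves < 0.05 rad RMS residual phase."""
        f = _flat_field()
        h = form_hologram(f, noise_level=0.01, noise_seed=5)
        ref = form_hologram(f, noise_level=0.01, noise_seed=6)
        out = process_hologram(h, ref)
        b = 8
        rms = np.sqrt(np.mean(out.phase[b:-b, b:-b] ** 2))
        assert rms < 0.05
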