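"""Direct inversion: Ewald geometry, accuracy, missing cone, positivity."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import make_bead
from holotomo.core import MEDIUM_RI, WAVELENGTH_UM, RITomogram, k_axis
from holotomo.forward import (ComplexField2D, RytovPropagator, make_schedule)
from holotomo.reconstruct import (ScatteringSpectrum3D, apply_positivity,
                                  invert_spectrum, map_to_ewald,
                                  reconstruct_tomogram)


def _flat(n, pitch, angle=0.0):
    return ComplexField2D(amplitude=np.ones((n, n)), phase=np.zeros((n, n)),
                          angle_deg=angle, pixel_pitch_um=pitch)


def test_zero_field_leaves_spectrum_values_zero(schedule21):
    spec = ScatteringSpectrum3D.for_grid((48, 48, 48), 0.1)
    map_to_ewald(_flat(48, 0.1), 0.0, schedule21, spec)
    assert np.all(spec.values == 0)
    assert spec.weights.sum() > 0  # the cap was visited


def test_single_angle_samples_lie_on_canonical_cap(schedule21):
    """Deposited voxels at normal incidence satisfy |K + k_m z| = k_m."""
    n, pitch = 64, 0.1
    tomo = make_bead(0.5, 1.34, n, pitch)
    f = RytovPropagator(tomo, schedule21).field(0.0)
    spec = ScatteringSpectrum3D.for_grid((n,) * 3, pitch)
    map_to_ewald(f, 0.0, schedule21, spec)
    km = schedule21.k_medium
    kax = k_axis(n, pitch)
    KX, KY, KZ = np.meshgrid(kax, kax, kax, indexing="ij")
    hit = spec.weights > 0
    r = np.sqrt(KX[hit] ** 2 + KY[hit] ** 2 + (KZ[hit] + km) ** 2)
    dk = kax[1] - kax[0]
    assert np.all(np.abs(r - km) < 2 * dk)


def test_symmetric_phantom_inversion_nearly_real(schedule21):
    """+-theta pairs of a symmetric phantom give a nearly real potential."""
    n, pitch = 64, 0.1
    tomo = make_bead(1.5, 1.35, n, pitch)
    prop = RytovPropagator(tomo, schedule21)
    spec = ScatteringSpectrum3D.for_grid((n,) * 3, pitch)
    for ang in (-30.0, 30.0):
        map_to_ewald(prop.field(ang), ang, schedule21, spec)
    avg = np.where(spec.weights > 0,
                   spec.values / np.maximum(spec.weights, 1e-30), 0)
    f = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(avg)))
    assert np.linalg.norm(f.imag) < 0.15 * np.linalg.norm(f.real)


def test_uniform_fields_reconstruct_to_medium(schedule21):
    n, pitch = 48, 0.1
    spec = ScatteringSpectrum3D.for_grid((n,) * 3, pitch)
    for ang in (-30.0, 0.0, 30.0):
        map_to_ewald(_flat(n, pitch, ang), ang, schedule21, spec)
    tomo = invert_spectrum(spec, MEDIUM_RI, WAVELENGTH_UM)
    assert np.allclose(tomo.values, MEDIUM_RI, atol=1e-9)


def test_all_zero_spectrum_rejected():
    spec = ScatteringSpectrum3D.for_grid((16, 16, 16), 0.1)
    with pytest.raises(ValueError):
        invert_spectrum(spec, MEDIUM_RI, WAVELENGTH_UM)


def test_single_angle_projection_limit():
    """At normal incidence the axial integral of (n - n_m) recovers the
    phase profile scaled by lambda / 2 pi (weak smooth object)."""
    n, pitch = 96, 0.1
    x = (np.arange(n) - n // 2) * pitch
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    vals = (MEDIUM_RI
            + 0.005 * np.exp(-(X**2 + Y**2 + Z**2) / (2 * 1.5**2)))
    tomo = RITomogram(vals.astype(np.float32), pitch)
    sch = make_schedule(1, (0, 0))
    f = RytovPropagator(tomo, sch).field(0.0)
    recon = reconstruct_tomogram([f], sch, (n,) * 3, pitch)
    proj = (recon.values.astype(np.float64) - MEDIUM_RI).sum(axis=2) * pitch
    expected = f.phase * WAVELENGTH_UM / (2 * np.pi)
    assert proj.max() == pytest.approx(expected.max(), rel=0.02)


class TestBeadAccuracy:
    @pytest.fixture(scope="class")
    def bead_run(self, bead4um):
        sch = make_schedule(61)
        prop = RytovPropagator(bead4um, sch)
        n = bead4um.shape[0]
        spec = ScatteringSpectrum3D.for_grid((n,) * 3, 0.1)
        for ang in sch.angles_deg:
            map_to_ewald(prop.field(ang), ang, sch, spec)
        tomo = invert_spectrum(spec, MEDIUM_RI, WAVELENGTH_UM)
        return sch, spec, tomo

    def test_core_ri_recovered(self, bead_run, bead4um):
        _, _, tomo = bead_run
        X, Y, Z = bead4um.meshgrid()
        core = X**2 + Y**2 + Z**2 <= 1.0**2
        assert abs(float(tomo.values[core].mean()) - 1.36) < 5e-3

    def test_missing_cone_and_axial_elongation(self, bead_run):
        sch, spec, tomo = bead_run
        n = spec.values.shape[0]
        kax = k_axis(n, 0.1)
        KX, KY, KZ = np.meshgrid(kax, kax, kax, indexing="ij")
        ball = KX**2 + KY**2 + KZ**2 <= (sch.k0 * sch.detection_na) ** 2
        zero_frac = float(((spec.weights == 0) & ball).sum() / ball.sum())
        assert zero_frac > 0
        mask = tomo.values >= 1.34
        zext = np.flatnonzero(mask.any(axis=(0, 1))).size
        xext = np.flatnonzero(mask.any(axis=(1, 2))).size
        assert zext / xext > 1.0

    def test_positivity_reduces_elongation(self, bead_run):
        sch, spec, tomo = bead_run
        def elong(t):
            m = t.values >= 1.34
            return (np.flatnonzero(m.any(axis=(0, 1))).size
                    / np.flatnonzero(m.any(axis=(1, 2))).size)
        reg = apply_positivity(tomo, MEDIUM_RI, 30, spec, WAVELENGTH_UM)
        assert elong(reg) <= elong(tomo)


class TestPositivity:
    def test_zero_iterations_is_identity(self, bead4um):
        out = apply_positivity(bead4um, n_iterations=0)
        assert out is bead4um

    def test_uniform_tomogram_is_fixed_point(self):
        tomo = RITomogram(np.full((32, 32, 32), MEDIUM_RI, dtype=np.float32),
                          0.1)
        out = apply_positivity(tomo, MEDIUM_RI, 5)
        assert np.allclose(out.values, MEDIUM_RI, atol=1e-6)

    def test_negative_iterations_rejected(self, bead4um):
        with pytest.raises(ValueError):
            apply_positivity(bead4um, n_iterations=-1)


def test_weak_phantom_linearity(schedule21):
    """Reconstruction of two well-separated weak beads equals the sum of the
    individual reconstructions (first-order regime)."""
    n, pitch = 64, 0.1
    x = (np.arange(n) - n // 2) * pitch
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")

    def bead_at(cx):
        v = np.where((X - cx) ** 2 + Y**2 + Z**2 <= 1.0,
                     MEDIUM_RI + 0.004, MEDIUM_RI)
        return RITomogram(v.astype(np.float32), pitch)

    def recon(tomo):
        prop = RytovPropagator(tomo, schedule21)
        fields = [prop.field(a) for a in schedule21.angles_deg]
        out = reconstruct_tomogram(fields, schedule21, (n,) * 3, pitch)
        return out.values.astype(np.float64) - MEDIUM_RI

    both = np.where(((X - 1.6) ** 2 + Y**2 + Z**2 <= 1.0)
                    | ((X + 1.6) ** 2 + Y**2 + Z**2 <= 1.0),
                    MEDIUM_RI + 0.004, MEDIUM_RI).astype(np.float32)
    d_both = recon(RITomogram(both, pitch))
    d_sum = recon(bead_at(1.6)) + recon(bead_at(-1.6))
    assert np.linalg.norm(d_both - d_sum) < 0.01 * np.linalg.norm(d_both)
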