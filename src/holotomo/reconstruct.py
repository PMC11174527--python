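"""Direct-inversion holographic tomography (Fourier diffraction theorem).

Each angle's unwrapped complex Rytov phase is Fourier transformed and placed
on the Ewald-sphere cap belonging to its illumination direction; the caps are
accumulated with weights into a 3D scattering-potential spectrum, the
weighted average is inverse transformed, and the potential is converted back
to refractive index:

    F(k_s - k_in) = -2 i k_z U_s(k_perp),    k_z = sqrt(k_m^2 - |k_perp|^2)
    f(r) = k0^2 (n(r)^2 - n_m^2)   ->   n(r) = sqrt(n_m^2 + f(r) / k0^2)

With a +-45 degree scan the spectrum has an unsampled missing cone around
the axial frequency axis; reconstructions therefore elongate along z.  An
optional Gerchberg-Papoulis non-negativity constraint
(:func:`apply_positivity`) mitigates the missing cone by alternating the
real-space constraint n >= n_m with re-imposition of the measured caps.

Cap samples are spread onto the spectrum grid with trilinear weights by
default; nearest-voxel deposition is available but noticeably less accurate
for quantitative RI values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import RITomogram, fft2c, fftnc, ifftnc, k_axis
from .forward import ComplexField2D, IlluminationSchedule

log = logging.getLogger(__name__)


@dataclass
class ScatteringSpectrum3D:
    """Accumulated 3D spectrum of the scattering potential.

    ``values`` holds weighted sums of cap samples and ``weights`` the
    accumulated deposition weights; the weighted average is formed at
    inversion time.  ``grid_pitch_cyc_per_um`` is the spectral voxel pitch in
    cycles/um (identical on all axes).
    """

    values: np.ndarray
    weights: np.ndarray
    grid_pitch_cyc_per_um: float

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must share one grid")

    @classmethod
    def for_grid(cls, grid_shape: tuple[int, int, int],
                 voxel_pitch_um: float) -> "ScatteringSpectrum3D":
        """Empty spectrum matched to a real-space grid."""
        n = grid_shape[0]
        if any(s != n for s in grid_shape):
            raise ValueError("spectrum grid must be cubic")
        return cls(values=np.zeros(grid_shape, dtype=np.complex128),
                   weights=np.zeros(grid_shape, dtype=np.float64),
                   grid_pitch_cyc_per_um=1.0 / (n * voxel_pitch_um))

    @property
    def voxel_pitch_um(self) -> float:
        """Real-space voxel pitch of the matched tomogram grid."""
        n = self.values.shape[0]
        return 1.0 / (n * self.grid_pitch_cyc_per_um)


def map_to_ewald(field: ComplexField2D, angle_deg: float,
                 schedule: IlluminationSchedule,
                 spectrum: ScatteringSpectrum3D,
                 spreading: str = "trilinear") -> ScatteringSpectrum3D:
    """Deposit one angle's field onto its Ewald cap in the 3D spectrum.

    The field must be illumination-referenced (amplitude ratio + unwrapped
    phase).  Its complex Rytov phase is multiplied back onto the tilted
    plane-wave carrier, Fourier transformed, scaled by the diffraction-
    theorem factor and spread onto the spectrum grid.  Samples outside the
    detection NA (evanescent or uncollected) are discarded and counted in
    the log.  Returns the updated spectrum (mutated in place).
    """
    if spreading not in ("trilinear", "nearest"):
        raise ValueError(f"unknown spreading {spreading!r}")
    n = spectrum.values.shape[0]
    if field.amplitude.shape != (n, n):
        raise ValueError("field grid does not match the spectrum grid")
    p = field.pixel_pitch_um
    if abs(p - spectrum.voxel_pitch_um) > 1e-9 * p:
        raise ValueError("field pixel pitch does not match the spectrum")

    k0 = schedule.k0
    km = schedule.k_medium
    kax = k_axis(n, p)
    dk = kax[1] - kax[0]
    kx, ky = np.meshgrid(kax, kax, indexing="ij")
    kperp2 = kx**2 + ky**2
    valid = kperp2 <= min(k0 * schedule.detection_na, km) ** 2
    n_discard = int((~valid).sum())
    if n_discard:
        log.debug("map_to_ewald: %d detector samples outside the NA "
                  "discarded", n_discard)
    kz = np.sqrt(np.maximum(km**2 - kperp2, 0.0))
    kin = schedule.illumination_wavevector(angle_deg)

    x = (np.arange(n) - n // 2) * p
    X, Y = np.meshgrid(x, x, indexing="ij")
    uin = np.exp(1j * (kin[0] * X + kin[1] * Y))
    psi = np.log(np.maximum(field.amplitude, 1e-12)) + 1j * field.phase
    Us = fft2c(uin * psi) * p**2
    Fest = -2j * kz[valid] * Us[valid]

    ci = (kx[valid] - kin[0] - kax[0]) / dk
    cj = (ky[valid] - kin[1] - kax[0]) / dk
    ck = (kz[valid] - kin[2] - kax[0]) / dk
    _deposit(spectrum.values, spectrum.weights, ci, cj, ck, Fest, spreading)
    return spectrum


def _deposit(S, W, ci, cj, ck, vals, spreading):
    n = S.shape[0]
    if spreading == "nearest":
        ii = np.rint(ci).astype(int)
        jj = np.rint(cj).astype(int)
        kk = np.rint(ck).astype(int)
        ok = ((ii >= 0) & (ii < n) & (jj >= 0) & (jj < n)
              & (kk >= 0) & (kk < n))
        np.add.at(S, (ii[ok], jj[ok], kk[ok]), vals[ok])
        np.add.at(W, (ii[ok], jj[ok], kk[ok]), 1.0)
        return
    i0 = np.floor(ci).astype(int)
    j0 = np.floor(cj).astype(int)
    k0i = np.floor(ck).astype(int)
    fi, fj, fk = ci - i0, cj - j0, ck - k0i
    for di in (0, 1):
        wi = fi if di else 1 - fi
        for dj in (0, 1):
            wj = fj if dj else 1 - fj
            for dzk in (0, 1):
                w = wi * wj * (fk if dzk else 1 - fk)
                ii, jj, kk = i0 + di, j0 + dj, k0i + dzk
                ok = ((ii >= 0) & (ii < n) & (jj >= 0) & (jj < n)
                      & (kk >= 0) & (kk < n) & (w > 0))
                np.add.at(S, (ii[ok], jj[ok], kk[ok]), w[ok] * vals[ok])
                np.add.at(W, (ii[ok], jj[ok], kk[ok]), w[ok])


def invert_spectrum(spectrum: ScatteringSpectrum3D, medium_ri: float,
                    wavelength_um: float) -> RITomogram:
    """Weight-average the spectrum and inverse transform it to an RI volume.

    The imaginary residual of the recovered potential (absorption plus
    inconsistency between overlapping caps) is discarded after its relative
    magnitude is logged.
    """
    W = spectrum.weights
    if not np.any(W > 0):
        raise ValueError("cannot invert an all-zero spectrum")
    avg = np.where(W > 0, spectrum.values / np.maximum(W, 1e-30), 0.0)
    p = spectrum.voxel_pitch_um
    f = ifftnc(avg) / p**3
    imag_ratio = float(np.linalg.norm(f.imag) / max(np.linalg.norm(f.real),
                                                    1e-30))
    log.info("invert_spectrum: imaginary residual %.2e of the real part",
             imag_ratio)
    k0 = 2 * np.pi / wavelength_um
    n = np.sqrt(np.maximum(medium_ri**2 + f.real / k0**2, 0.0))
    return RITomogram(n.astype(np.float32), voxel_pitch_um=p,
                      medium_ri=medium_ri)


def apply_positivity(tomo: RITomogram, medium_ri: float | None = None,
                     n_iterations: int = 0,
                     spectrum: ScatteringSpectrum3D | None = None,
                     wavelength_um: float = 0.6328) -> RITomogram:
    """Gerchberg-Papoulis missing-cone mitigation.

    Alternates the real-space constraint ``n >= medium_ri`` with
    re-imposition of the measured cap values in Fourier space.  Without a
    measured ``spectrum`` only the real-space clamp is applied (a single
    projection).  ``n_iterations = 0`` returns the input unchanged.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    if n_iterations == 0:
        return tomo
    nm = tomo.medium_ri if medium_ri is None else medium_ri
    vals = np.asarray(tomo.values, dtype=np.float64)
    if spectrum is None:
        return RITomogram(np.maximum(vals, nm).astype(np.float32),
                          voxel_pitch_um=tomo.voxel_pitch_um, medium_ri=nm)
    W = spectrum.weights
    measured = W > 0
    meas_vals = np.where(measured, spectrum.values / np.maximum(W, 1e-30), 0.0)
    k0 = 2 * np.pi / wavelength_um
    p = tomo.voxel_pitch_um
    g = k0**2 * (vals**2 - nm**2)
    for _ in range(n_iterations):
        n_clamped = np.sqrt(np.maximum(nm**2 + g / k0**2, nm**2))
        g = k0**2 * (n_clamped**2 - nm**2)
        G = fftnc(g) * p**3
        G[measured] = meas_vals[measured]
        g = (ifftnc(G) / p**3).real
    n_out = np.sqrt(np.maximum(nm**2 + g / k0**2, nm**2))
    return RITomogram(n_out.astype(np.float32), voxel_pitch_um=p,
                      medium_ri=nm)


def reconstruct_tomogram(fields, schedule: IlluminationSchedule,
                         grid_shape: tuple[int, int, int],
                         voxel_pitch_um: float,
                         spreading: str = "trilinear",
                         positivity_iterations: int = 0) -> RITomogram:
    """Convenience chain: accumulate all fields and invert.

    ``fields`` is an iterable of illumination-referenced
    :class:`ComplexField2D` (one per schedule angle, unwrapped phase).
    """
    spectrum = ScatteringSpectrum3D.for_grid(grid_shape, voxel_pitch_um)
    for f in fields:
        map_to_ewald(f, f.angle_deg, schedule, spectrum, spreading=spreading)
    tomo = invert_spectrum(spectrum, schedule.medium_ri,
                           schedule.wavelength_um)
    if positivity_iterations > 0:
        tomo = apply_positivity(tomo, schedule.medium_ri,
                                positivity_iterations, spectrum,
                                schedule.wavelength_um)
    return tomo
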