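"""Forward optical model: angle-scanned Rytov fields and off-axis holograms.

The acquisition emulated here is a Mach-Zehnder holographic-tomography setup:
a He-Ne object beam (632.8 nm) scans the sample over -45..45 degrees (241
angles by default), the transmitted wavefront is collected by a 1.2-NA
water-immersion objective and interfered with a reference beam to form an
off-axis hologram per angle.

Scattering model
----------------
First Rytov approximation computed through the Fourier diffraction theorem:
for illumination wavevector ``k_in`` (|k_in| = n_m k0) the first-Born
scattered field at the central plane of the volume is obtained by sampling
the 3D spectrum of the scattering potential ``f = k0^2 (n^2 - n_m^2)`` on
the Ewald cap,

    U_s(k_perp) = (i / (2 k_z)) F(k - k_in),   k = (k_perp, k_z),
    k_z = sqrt(n_m^2 k0^2 - |k_perp|^2),

restricted to the detection NA, and the Rytov field is the complex
exponential of psi = u_s / u_in.  Fields are referenced to the illumination
(amplitude ratio and relative phase), i.e. a sample-free acquisition has
amplitude 1 and phase 0.

The reference arm is descanned: its tilt tracks the illumination so that the
hologram sideband sits at a fixed carrier for every scan angle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.restoration import unwrap_phase as _unwrap_2d

from .core import (MEDIUM_RI, WAVELENGTH_UM, RITomogram, fft2c, fftnc,
                   ifft2c, k_axis)

log = logging.getLogger(__name__)

#: Default refractive-index contrast above which a Rytov-validity warning is
#: emitted (the model degrades gracefully, it does not fail).
RYTOV_CONTRAST_BOUND = 0.1


class CarrierSeparationError(ValueError):
    """Carrier too small to separate the sideband from the autocorrelation."""


@dataclass(frozen=True)
class IlluminationSchedule:
    """Angle-scan geometry of one tomographic acquisition.

    ``rotation_axis`` is the transverse axis about which the illumination
    direction rocks; the default (y) tilts the beam in the x-z plane.
    """

    angles_deg: tuple[float, ...]
    wavelength_um: float = WAVELENGTH_UM
    illumination_na: float = 0.8
    detection_na: float = 1.2
    medium_ri: float = MEDIUM_RI
    rotation_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.size == 0:
            raise ValueError("schedule needs at least one angle")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(np.abs(a) > 90):
            raise ValueError("angles outside the physical range [-90, 90]")
        ax = np.asarray(self.rotation_axis, dtype=float)
        if abs(ax[2]) > 1e-12 or np.linalg.norm(ax) == 0:
            raise ValueError("rotation_axis must be a transverse unit vector")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber, rad/um."""
        return 2 * np.pi / self.wavelength_um

    @property
    def k_medium(self) -> float:
        """Wavenumber in the medium, rad/um."""
        return self.k0 * self.medium_ri

    @property
    def tilt_direction(self) -> np.ndarray:
        """Transverse unit vector along which the illumination tilts."""
        ax = np.asarray(self.rotation_axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        return np.cross(ax, (0.0, 0.0, 1.0))

    def illumination_wavevector(self, angle_deg: float) -> np.ndarray:
        """3-vector k_in for one scan angle (rad/um, |k_in| = k_medium)."""
        t = np.deg2rad(angle_deg)
        m = self.tilt_direction
        d = np.array([m[0] * np.sin(t), m[1] * np.sin(t), np.cos(t)])
        return self.k_medium * d


def make_schedule(n_angles: int = 241,
                  span_deg: tuple[float, float] = (-45.0, 45.0),
                  **kwargs) -> IlluminationSchedule:
    """Evenly spaced scan angles spanning a closed interval, endpoints included."""
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    lo, hi = span_deg
    if lo > hi or lo < -90 or hi > 90:
        raise ValueError(f"span {span_deg} outside the physical range")
    angles = np.linspace(lo, hi, n_angles)
    return IlluminationSchedule(angles_deg=tuple(angles), **kwargs)


@dataclass
class ComplexField2D:
    """Illumination-referenced complex wavefront for one scan angle.

    ``amplitude`` is the amplitude ratio to the unscattered beam and
    ``phase`` the (unwrapped) relative phase in radians; both share shape.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    angle_deg: float
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must share one grid")

    def complex(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class Hologram:
    """Off-axis intensity hologram for one scan angle."""

    intensity: np.ndarray
    pixel_pitch_um: float
    carrier_frequency_cyc_per_um: tuple[float, float]
    angle_deg: float = 0.0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")


class RytovPropagator:
    """Precomputed forward model for one tomogram.

    Computes the 3D spectrum of the scattering potential once and samples it
    on the (NA-limited) Ewald cap per angle.  Use this class directly when
    propagating many angles; :func:`propagate_field` is the one-shot wrapper.
    """

    def __init__(self, tomo: RITomogram, schedule: IlluminationSchedule):
        self.tomo = tomo
        self.schedule = schedule
        p = tomo.voxel_pitch_um
        self._check_sampling(p)
        n = np.asarray(tomo.values, dtype=np.float64)
        nm = tomo.medium_ri
        contrast = float(np.max(np.abs(n - nm)))
        if contrast > RYTOV_CONTRAST_BOUND:
            warnings.warn(
                f"RI contrast {contrast:.3f} exceeds the Rytov validity "
                f"bound {RYTOV_CONTRAST_BOUND}; results degrade gradually",
                stacklevel=2)
        k0 = schedule.k0
        f = k0**2 * (n**2 - nm**2)
        self._F = fftnc(f) * p**3
        self._kaxes = [k_axis(s, p) for s in tomo.shape]
        kx, ky = np.meshgrid(self._kaxes[0], self._kaxes[1], indexing="ij")
        km = schedule.k_medium
        kperp2 = kx**2 + ky**2
        self.na_mask = kperp2 <= min(k0 * schedule.detection_na, km) ** 2
        self._kx, self._ky = kx, ky
        self._kz = np.sqrt(np.maximum(km**2 - kperp2, 0.0))
        ax = [tomo.axis_coords(0), tomo.axis_coords(1)]
        self._X, self._Y = np.meshgrid(ax[0], ax[1], indexing="ij")

    def _check_sampling(self, p: float) -> None:
        s = self.schedule
        span = max(abs(a) for a in s.angles_deg)
        kmax = s.k_medium * np.sin(np.deg2rad(span)) + s.k0 * s.detection_na
        if kmax > np.pi / p * (1 + 1e-9):
            raise ValueError(
                f"voxel pitch {p} um undersamples the tilted field "
                f"(need pitch <= {np.pi / kmax:.3f} um)")

    def rytov_phase(self, angle_deg: float) -> np.ndarray:
        """Complex Rytov phase psi(x, y) at the volume mid-plane."""
        kin = self.schedule.illumination_wavevector(angle_deg)
        dks = [ax[1] - ax[0] for ax in self._kaxes]
        m = self.na_mask
        coords = np.stack([
            (self._kx[m] - kin[0] - self._kaxes[0][0]) / dks[0],
            (self._ky[m] - kin[1] - self._kaxes[1][0]) / dks[1],
            (self._kz[m] - kin[2] - self._kaxes[2][0]) / dks[2],
        ])
        Fc = (map_coordinates(self._F.real, coords, order=1, cval=0.0)
              + 1j * map_coordinates(self._F.imag, coords, order=1, cval=0.0))
        Us = np.zeros(m.shape, dtype=np.complex128)
        Us[m] = (1j / (2 * self._kz[m])) * Fc
        nx, ny = m.shape
        scale = nx * ny * dks[0] * dks[1] / (2 * np.pi) ** 2
        us = ifft2c(Us) * scale
        uin = np.exp(1j * (kin[0] * self._X + kin[1] * self._Y))
        return us / uin

    def field(self, angle_deg: float) -> ComplexField2D:
        """NA-limited exit field (amplitude ratio + unwrapped phase).

        The Rytov field exp(psi) is low-passed by the detection-NA pupil —
        the collection objective truncates the exit field itself, not the
        Rytov phase — and the phase of the filtered field is unwrapped.
        """
        psi = self.rytov_phase(angle_deg)
        o = np.exp(psi)
        o_na = ifft2c(fft2c(o) * self.na_mask)
        phase = np.angle(o_na)
        if np.ptp(psi.imag) > 1.8 * np.pi:
            phase = np.asarray(_unwrap_2d(phase))
            b = max(2, min(8, min(phase.shape) // 4))
            edge = np.ones(phase.shape, dtype=bool)
            edge[b:-b, b:-b] = False
            phase -= 2 * np.pi * np.round(np.median(phase[edge]) / (2 * np.pi))
        return ComplexField2D(
            amplitude=np.abs(o_na), phase=phase,
            angle_deg=float(angle_deg),
            pixel_pitch_um=self.tomo.voxel_pitch_um)


def propagate_field(tomo: RITomogram, angle_deg: float,
                    schedule: IlluminationSchedule) -> ComplexField2D:
    """Illumination-referenced Rytov field of ``tomo`` at one scan angle."""
    return RytovPropagator(tomo, schedule).field(angle_deg)


def default_carrier(shape: tuple[int, int],
                    pixel_pitch_um: float) -> tuple[float, float]:
    """Diagonal carrier at 0.54 of Nyquist per axis, snapped onto the FFT grid.

    For weak-phase objects the hologram autocorrelation term is first-order
    suppressed beyond the object band, so this placement lets the
    demodulation window pass the full detection-NA band while the sideband
    still clears both the DC term and the Nyquist edge.
    """
    fc = []
    for n in shape:
        idx = max(1, round(0.27 * n))
        fc.append(idx / (n * pixel_pitch_um))
    return tuple(fc)


def _object_bandwidth(obj: np.ndarray, pitch: float) -> float:
    """Radius (rad/um) containing 99% of the off-DC spectral energy."""
    spec = np.abs(fft2c(obj - obj.mean())) ** 2
    kx = k_axis(obj.shape[0], pitch)
    ky = k_axis(obj.shape[1], pitch)
    kr = np.hypot(*np.meshgrid(kx, ky, indexing="ij"))
    order = np.argsort(kr, axis=None)
    cum = np.cumsum(spec.ravel()[order])
    if cum[-1] == 0:
        return 0.0
    cut = np.searchsorted(cum, 0.99 * cum[-1])
    return float(kr.ravel()[order][min(cut, cum.size - 1)])


def form_hologram(field: ComplexField2D,
                  carrier_cyc_per_um: tuple[float, float] | None = None,
                  noise_level: float = 0.0,
                  noise_seed: int | None = None) -> Hologram:
    """Interfere the object field with a unit descanned reference beam.

    The recorded intensity is ``|o exp(2 pi i f_c . r) + 1|^2`` with ``o``
    the illumination-referenced object field, optionally degraded by
    multiplicative Gaussian noise of relative strength ``noise_level``.

    Raises
    ------
    CarrierSeparationError
        If the carrier magnitude does not exceed the object bandwidth.
    """
    p = field.pixel_pitch_um
    if carrier_cyc_per_um is None:
        carrier_cyc_per_um = default_carrier(field.amplitude.shape, p)
    o = field.complex()
    kc = 2 * np.pi * np.asarray(carrier_cyc_per_um)
    bw = _object_bandwidth(o, p)
    if np.hypot(*kc) <= bw:
        raise CarrierSeparationError(
            f"carrier magnitude {np.hypot(*kc):.2f} rad/um does not exceed "
            f"the object bandwidth {bw:.2f} rad/um")
    nx, ny = o.shape
    x = (np.arange(nx) - nx // 2) * p
    y = (np.arange(ny) - ny // 2) * p
    X, Y = np.meshgrid(x, y, indexing="ij")
    obj = o * np.exp(1j * (kc[0] * X + kc[1] * Y))
    intensity = np.abs(obj + 1.0) ** 2
    if noise_level > 0:
        rng = np.random.default_rng(noise_seed)
        intensity = intensity * (1.0 + noise_level * rng.standard_normal(
            intensity.shape))
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity=intensity, pixel_pitch_um=p,
                    carrier_frequency_cyc_per_um=tuple(carrier_cyc_per_um),
                    angle_deg=field.angle_deg, noise_seed=noise_seed)
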