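"""Shared containers and numerical helpers.

The central object of the package is the :class:`RITomogram`: a 3D scalar
refractive-index (RI) volume on an isotropic voxel grid, immersed in a
homogeneous medium (phosphate-buffered saline, RI 1.334, unless stated
otherwise).  Axis order is ``(x, y, z)`` with ``z`` the optical axis;
coordinates refer to voxel centers and the grid is centered on the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Refractive index of the PBS imaging medium.
MEDIUM_RI = 1.334

#: He-Ne laser wavelength in micrometers.
WAVELENGTH_UM = 0.6328


class SizingError(ValueError):
    """An object does not fit on the requested grid."""


class PlacementError(RuntimeError):
    """A compartment could not be placed after bounded retries."""


@dataclass
class RITomogram:
    """3D refractive-index volume on an isotropic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Refractive index per voxel (dimensionless).
    voxel_pitch_um : float
        Voxel pitch, identical along x, y and z, in micrometers.
    medium_ri : float
        RI of the surrounding medium.
    """

    values: np.ndarray
    voxel_pitch_um: float
    medium_ri: float = MEDIUM_RI

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("tomogram values must be a 3D array")
        if min(self.values.shape) < 2:
            raise ValueError("tomogram grid must be >= 2 voxels per axis")
        if self.voxel_pitch_um <= 0:
            raise ValueError("voxel_pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis`` in micrometers, centered."""
        n = self.values.shape[axis]
        return (np.arange(n) - n // 2) * self.voxel_pitch_um

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )


@dataclass
class SegmentationMasks:
    """Boolean body / nucleus / cytoplasm volumes on a shared grid.

    Invariants (enforced by :func:`holotomo.segment.derive_cytoplasm`):
    ``nucleus <= body`` and ``cytoplasm == body & ~nucleus``.
    """

    body: np.ndarray
    nucleus: np.ndarray
    cytoplasm: np.ndarray

    def __post_init__(self) -> None:
        if not (self.body.shape == self.nucleus.shape == self.cytoplasm.shape):
            raise ValueError("masks must share one grid")


# ---------------------------------------------------------------------------
# Centered FFT helpers.  All spectra in this package live on fftshift-centered
# grids with angular frequency axes 2*pi*fftfreq(n, pitch).

def fft2c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a)))


def ifft2c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a)))


def fftnc(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))


def ifftnc(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a)))


def k_axis(n: int, pitch_um: float) -> np.ndarray:
    """Centered angular-frequency axis (rad/um) for an n-point grid."""
    return 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(n, pitch_um))
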