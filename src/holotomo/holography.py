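"""Off-axis hologram processing: sideband demodulation, background
normalization and 2D phase unwrapping.

``demodulate`` isolates the +1 diffraction order around the carrier with a
raised-cosine circular window and re-centers it, returning the complex object
field with wrapped phase.  ``normalize_background`` divides by a sample-free
acquisition to cancel common-mode tilt and aberration.  ``unwrap_phase`` is a
reliability-sorting 2D unwrapper (congruent to its input modulo 2 pi at every
pixel).
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_2d

from .core import fft2c, ifft2c, k_axis
from .forward import ComplexField2D, Hologram

log = logging.getLogger(__name__)


class DemodulationError(ValueError):
    """No usable sideband at (or near) the expected carrier."""


def _carrier_index(holo: Hologram) -> tuple[int, int]:
    """Grid index offset of the carrier from the spectrum center."""
    n = holo.intensity.shape
    p = holo.pixel_pitch_um
    fc = holo.carrier_frequency_cyc_per_um
    return tuple(int(round(f * ni * p)) for f, ni in zip(fc, n))


def detect_carrier(holo: Hologram) -> tuple[int, int]:
    """Locate the sideband peak (grid index offsets from the center).

    The DC region (one eighth of Nyquist) is excluded; of the two conjugate
    sidebands the one with positive summed index is returned.

    Raises
    ------
    DemodulationError
        If no peak stands out of the spectrum floor.
    """
    spec = np.abs(fft2c(holo.intensity))
    nx, ny = spec.shape
    ix, iy = np.meshgrid(np.arange(nx) - nx // 2, np.arange(ny) - ny // 2,
                         indexing="ij")
    rr = np.hypot(ix / nx, iy / ny)  # cycles per pixel
    search = (rr > 1 / 16) & ((ix + iy) > 0)
    if not search.any():
        raise DemodulationError("hologram too small to search for a sideband")
    vals = np.where(search, spec, 0.0)
    peak = np.unravel_index(np.argmax(vals), spec.shape)
    floor = np.median(spec[search])
    if vals[peak] < 10 * max(floor, 1e-300):
        raise DemodulationError("no detectable sideband peak")
    return int(peak[0] - nx // 2), int(peak[1] - ny // 2)


def _window(shape, pitch, kc_idx):
    """Raised-cosine circular window centered on the carrier.

    Radius = min(0.6 x carrier distance to DC, carrier distance to the
    Nyquist edge), flat to 85% of the radius with a cosine taper outside.
    With the default carrier this passes the whole detection-NA band; the
    0.6 factor keeps the window clear of the weak-object autocorrelation
    content around DC.
    """
    kx = k_axis(shape[0], pitch)
    ky = k_axis(shape[1], pitch)
    dkx, dky = kx[1] - kx[0], ky[1] - ky[0]
    kcx, kcy = kc_idx[0] * dkx, kc_idx[1] * dky
    knyq = np.pi / pitch
    r_dc = np.hypot(kcx, kcy)
    r_ny = min(knyq - abs(kcx), knyq - abs(kcy))
    rw = min(0.6 * r_dc, r_ny)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    kr = np.hypot(KX - kcx, KY - kcy)
    t = np.clip((kr - 0.85 * rw) / (0.15 * rw), 0.0, 1.0)
    return np.where(kr <= rw, 0.5 * (1 + np.cos(np.pi * t)), 0.0), rw, (dkx, dky)


def demodulate(holo: Hologram, use_stored_carrier: bool = True,
               ) -> ComplexField2D:
    """Recover the complex object field from an off-axis hologram.

    The +1 order is windowed around the carrier, re-centered by an integer
    spectral shift, and inverse transformed.  The returned phase is wrapped
    to (-pi, pi]; residual sub-pixel carrier and tilt are expected to cancel
    in :func:`normalize_background`.

    Raises
    ------
    DemodulationError
        If no sideband is detectable, or the stored carrier disagrees with
        the detected peak by more than the window radius.
    """
    detected = detect_carrier(holo)
    kc_idx = detected
    win, rw, (dkx, dky) = _window(holo.intensity.shape,
                                  holo.pixel_pitch_um, kc_idx)
    if use_stored_carrier and holo.carrier_frequency_cyc_per_um is not None:
        stored = _carrier_index(holo)
        off = np.hypot((stored[0] - detected[0]) * dkx,
                       (stored[1] - detected[1]) * dky)
        if off > rw:
            raise DemodulationError(
                f"stored carrier {stored} is {off:.2f} rad/um away from the "
                f"detected sideband {detected} (window radius {rw:.2f})")
        kc_idx = stored
        win, rw, _ = _window(holo.intensity.shape, holo.pixel_pitch_um, kc_idx)
    spec = fft2c(holo.intensity) * win
    spec = np.roll(spec, (-kc_idx[0], -kc_idx[1]), axis=(0, 1))
    u = ifft2c(spec)
    return ComplexField2D(amplitude=np.abs(u), phase=np.angle(u),
                          angle_deg=holo.angle_deg,
                          pixel_pitch_um=holo.pixel_pitch_um)


def unwrap_phase(wrapped: np.ndarray, border: int = 8) -> np.ndarray:
    """2D phase unwrapping, congruent to the input modulo 2 pi everywhere.

    Uses reliability-sorting unwrapping, then removes the whole multiple of
    2 pi that brings the median border phase closest to zero (only 2 pi
    multiples are removed, preserving exact congruence).
    """
    wrapped = np.asarray(wrapped, dtype=np.float64)
    out = np.asarray(_unwrap_2d(wrapped))
    b = min(border, min(wrapped.shape) // 4)
    edge = np.ones(wrapped.shape, dtype=bool)
    if b > 0:
        edge[b:-b, b:-b] = False
    offset = 2 * np.pi * np.round(np.median(out[edge]) / (2 * np.pi))
    return out - offset


def normalize_background(field: ComplexField2D,
                         reference_field: ComplexField2D,
                         amplitude_floor: float = 1e-6) -> ComplexField2D:
    """Flat-field the object acquisition by a sample-free acquisition.

    Returns the amplitude ratio and the wrapped phase difference; tilt or
    aberration common to both arms cancels in the quotient.  Reference
    pixels with near-zero amplitude are masked (ratio 1) and counted in the
    log.
    """
    if field.amplitude.shape != reference_field.amplitude.shape:
        raise ValueError("field and reference grids differ")
    aref = reference_field.amplitude
    bad = aref < amplitude_floor
    if bad.any():
        log.warning("normalize_background: %d zero-amplitude reference "
                    "pixels masked", int(bad.sum()))
    amp = np.where(bad, 1.0, field.amplitude / np.where(bad, 1.0, aref))
    dphi = field.phase - reference_field.phase
    dphi = np.angle(np.exp(1j * dphi))
    return ComplexField2D(amplitude=amp, phase=dphi,
                          angle_deg=field.angle_deg,
                          pixel_pitch_um=field.pixel_pitch_um)


def process_hologram(holo: Hologram, reference: Hologram) -> ComplexField2D:
    """Demodulate, flat-field and unwrap one hologram.

    Convenience chain used by the pipeline: the sample and reference
    holograms are demodulated identically, divided, and the phase difference
    is unwrapped.  The result matches the convention of
    :func:`holotomo.forward.propagate_field` (amplitude 1 / phase 0 where
    there is no sample).
    """
    f = demodulate(holo)
    r = demodulate(reference)
    norm = normalize_background(f, r)
    return ComplexField2D(amplitude=norm.amplitude,
                          phase=unwrap_phase(norm.phase),
                          angle_deg=norm.angle_deg,
                          pixel_pitch_um=norm.pixel_pitch_um)
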