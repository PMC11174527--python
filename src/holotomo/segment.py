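"""RI-threshold 3D segmentation of cell body, nucleus and cytoplasm.

The cell body is everything at or above an RI threshold (1.34 against the
PBS background of 1.334), cleaned by morphological opening/closing and a
connected-component policy.  The nucleus is found from a seed point in the
z = 0 section: the bright region around the seed is contoured by its 3D
gradient-magnitude edges and a 3D ellipsoid is least-squares fitted to the
edge point cloud.  The cytoplasm is the exact set difference body minus
nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import RITomogram, SegmentationMasks

log = logging.getLogger(__name__)

#: 26-connectivity structuring element for component labelling.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SeedError(ValueError):
    """Nucleus seed lies outside the body mask."""


class EllipsoidFitError(RuntimeError):
    """The edge point cloud does not constrain an ellipsoid."""


@dataclass
class SegmentationConfig:
    """Parameters of the threshold segmentation.

    ``body_ri_threshold`` defaults to 1.34 (background PBS is 1.334).
    ``component_policy`` selects which thresholded components form the body:
    the largest one (default), all of them, or the one containing
    ``nucleus_seed_xy``.
    """

    body_ri_threshold: float = 1.34
    erosion_radius_vox: int = 1
    dilation_radius_vox: int = 1
    component_policy: str = "largest"
    nucleus_seed_xy: tuple[float, float] | None = None
    smoothing_sigma_um: float = 0.4

    def __post_init__(self) -> None:
        if self.component_policy not in ("largest", "all", "seeded"):
            raise ValueError(f"unknown policy {self.component_policy!r}")


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    z = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(z, z, z, indexing="ij")
    return X**2 + Y**2 + Z**2 <= r**2


def segment_body(tomo: RITomogram, config: SegmentationConfig | None = None,
                 ) -> np.ndarray:
    """Threshold + morphology + component-policy body mask.

    Returns an all-False mask (with a warning) when nothing survives; this
    is a signal, not an error.
    """
    config = config or SegmentationConfig()
    if config.body_ri_threshold <= tomo.medium_ri:
        raise ValueError("body threshold must exceed the medium RI")
    mask = np.asarray(tomo.values) >= config.body_ri_threshold
    if config.erosion_radius_vox > 0:
        mask = ndi.binary_opening(mask, _ball(config.erosion_radius_vox))
    if config.dilation_radius_vox > 0:
        mask = ndi.binary_closing(mask, _ball(config.dilation_radius_vox))
    if not mask.any():
        log.warning("segment_body: empty mask after morphology")
        return mask
    if config.component_policy == "all":
        return mask
    labels, n = ndi.label(mask, structure=_CONN26)
    if config.component_policy == "seeded" and config.nucleus_seed_xy is not None:
        idx = _seed_index(tomo, config.nucleus_seed_xy)
        sec = labels[idx[0], idx[1], :]
        hit = sec[sec > 0]
        if hit.size == 0:
            log.warning("segment_body: seed column hits no component; "
                        "falling back to largest")
        else:
            return labels == hit[0]
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _seed_index(tomo: RITomogram, seed_xy_um) -> tuple[int, int]:
    nx, ny = tomo.shape[0], tomo.shape[1]
    p = tomo.voxel_pitch_um
    i = int(round(seed_xy_um[0] / p)) + nx // 2
    j = int(round(seed_xy_um[1] / p)) + ny // 2
    if not (0 <= i < nx and 0 <= j < ny):
        raise SeedError(f"seed {seed_xy_um} um outside the grid")
    return i, j


def z0_section_index(body: np.ndarray) -> int:
    """z-slice with the largest body cross-section (the working z = 0)."""
    areas = body.sum(axis=(0, 1))
    return int(np.argmax(areas))


def auto_nucleus_seed(tomo: RITomogram, body: np.ndarray,
                      sigma_um: float = 0.8) -> tuple[float, float]:
    """Automatic nucleus seed: centroid of the dominant high-RI blob in the
    z = 0 section.

    The section is smoothed with a Gaussian wide enough to suppress
    sub-micrometer particles, thresholded at its upper decile inside the
    body, and the connected region with the largest integrated elevation
    above the cytoplasm level wins.
    """
    z0 = z0_section_index(body)
    sec = np.asarray(tomo.values[:, :, z0], dtype=np.float64)
    bmask = body[:, :, z0]
    if not bmask.any():
        raise SeedError("empty body section")
    sig = sigma_um / tomo.voxel_pitch_um
    smooth = ndi.gaussian_filter(sec, sig)
    inside = smooth[bmask]
    thr = np.percentile(inside, 90)
    cand = (smooth >= thr) & bmask
    labels, n = ndi.label(cand)
    if n == 0:
        com = ndi.center_of_mass(bmask)
        return _index_to_um(tomo, com)
    level = np.median(inside)
    best, best_mass = 1, -np.inf
    for lab in range(1, n + 1):
        m = labels == lab
        mass = float(np.sum(smooth[m] - level))
        if mass > best_mass:
            best, best_mass = lab, mass
    com = ndi.center_of_mass(labels == best)
    log.info("auto_nucleus_seed: blob %d of %d at %s", best, n, com)
    return _index_to_um(tomo, com)


def _index_to_um(tomo, ij) -> tuple[float, float]:
    p = tomo.voxel_pitch_um
    return ((ij[0] - tomo.shape[0] // 2) * p, (ij[1] - tomo.shape[1] // 2) * p)


def _fit_ellipsoid(points_um: np.ndarray) -> np.ndarray:
    """Algebraic least-squares quadric fit; returns the 9 coefficients of
    A x^2 + B y^2 + C z^2 + D xy + E xz + F yz + G x + H y + I z = 1.

    Raises :class:`EllipsoidFitError` when the cloud is degenerate or the
    fitted quadric is not an ellipsoid.
    """
    if points_um.shape[0] < 9:
        raise EllipsoidFitError(
            f"only {points_um.shape[0]} edge points (need >= 9)")
    x, y, z = points_um.T
    M = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    coef, *_ = np.linalg.lstsq(M, np.ones(len(x)), rcond=None)
    A = np.array([[coef[0], coef[3] / 2, coef[4] / 2],
                  [coef[3] / 2, coef[1], coef[5] / 2],
                  [coef[4] / 2, coef[5] / 2, coef[2]]])
    if np.any(np.linalg.eigvalsh(A) <= 0):
        raise EllipsoidFitError("fitted quadric is not an ellipsoid")
    return coef


def ellipsoid_mask_from_coeffs(coef: np.ndarray, tomo: RITomogram,
                               ) -> np.ndarray:
    X, Y, Z = tomo.meshgrid()
    q = (coef[0] * X * X + coef[1] * Y * Y + coef[2] * Z * Z
         + coef[3] * X * Y + coef[4] * X * Z + coef[5] * Y * Z
         + coef[6] * X + coef[7] * Y + coef[8] * Z)
    return q <= 1.0


def segment_nucleus(tomo: RITomogram, body: np.ndarray,
                    config: SegmentationConfig | None = None) -> np.ndarray:
    """Seeded nucleus mask via 3D edge contouring + ellipsoid fitting.

    From the seed (given in the config, or automatic) the bright region
    around it is grown at a threshold halfway between the seed RI and the
    body median; the region's boundary voxels with above-median gradient
    magnitude form the edge cloud to which the ellipsoid is fitted.  The
    fitted ellipsoid is clipped to the body.
    """
    config = config or SegmentationConfig()
    if not body.any():
        raise ValueError("body mask is empty")
    seed_xy = config.nucleus_seed_xy
    if seed_xy is None:
        seed_xy = auto_nucleus_seed(tomo, body)
    i, j = _seed_index(tomo, seed_xy)
    z0 = z0_section_index(body)
    if not body[i, j, z0]:
        raise SeedError(f"seed {seed_xy} um outside the body at z = 0")

    vals = np.asarray(tomo.values, dtype=np.float64)
    sig = config.smoothing_sigma_um / tomo.voxel_pitch_um
    smooth = ndi.gaussian_filter(vals, sig)
    # Otsu inside the body separates the nucleus mode from the cytoplasm
    # bulk and is robust to the small bright nucleolus at the seed.
    from skimage.filters import threshold_otsu
    level = np.median(smooth[body])
    try:
        thr = float(threshold_otsu(smooth[body]))
    except ValueError:
        thr = 0.5 * (smooth[i, j, z0] + level)
    if smooth[i, j, z0] < thr:  # seed darker than the Otsu split
        thr = 0.5 * (smooth[i, j, z0] + level)
    cand = (smooth >= thr) & body
    labels, _ = ndi.label(cand, structure=_CONN26)
    lab = labels[i, j, z0]
    if lab == 0:
        raise EllipsoidFitError("no bright region at the seed")
    region = labels == lab

    shell = region & ~ndi.binary_erosion(region, _ball(1))
    gx, gy, gz = np.gradient(smooth, tomo.voxel_pitch_um)
    gmag = np.sqrt(gx**2 + gy**2 + gz**2)
    gthr = np.median(gmag[shell])
    edge = shell & (gmag >= gthr)
    if edge.sum() < 9:
        edge = shell  # fall back to the full contour
    idx = np.argwhere(edge)
    pts = (idx - np.array([s // 2 for s in tomo.shape])) * tomo.voxel_pitch_um
    coef = _fit_ellipsoid(pts)
    nucleus = ellipsoid_mask_from_coeffs(coef, tomo) & body
    return nucleus


def derive_cytoplasm(body: np.ndarray, nucleus: np.ndarray) -> np.ndarray:
    """Exact set difference body minus nucleus; requires nucleus <= body."""
    if np.any(nucleus & ~body):
        raise ValueError("nucleus mask is not contained in the body mask")
    return body & ~nucleus


def segment_cell(tomo: RITomogram, config: SegmentationConfig | None = None,
                 ) -> SegmentationMasks:
    """Full segmentation: body, nucleus (best effort), cytoplasm."""
    config = config or SegmentationConfig()
    body = segment_body(tomo, config)
    if not body.any():
        empty = np.zeros_like(body)
        return SegmentationMasks(body=body, nucleus=empty, cytoplasm=empty)
    try:
        nucleus = segment_nucleus(tomo, body, config)
    except (SeedError, EllipsoidFitError) as exc:
        log.warning("segment_cell: nucleus segmentation failed (%s); "
                    "returning an empty nucleus", exc)
        nucleus = np.zeros_like(body)
    return SegmentationMasks(body=body, nucleus=nucleus,
                             cytoplasm=derive_cytoplasm(body, nucleus))
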