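"""Morphometric quantification: the 16 physical parameters and RI histograms.

Per cell, four quantities are computed for each of the three compartments
(body, nucleus, cytoplasm):

* section area — in-mask pixel count at the z = 0 plane times pitch^2,
* height — axial extent (max - min occupied slice + 1) times pitch,
* volume — voxel count times pitch^3,
* average RI — arithmetic mean of the tomogram over the mask,

plus the four nucleo-cytoplasmic ratios (NCR = nucleus value / cytoplasm
value) of those quantities: 16 parameters in total.

The working z = 0 plane defaults to the slice with the largest body
cross-section (cell-relative); a fixed instrument plane can be requested
instead.  RI histograms of the z = 0 section are fitted with a sum of
Gaussians, which is how the high-RI autophagy-specific mode (RI > 1.42)
is made visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import RITomogram, SegmentationMasks
from .segment import z0_section_index

log = logging.getLogger(__name__)

COMPARTMENTS = ("body", "nucleus", "cytoplasm")
QUANTITIES = ("section_area_um2", "height_um", "volume_um3", "mean_ri")
NCR_NAMES = ("ncr_section_area", "ncr_height", "ncr_volume", "ncr_mean_ri")

#: Column order of the 16 physical parameters in cohort tables.
PARAMETER_NAMES = tuple(f"{q}_{c}" for c in COMPARTMENTS
                        for q in QUANTITIES) + NCR_NAMES


@dataclass
class MorphologyRecord:
    """The 16 physical parameters of one cell."""

    parameters: dict[str, float]
    cell_id: str = ""
    state: str = ""
    z0_index: int = 0
    ncr_defined: bool = True

    def __post_init__(self) -> None:
        missing = set(PARAMETER_NAMES) - set(self.parameters)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        extra = set(self.parameters) - set(PARAMETER_NAMES)
        if extra:
            raise ValueError(f"unexpected parameters: {sorted(extra)}")

    def to_row(self) -> dict:
        row = {"cell_id": self.cell_id, "state": self.state}
        row.update({k: self.parameters[k] for k in PARAMETER_NAMES})
        return row


def _compartment_metrics(tomo: RITomogram, mask: np.ndarray,
                         z0: int) -> dict[str, float]:
    p = tomo.voxel_pitch_um
    count = int(mask.sum())
    if count == 0:
        return {"section_area_um2": 0.0, "height_um": 0.0,
                "volume_um3": 0.0, "mean_ri": float("nan")}
    zs = np.flatnonzero(mask.any(axis=(0, 1)))
    return {
        "section_area_um2": float(mask[:, :, z0].sum()) * p**2,
        "height_um": float(zs[-1] - zs[0] + 1) * p,
        "volume_um3": count * p**3,
        "mean_ri": float(np.asarray(tomo.values)[mask].mean()),
    }


def compute_morphology(tomo: RITomogram, masks: SegmentationMasks,
                       z0_policy: str = "max_area",
                       z0_index: int | None = None,
                       cell_id: str = "", state: str = "",
                       ) -> MorphologyRecord:
    """Compute the 16-parameter record for one segmented cell.

    ``z0_policy`` is ``"max_area"`` (slice of largest body section, default)
    or ``"fixed"`` (use ``z0_index``).  An empty cytoplasm leaves the NCRs
    undefined (NaN, flagged); an empty nucleus yields NCRs of 0 with a
    warning.
    """
    if not masks.body.any():
        raise ValueError("empty body mask")
    if z0_policy == "max_area":
        z0 = z0_section_index(masks.body)
    elif z0_policy == "fixed":
        if z0_index is None:
            z0 = tomo.shape[2] // 2
        else:
            z0 = int(z0_index)
    else:
        raise ValueError(f"unknown z0 policy {z0_policy!r}")

    params: dict[str, float] = {}
    per = {}
    for name in COMPARTMENTS:
        m = getattr(masks, name)
        per[name] = _compartment_metrics(tomo, m, z0)
        for q in QUANTITIES:
            params[f"{q}_{name}"] = per[name][q]

    ncr_defined = True
    if not masks.cytoplasm.any():
        log.warning("compute_morphology: empty cytoplasm, NCRs undefined")
        ncr_defined = False
        for name in NCR_NAMES:
            params[name] = float("nan")
    elif not masks.nucleus.any():
        log.warning("compute_morphology: empty nucleus, NCRs set to 0")
        for name in NCR_NAMES:
            params[name] = 0.0
    else:
        for name, q in zip(NCR_NAMES, QUANTITIES):
            denom = per["cytoplasm"][q]
            if denom == 0 or not np.isfinite(denom):
                log.warning("compute_morphology: cytoplasm %s is zero, "
                            "%s undefined", q, name)
                params[name] = float("nan")
            else:
                params[name] = per["nucleus"][q] / denom

    return MorphologyRecord(parameters=params, cell_id=cell_id, state=state,
                            z0_index=z0, ncr_defined=ncr_defined)


# ---------------------------------------------------------------------------
# RI histogram fitting (sum of Gaussians on the z = 0 section)

#: Histogram bin width in RI units, matching the instrument-level RI accuracy.
HIST_BIN_WIDTH = 0.002
HIST_RI_MAX = 1.45


@dataclass
class RIHistogramFit:
    """Section RI histogram with a sum-of-Gaussians decomposition.

    ``components`` are (weight, center_ri, width_ri) tuples sorted by center.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[tuple[float, float, float]] = field(default_factory=list)
    fit_residual: float = float("nan")
    success: bool = False


def _gauss_sum(x, *p):
    y = np.zeros_like(x)
    for i in range(0, len(p), 3):
        a, c, w = p[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - c) / max(w, 1e-6)) ** 2)
    return y


def fit_histogram_counts(bin_edges: np.ndarray, counts: np.ndarray,
                         n_components: int = 3) -> RIHistogramFit:
    """Poisson-weighted sum-of-Gaussians fit of a pre-binned histogram.

    The fit minimizes chi-square with sigma = sqrt(counts + 1), so sparse
    tail populations carry their statistical weight.  Initial centers: the
    global mode, then the highest and lowest occupied bins, then secondary
    peaks — a small high-RI population therefore always seeds a component.
    Non-convergence returns the raw histogram flagged as failed.
    """
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    counts = np.asarray(counts, dtype=float)
    occupied = np.flatnonzero(counts >= 1.0)
    if occupied.size == 0:
        return RIHistogramFit(bin_edges=bin_edges, counts=counts)
    bw = bin_edges[1] - bin_edges[0]
    from scipy.signal import find_peaks
    # component roles: bulk mode(s), the high-RI tail, the low edge —
    # seed one component at the global peak and one at the highest
    # occupied bin so a sparse high-RI population is never dropped
    inits = [centers[int(np.argmax(counts))]]
    for extra in (centers[occupied[-1]], centers[occupied[0]]):
        if len(inits) < n_components and \
                all(abs(extra - c) > bw / 2 for c in inits):
            inits.append(extra)
    pk, _props = find_peaks(counts, prominence=0.02 * counts.max())
    for i in sorted(pk, key=lambda i: -counts[i]):
        if len(inits) >= n_components:
            break
        if all(abs(centers[i] - c) > bw for c in inits):
            inits.append(centers[i])
    while len(inits) < n_components:
        inits.append(centers[occupied[len(inits) % occupied.size]])
    p0 = []
    for c in inits[:n_components]:
        idx = int(np.clip(np.searchsorted(centers, c), 0, len(centers) - 1))
        p0.extend([max(counts[idx], 1.0), c, 2 * bw])
    lo = [0.0, bin_edges[0], bw / 2] * n_components
    hi = [counts.max() * 2 + 1, bin_edges[-1], bin_edges[-1] - bin_edges[0]] \
        * n_components
    try:
        # Poisson weighting: chi-square with sigma = sqrt(counts + 1)
        popt, _ = curve_fit(_gauss_sum, centers, counts, p0=p0,
                            sigma=np.sqrt(counts + 1.0),
                            bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        log.warning("fit_histogram_counts: fit failed (%s)", exc)
        return RIHistogramFit(bin_edges=bin_edges, counts=counts)
    comps = sorted(
        [(float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
         for i in range(0, len(popt), 3)], key=lambda c: c[1])
    resid = float(np.sqrt(np.mean((_gauss_sum(centers, *popt) - counts) ** 2)))
    return RIHistogramFit(bin_edges=bin_edges, counts=counts,
                          components=comps, fit_residual=resid, success=True)


def section_histogram(tomo: RITomogram, mask: np.ndarray, z0_index: int,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of in-mask RI values of one section (fixed 0.002 bins)."""
    sec = np.asarray(tomo.values[:, :, z0_index])
    m = mask[:, :, z0_index]
    edges = np.arange(tomo.medium_ri, HIST_RI_MAX + HIST_BIN_WIDTH,
                      HIST_BIN_WIDTH)
    counts, _ = np.histogram(sec[m], bins=edges)
    return edges, counts


def fit_ri_histogram(tomo: RITomogram, mask: np.ndarray, z0_index: int,
                     n_components: int = 3) -> RIHistogramFit:
    """Sum-of-Gaussians fit of the z = 0 section RI histogram.

    Requires at least 50 in-mask section pixels.
    """
    m = mask[:, :, z0_index]
    if int(m.sum()) < 50:
        raise ValueError(
            f"section has only {int(m.sum())} in-mask pixels (need >= 50)")
    edges, counts = section_histogram(tomo, mask, z0_index)
    return fit_histogram_counts(edges, counts, n_components)
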