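"""Morphometrics: the 16-parameter record and RI-histogram fitting."""

import numpy as np
import pytest

from conftest import make_bead
from holotomo.core import MEDIUM_RI, RITomogram, SegmentationMasks
from holotomo.morphometry import (PARAMETER_NAMES, MorphologyRecord,
                                  compute_morphology, fit_histogram_counts,
                                  fit_ri_histogram)


def _sphere_masks(radius_um, n, pitch, ri=1.36):
    tomo = make_bead(radius_um, ri, n, pitch)
    body = tomo.values > MEDIUM_RI
    empty = np.zeros_like(body)
    return tomo, SegmentationMasks(body=body, nucleus=empty,
                                   cytoplasm=body.copy())


def test_record_has_exactly_16_parameters():
    tomo, masks = _sphere_masks(2.0, 64, 0.1)
    rec = compute_morphology(tomo, masks)
    assert len(rec.parameters) == 16
    assert set(rec.parameters) == set(PARAMETER_NAMES)
    with pytest.raises(ValueError):
        MorphologyRecord(parameters={k: 0.0 for k in PARAMETER_NAMES[:-1]})


def test_sphere_oracles():
    """Volume 523.6 um^3, height 10 um, equatorial section 78.54 um^2."""
    tomo, masks = _sphere_masks(5.0, 112, 0.1)
    rec = compute_morphology(tomo, masks)
    assert rec.parameters["volume_um3_body"] == pytest.approx(523.6, rel=0.03)
    assert rec.parameters["height_um_body"] == pytest.approx(10.0, abs=0.101)
    assert rec.parameters["section_area_um2_body"] == pytest.approx(
        78.54, rel=0.03)
    assert rec.parameters["mean_ri_body"] == pytest.approx(1.36, abs=1e-6)


def test_symmetric_compartments_give_unit_mean_ri_ncr():
    vals = np.full((32, 32, 32), 1.36, dtype=np.float32)
    tomo = RITomogram(vals, 0.2)
    body = np.zeros((32, 32, 32), dtype=bool)
    body[8:24, 8:24, 8:24] = True
    nucleus = body.copy()
    nucleus[:, 16:, :] = False   # left half
    cytoplasm = body & ~nucleus  # mirrored right half
    masks = SegmentationMasks(body=body, nucleus=nucleus, cytoplasm=cytoplasm)
    rec = compute_morphology(tomo, masks)
    assert rec.parameters["ncr_mean_ri"] == 1.0
    assert rec.parameters["ncr_volume"] == 1.0


def test_volume_partition_within_one_voxel():
    tomo, masks = _sphere_masks(3.0, 80, 0.1)
    half = masks.body.copy()
    half[:, :, :40] = False
    masks = SegmentationMasks(body=masks.body, nucleus=half,
                              cytoplasm=masks.body & ~half)
    rec = compute_morphology(tomo, masks)
    p = rec.parameters
    assert abs(p["volume_um3_body"]
               - p["volume_um3_nucleus"] - p["volume_um3_cytoplasm"]) \
        <= 0.1**3 + 1e-9


def test_empty_nucleus_flags():
    tomo, masks = _sphere_masks(2.0, 64, 0.1)
    rec = compute_morphology(tomo, masks)
    assert all(rec.parameters[k] == 0.0 for k in
               ("ncr_volume", "ncr_mean_ri", "ncr_height",
                "ncr_section_area"))


def test_empty_cytoplasm_flags_nan():
    tomo, masks = _sphere_masks(2.0, 64, 0.1)
    m = SegmentationMasks(body=masks.body, nucleus=masks.body,
                          cytoplasm=np.zeros_like(masks.body))
    rec = compute_morphology(tomo, m)
    assert not rec.ncr_defined
    assert np.isnan(rec.parameters["ncr_volume"])


def test_voxel_pitch_equivariance():
    """Halving the pitch changes the volume estimate by < 3%."""
    vols = []
    for n, pitch in ((64, 0.2), (128, 0.1)):
        tomo, masks = _sphere_masks(4.0, n, pitch)
        rec = compute_morphology(tomo, masks)
        vols.append(rec.parameters["volume_um3_body"])
    assert abs(vols[1] - vols[0]) / vols[0] < 0.03


class TestHistogram:
    def test_single_ri_section_gives_one_bin_component(self):
        tomo, masks = _sphere_masks(2.0, 64, 0.2, ri=1.36)
        z0 = 32
        fit = fit_ri_histogram(tomo, masks.body, z0, n_components=1)
        assert fit.success
        w, c, s = fit.components[0]
        assert c == pytest.approx(1.36, abs=0.002)
        assert s <= 0.004  # bin-limited width

    def test_two_population_mixture_recovered(self):
        edges = np.arange(1.334, 1.452, 0.002)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = (1000 * np.exp(-0.5 * ((centers - 1.35) / 0.003) ** 2)
                  + 1000 * np.exp(-0.5 * ((centers - 1.40) / 0.003) ** 2))
        fit = fit_histogram_counts(edges, counts, n_components=2)
        assert fit.success
        got = sorted(c for _w, c, _s in fit.components)
        assert got[0] == pytest.approx(1.35, abs=0.002)
        assert got[1] == pytest.approx(1.40, abs=0.002)

    def test_autophagy_like_section_finds_high_ri_component(self):
        """A section with sparse 1.425-RI particles keeps a fitted mode
        above 1.42."""
        n = 128
        vals = np.full((n, n, 3), MEDIUM_RI, dtype=np.float32)
        x = (np.arange(n) - n // 2) * 0.1
        X, Y = np.meshgrid(x, x, indexing="ij")
        disk = X**2 + Y**2 <= 5.0**2
        vals[:, :, 1][disk] = 1.355
        for cx, cy in ((2.0, 1.0), (-2.5, 0.5), (0.5, -3.0)):
            p = (X - cx) ** 2 + (Y - cy) ** 2 <= 0.45**2
            vals[:, :, 1][p] = 1.425
        tomo = RITomogram(vals, 0.1)
        mask = np.broadcast_to(disk[:, :, None], vals.shape)
        fit = fit_ri_histogram(tomo, mask, 1, n_components=3)
        assert fit.success
        assert fit.components[-1][1] > 1.42
        # counts bookkeeping: histogram covers every in-mask pixel
        assert fit.counts.sum() == disk.sum()

    def test_small_section_rejected(self):
        tomo, masks = _sphere_masks(2.0, 64, 0.2)
        with pytest.raises(ValueError):
            fit_ri_histogram(tomo, masks.body, 2)
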