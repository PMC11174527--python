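# holotomo

Label-free characterization of cell-death morphology with simulated
holographic tomography (HT / optical diffraction tomography).

Cells dying by different programmed pathways look different in 3D
refractive index (RI): autophagic cells shrink and accumulate small
high-RI (> 1.42) particles of 0.8–1 µm; apoptotic cells fragment and
condense their nucleus into a dense (RI > 1.41) sphere of about 7 µm;
ferroptotic cells stay near-normal in shape but show a slightly elevated
nucleus-to-cytoplasm mean-RI ratio. `holotomo` implements the full
measurement-and-analysis chain needed to quantify those signatures, with a
synthetic-data generator standing in for the microscope:

1. **Phantoms** — analytic 3D RI models of normal, autophagic, apoptotic
   and ferroptotic cells in PBS (n_m = 1.334), with seeded cohort jitter.
2. **Forward optics** — first-Rytov scattering through the Fourier
   diffraction theorem for a −45°…45° illumination scan (241 angles,
   λ = 632.8 nm, detection NA 1.2) and off-axis hologram formation.
3. **Phase retrieval** — sideband demodulation, flat-fielding against a
   sample-free acquisition, reliability-sorted 2D phase unwrapping.
4. **Tomography** — direct inversion: each angle's Rytov spectrum is
   placed on its Ewald cap, F(k_s − k_in) = −2i k_z U_s(k⊥), accumulated
   with weights and inverse-transformed to n(r); optional
   Gerchberg–Papoulis positivity iterations against the ±45° missing cone.
5. **Segmentation** — RI threshold 1.34 for the cell body, seeded 3D
   edge-cloud ellipsoid fit for the nucleus, cytoplasm by exact set
   difference.
6. **Morphometrics** — 16 physical parameters per cell: {section area at
   z = 0, height, volume, mean RI} × {body, nucleus, cytoplasm} plus the
   four nucleo-cytoplasmic ratios (NCR = nucleus/cytoplasm), and
   sum-of-Gaussians fits of section RI histograms.
7. **Statistics** — pairwise Mann–Whitney U tests across states with the
   standard star labels (n.s. / * / ** / *** / ****) and box-plot reports.

Externally measured RI tomograms (32-bit TIFF stacks or HDF5 volumes with
`voxel_pitch_um` and `medium_ri` metadata) can enter the pipeline directly
at stage 5.

## Worked example

Simulate one autophagic cell, reconstruct it, and quantify it:

```bash
holotomo simulate --state autophagy --scale 0.45 --grid 128 \
    --angles 61 --noise 0.01 --seed 7 --out auto_holo.h5
holotomo reconstruct auto_holo.h5 --positivity 20 --out auto_ri.tif
holotomo quantify auto_ri.tif
```

The `quantify` step prints the 16-parameter record, e.g. (values from this
exact command sequence):

```json
{
  "height_um_body": 5.7,
  "mean_ri_body": 1.3486932516098022,
  "mean_ri_cytoplasm": 1.345397710800171,
  "mean_ri_nucleus": 1.3523439168930054,
  "ncr_mean_ri": 1.0051629388373964,
  "ncr_volume": 0.9027248985242755,
  "section_area_um2_body": 38.16,
  "volume_um3_body": 120.941
}
```

(abridged). The nucleus mean RI sits above the cytoplasm's and the
mean-RI NCR is above 1, as expected for this state; the body volume
exceeds the ground truth (85.6 µm³ for this spec) because the ±45°
missing cone smears thin cells axially at the near-background 1.34
threshold — see `docs/methods.md` for the quantitative discussion.

A full synthetic study (4 states × 10 cells, reconstruction, segmentation,
cohort statistics and box plots) is one command:

```bash
holotomo run-all --seed 1 --cells 10 --out demo_run
```

which writes `cohort.csv` (one row per cell, 16 parameter columns),
`statistics.csv` (pairwise tests with star labels) and one box-plot panel
per parameter.

The same stages are available as a library:

```python
from holotomo import (PhantomSpec, generate_phantom, make_schedule,
                      segment_cell, compute_morphology)
from holotomo.pipeline import simulate_cell, reconstruct_cell

spec = PhantomSpec.for_state("apoptosis", rng_seed=0)
tomo = generate_phantom(spec, (128, 128, 128), 0.1)   # ground truth
holos = simulate_cell(tomo, make_schedule(61), noise_level=0.01)
recon = reconstruct_cell(holos, make_schedule(61), 128)
record = compute_morphology(recon, segment_cell(recon))
```

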