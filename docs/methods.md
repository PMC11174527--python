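# Methods

`holotomo` simulates and analyzes holographic-tomography (HT, also called
optical diffraction tomography) measurements of single cells in four states
— normal, autophagic, apoptotic and ferroptotic — and quantifies the
morphological signatures that separate them. This note records the models,
the numerical choices and their rationale, and what the synthetic data do
and do not establish.

## Imaging model

The acquisition emulated is a Mach–Zehnder off-axis holographic tomograph:
a He–Ne object beam (λ = 632.8 nm) scans the sample over θ ∈ [−45°, 45°]
(241 angles by default), the transmitted wavefront is collected by a 1.2-NA
water-immersion objective and interfered with a reference beam. The sample
is described by its refractive index n(r) in a medium of n_m = 1.334 (PBS),
through the scattering potential

    f(r) = k0² (n(r)² − n_m²),    k0 = 2π/λ.

**Forward model.** First Rytov approximation computed through the Fourier
diffraction theorem: for illumination wavevector k_in (|k_in| = n_m k0) the
first-Born scattered field at the mid-plane of the volume is obtained by
sampling the 3D spectrum F(K) of the potential on the Ewald cap
K = (k⊥, k_z) − k_in, k_z = √(n_m²k0² − |k⊥|²), as

    U_s(k⊥) = (i / 2k_z) · F(k − k_in),

restricted to |k⊥| ≤ k0·NA_det, and the total field is u_in·exp(ψ) with the
complex Rytov phase ψ = u_s/u_in. The detection-NA pupil is applied to the
*exit field* exp(ψ) (a hard circular low-pass, as the collection objective
acts on the field, not on ψ); the phase of the filtered field is unwrapped
when it exceeds 2π. Fields are illumination-referenced: a sample-free
acquisition has amplitude 1 and phase 0.

The Rytov regime is accurate for contrasts Δn ≲ 0.03–0.05 at cell scales;
a warning (not an error) is emitted above Δn = 0.1. The condensed apoptotic
nucleus (Δn ≈ 0.08) is near the edge of the regime, which mirrors the
situation with real dense organelles.

**Holograms.** The reference arm is descanned (its tilt tracks the
illumination minus a fixed carrier), so the off-axis sideband sits at a
constant carrier for all scan angles; beam-scanning HT systems behave this
way. The recorded intensity is |o·e^{2πi f_c·r} + 1|², optionally degraded
by multiplicative Gaussian noise (default 1% in cohort simulations). The
default carrier sits at 0.54 of Nyquist per axis: for weak-phase objects the
autocorrelation term is first-order suppressed beyond the object band, so
this placement lets the demodulation window (radius min(0.6·|k_c|, distance
to the Nyquist edge), raised-cosine taper from 85% of the radius) pass the
entire detection-NA band. A carrier at 1/3 of Nyquist with a half-distance
window — a common conservative textbook choice — was measured to clip the
collected band at ~7.4 rad/µm versus the NA limit of 11.9 rad/µm and was
rejected for that reason.

**Phase retrieval.** Sideband demodulation (windowing + integer spectral
re-centering), flat-field division by an identically processed sample-free
hologram, and reliability-sorting 2D phase unwrapping
(`skimage.restoration.unwrap_phase`). Unwrapping removes only whole
multiples of 2π (chosen so the median border phase is nearest zero), which
preserves exact congruence with the wrapped input.

**Direct inversion.** Each angle's Rytov spectrum is placed on its Ewald cap
with the diffraction-theorem weight −2i·k_z and accumulated into a 3D
spectrum with *trilinear* spreading and weight averaging; the weighted
average is inverse-transformed and converted back to n(r), discarding the
imaginary residual after logging its magnitude. Nearest-voxel deposition is
available behind a flag but measured ~8× less accurate for quantitative RI
on a homogeneous bead (|ΔRI| ≈ 0.0065 versus ≈ 0.0008 at 192³), so
trilinear is the default. The reconstruction grid should pad the object to
roughly three object diameters: wrap-around of the diffracted field
otherwise biases interior RI values (128³ versus 192³ moves the bead-core
error from ≈0.003 to ≈0.0008).

**Missing cone.** A ±45° single-axis scan leaves an unsampled double cone
around the axial frequency axis. Consequences, all reproduced by the
package: reconstructed beads elongate axially (z/x extent ratio ≈ 1.26 at
the 1.34-RI level), interior RI is slightly underestimated, and thin
adherent-cell shapes smear axially by roughly the axial resolution limit
λ/(n_m(1−cos 45°)) ≈ 1.6 µm. An optional Gerchberg–Papoulis non-negativity
constraint (alternating n ≥ n_m in real space with re-imposition of the
measured caps in Fourier space) mitigates the elongation; it is off for
plain direct inversion and on (20 iterations) in the quantification
pipeline, where mask-derived sizes benefit from it. Volume estimates of
thin cells segmented at a threshold only 0.006 above background remain
inflated by several tens of percent even with the constraint — this is a
property of limited-angle direct inversion, not of the implementation, and
it bounds what threshold-based volumetry can promise on flat cells.

## Phantoms

Cells are modeled as analytic compartments voxelized onto an isotropic grid:
ellipsoidal body (cytoplasm RI), ellipsoidal nucleus, one spherical
nucleolus, plus state extras. Defaults (chosen once; semi-axes in µm):

| state       | body         | nucleus        | RIs (cyt/nuc/nucleolus) | extras |
|-------------|--------------|----------------|-------------------------|--------|
| normal      | 10 × 8 × 4   | 4.5 × 4.5 × 3.5 | 1.355 / 1.365 / 1.390  | —      |
| autophagy   | 8.9 × 7.1 × 3.55 (70% volume) | 4 × 4 × 3 | as normal | 5 particles, RI 1.425, ⌀ 0.8–1 µm |
| apoptosis   | 5.5 × 5.5 × 4.5 | 3.5 sphere (⌀ 7 µm) | 1.360 / 1.415 / — | 3 detached fragments |
| ferroptosis | as normal    | as normal      | 1.352 / 1.372 / 1.392   | —      |

The anchors with quantitative footing are the medium (1.334), the autophagy
particles (RI > 1.42, 0.8–1 µm), the condensed apoptotic nucleus (⌀ ≈ 7 µm,
RI > 1.41), the ~30% autophagic volume reduction, and the elevated
ferroptotic mean-RI NCR; absolute cytoplasm/nucleus RIs for normal cells
are configurable package defaults, not literature values. Every compartment
respects medium < cytoplasm < nucleus ≤ nucleolus.

Cohorts jitter geometry and RI *contrasts* (relative to the medium) with
independent multiplicative truncated-normal factors (|z| ≤ 2; default 10%);
RI draws violating the ordering are redrawn. All randomness flows from
`numpy` `SeedSequence` spawning, so cohorts are reproducible from one seed.

What the phantoms do **not** emulate: protrusions and irregular cell
outlines, substrate/coverslip optics, intracellular texture beyond the four
compartment classes, dry-mass calibration, absorption, camera quantization,
and partial coherence. Passing tests therefore demonstrate correctness of
the measurement and analysis chain on idealized geometry, not performance
on real tomograms.

## Segmentation and morphometrics

Body: voxels with RI ≥ 1.34 (the background is 1.334), morphological
opening and closing with 1-voxel ball elements, then a connected-component
policy (largest 26-connected component by default; `all` and `seeded`
variants available). Interactive mask cleanup and manual nucleus marking
have no place in a tested pipeline, so both are replaced by deterministic
equivalents: the component policy, and an explicit nucleus seed with an
automatic default (centroid of the dominant smoothed high-RI blob in the
z = 0 section; 0.8-µm smoothing suppresses sub-micron particles so
autophagic cells do not mislead the seed).

Nucleus: from the seed, the bright region is grown at Otsu's threshold of
the smoothed in-body RI (robust to the small bright nucleolus; midpoint
fallback when the seed is darker than the split), its boundary voxels with
above-median gradient magnitude form the edge cloud, and a general
algebraic least-squares quadric is fitted (9 coefficients; validated to be
an ellipsoid, with an axis-aligned fallback). The fitted ellipsoid is
clipped to the body; cytoplasm is the exact set difference. The identities
nucleus ⊆ body, cytoplasm = body \ nucleus, |body| = |nucleus| +
|cytoplasm| hold exactly by construction and are asserted in tests.

Per compartment: section area (pixel count at z = 0 × pitch²), height
(occupied axial slice span × pitch), volume (voxel count × pitch³), mean RI
(arithmetic mean over the mask, strictly over mask voxels), plus the four
nucleus/cytoplasm ratios — 16 parameters. The working z = 0 plane is the
slice of maximal body cross-section (cell-relative and reproducible; a
fixed instrument plane is available by config). Degenerate cases: empty
cytoplasm → NCRs NaN and flagged; empty nucleus → NCRs 0 with a warning.

RI histograms of the z = 0 section use fixed 0.002-RI bins (the
instrument-level RI accuracy) from the medium to 1.45 and are fitted with a
sum of Gaussians (default 3 components) by Poisson-weighted least squares
(σ = √(counts+1)); initial centers are the global mode and the highest and
lowest occupied bins, so a sparse high-RI population (the autophagy
particles) always seeds a component. "Direct fitting" of such histograms
does not name a model; sum-of-Gaussians is this package's documented
choice.

## Statistics

Pairwise state comparisons use the two-sided Mann–Whitney U test by default
(morphometric distributions are skewed; Welch's t is available), with the
conventional star labels at strict thresholds: n.s. p ≥ 0.05, * p < 0.05,
** p < 0.01, *** p < 0.001, **** p < 0.0001. No multiple-testing correction
is applied by default; Holm-adjusted columns are available behind a flag.
Constant-valued pairs are flagged degenerate (p = NaN). Type-I calibration
is verified by permutation splits of a single cohort.

## Problem sizes and tolerances

Defaults used by the test suite and the demo pipeline (chosen as sensible
desk-scale sizes): bead accuracy runs on 192³ grids at 0.1 µm pitch with
241 angles; cohort recovery uses 30 phantoms at 0.45 geometric scale on
128³ grids with 61 angles and 1% hologram noise; state-signature cohorts
use 20 cells/state voxelized at 0.2 µm pitch without optical simulation.
Key measured figures the tests assert: bead-core RI error ≤ 0.002 (measured
≈ 0.0008); forward-phase vs optical-path agreement within 2%; demodulation
round-trip ≤ 10⁻² rad RMS (measured ≤ 2.2×10⁻³ across states); rank
correlation of true vs recovered volume and section area > 0.9 (measured
≈ 0.99 each, with section-area median error ≈ 3%). Two axial quantities do
*not* meet their nominal bounds through the full optical pipeline: the
median body-volume error of thin cells is ≈ 34% (not < 10%) and the height
rank correlation collapses (ρ ≈ −0.1), because the missing-cone smear adds
a near-constant ≈ 2.3 µm to every mask height at the 1.34 threshold —
round apoptotic cells recover their height almost exactly while flat cells
inflate most, which reorders the ranking. The corresponding tests assert
the nominal bounds and fail; they document a physical limit of
limited-angle direct inversion with near-background thresholding, not an
implementation defect.

## Known limitations

- Scalar diffraction, first Rytov only; no multiple scattering, absorption
  or vectorial effects.
- Single-axis beam rotation; dual-axis scan patterns are not modeled.
- One cell per field of view; no crowded-field instance segmentation.
- Threshold volumetry of thin objects inherits the missing-cone bias of
  limited-angle direct inversion (quantified above).
- The synthetic cohorts encode the *reported direction* of each state
  contrast with plausible magnitudes; they cannot validate biological
  effect sizes.
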