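"""Synthetic 3D refractive-index cell phantoms for the four cell states.

Each phantom is a set of analytically defined compartments voxelized onto an
isotropic grid: an ellipsoidal cell body filled with cytoplasm RI, an
ellipsoidal nucleus, an optional spherical nucleolus, and state-specific
extras — small high-RI particles for autophagy (RI > 1.42, 0.8-1 um), and
detached apoptotic body fragments plus a condensed ~7 um spherical nucleus
for apoptosis.  The state defaults encode the qualitative morphology
contrasts of the four death pathways: autophagic cells are volume-reduced,
apoptotic nuclei are small, round and dense (RI > 1.41), ferroptotic cells
look like normal cells except for an elevated nucleus/cytoplasm RI contrast.

The medium is PBS at RI 1.334 and every compartment RI respects
``medium < cytoplasm < nucleus <= nucleolus``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import MEDIUM_RI, PlacementError, RITomogram, SizingError

STATES = ("normal", "autophagy", "apoptosis", "ferroptosis")

_MAX_PLACEMENT_TRIES = 500


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and optical description of one synthetic cell.

    Radii are semi-axes in micrometers.  ``fragment_count`` is the number of
    detached apoptotic bodies accompanying the main cell body.
    """

    state: str
    medium_ri: float = MEDIUM_RI
    cytoplasm_ri: float = 1.355
    nucleus_ri: float = 1.365
    nucleolus_ri: float = 1.390
    body_radii_um: tuple[float, float, float] = (10.0, 8.0, 4.0)
    nucleus_radii_um: tuple[float, float, float] = (4.5, 4.5, 3.5)
    nucleolus_radius_um: float = 1.0
    particle_count: int = 0
    particle_ri: float = 1.425
    particle_diameter_range_um: tuple[float, float] = (0.8, 1.0)
    fragment_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not (self.medium_ri < self.cytoplasm_ri < self.nucleus_ri
                <= self.nucleolus_ri):
            raise ValueError(
                "RI ordering violated: require medium < cytoplasm < nucleus "
                "<= nucleolus")
        if self.particle_count < 0 or self.fragment_count < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.particle_diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError("invalid particle diameter range")

    @classmethod
    def for_state(cls, state: str, scale: float = 1.0,
                  rng_seed: int = 0) -> "PhantomSpec":
        """Default spec for a cell state, optionally geometrically scaled.

        ``scale`` multiplies every compartment semi-axis (particle diameters
        are left at their physical size).
        """
        base = dict(state=state, rng_seed=rng_seed)
        if state == "normal":
            spec = cls(**base)
        elif state == "autophagy":
            # body scaled to ~70% of the normal volume (0.888 per axis)
            spec = cls(body_radii_um=(8.9, 7.1, 3.55),
                       nucleus_radii_um=(4.0, 4.0, 3.0),
                       particle_count=5, **base)
        elif state == "apoptosis":
            spec = cls(cytoplasm_ri=1.360, nucleus_ri=1.415,
                       nucleolus_ri=1.415, nucleolus_radius_um=0.0,
                       body_radii_um=(5.5, 5.5, 4.5),
                       nucleus_radii_um=(3.5, 3.5, 3.5),
                       fragment_count=3, **base)
        elif state == "ferroptosis":
            spec = cls(cytoplasm_ri=1.352, nucleus_ri=1.372,
                       nucleolus_ri=1.392, **base)
        else:
            raise ValueError(f"unknown state {state!r}")
        if scale != 1.0:
            spec = replace(
                spec,
                body_radii_um=tuple(r * scale for r in spec.body_radii_um),
                nucleus_radii_um=tuple(r * scale for r in spec.nucleus_radii_um),
                nucleolus_radius_um=spec.nucleolus_radius_um * scale,
            )
        return spec

    def body_volume_um3(self) -> float:
        a, b, c = self.body_radii_um
        return 4.0 / 3.0 * math.pi * a * b * c

    def nucleus_volume_um3(self) -> float:
        a, b, c = self.nucleus_radii_um
        return 4.0 / 3.0 * math.pi * a * b * c


def default_grid_shape(spec: PhantomSpec, voxel_pitch_um: float,
                       margin_um: float = 2.0) -> tuple[int, int, int]:
    """Smallest even grid holding the phantom with a lateral/axial margin.

    Apoptotic specs get extra lateral room for the detached fragments.
    """
    extra = 4.0 if spec.fragment_count > 0 else 0.0
    shape = []
    for i, r in enumerate(spec.body_radii_um):
        m = margin_um + (extra if i < 2 else 0.0)
        n = int(np.ceil(2 * (r + m) / voxel_pitch_um))
        shape.append(n + n % 2)
    return tuple(shape)


def _ellipsoid_mask(X, Y, Z, center, radii) -> np.ndarray:
    terms = 0.0
    for c, r, g in zip(center, radii, (X, Y, Z)):
        if r <= 0:
            return np.zeros(X.shape, dtype=bool)
        terms = terms + ((g - c) / r) ** 2
    return terms <= 1.0


def _rho(point, center, radii) -> float:
    """Normalized ellipsoidal coordinate of a point (1.0 on the surface)."""
    return math.sqrt(sum(((p - c) / r) ** 2
                         for p, c, r in zip(point, center, radii)))


def generate_phantom(spec: PhantomSpec, grid_shape: tuple[int, int, int],
                     voxel_pitch_um: float) -> RITomogram:
    """Voxelize a phantom spec onto a grid.

    Compartments are filled in order medium -> cytoplasm -> nucleus ->
    nucleolus -> particles, so later compartments overwrite earlier ones.
    Particle and fragment placement is rejection-sampled from the spec's
    seeded generator, so the phantom is reproducible from ``rng_seed``.

    Raises
    ------
    SizingError
        If the body (plus a 2-voxel margin) exceeds the grid.
    PlacementError
        If a particle or fragment cannot be placed after bounded retries.
    """
    if voxel_pitch_um <= 0:
        raise ValueError("voxel_pitch_um must be positive")
    p = voxel_pitch_um
    axes = [(np.arange(n) - n // 2) * p for n in grid_shape]
    half = [ax[-1] for ax in axes]
    if any(r > 0 and r + 2 * p > h for r, h in zip(spec.body_radii_um, half)):
        raise SizingError(
            f"body semi-axes {spec.body_radii_um} exceed grid "
            f"{grid_shape} at pitch {p}")

    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    vol = np.full(grid_shape, spec.medium_ri, dtype=np.float32)
    rng = np.random.default_rng(spec.rng_seed)

    body_c = (0.0, 0.0, 0.0)
    body = _ellipsoid_mask(X, Y, Z, body_c, spec.body_radii_um)
    vol[body] = spec.cytoplasm_ri

    nucleus = _ellipsoid_mask(X, Y, Z, body_c, spec.nucleus_radii_um)
    nucleus &= body
    vol[nucleus] = spec.nucleus_ri

    if spec.nucleolus_radius_um > 0 and all(r > 0 for r in spec.nucleus_radii_um):
        nc = _place_nucleolus(spec, rng)
        nucleolus = _ellipsoid_mask(X, Y, Z, nc,
                                    (spec.nucleolus_radius_um,) * 3)
        vol[nucleolus & nucleus] = spec.nucleolus_ri

    if spec.particle_count > 0:
        for c, r in _place_particles(spec, half, rng):
            vol[_ellipsoid_mask(X, Y, Z, c, (r, r, r))] = spec.particle_ri

    if spec.fragment_count > 0:
        for c, r in _place_fragments(spec, half, rng):
            frag = _ellipsoid_mask(X, Y, Z, c, (r, r, r))
            vol[frag & ~body] = spec.cytoplasm_ri

    return RITomogram(vol, voxel_pitch_um=p, medium_ri=spec.medium_ri)


def _place_nucleolus(spec, rng):
    """Random nucleolus center fully inside the nucleus."""
    r = spec.nucleolus_radius_um
    radii = spec.nucleus_radii_um
    for _ in range(_MAX_PLACEMENT_TRIES):
        c = tuple(rng.uniform(-0.5, 0.5) * a for a in radii)
        if _rho(c, (0, 0, 0), radii) <= 1.0 - r / min(radii):
            return c
    return (0.0, 0.0, 0.0)  # center always works for the defaults


def _place_particles(spec, half, rng):
    """Disjoint particle spheres fully inside the cytoplasm shell."""
    lo, hi = spec.particle_diameter_range_um
    placed: list[tuple[tuple, float]] = []
    ba = spec.body_radii_um
    na = spec.nucleus_radii_um
    for _ in range(spec.particle_count):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            r = 0.5 * rng.uniform(lo, hi)
            c = tuple(rng.uniform(-a, a) for a in ba)
            # containment via per-axis eroded/dilated ellipsoids
            if any(a <= r for a in ba) or \
                    _rho(c, (0, 0, 0), tuple(a - r for a in ba)) > 1.0:
                continue  # not fully inside the body
            if all(a > 0 for a in na) and \
                    _rho(c, (0, 0, 0), tuple(a + r + 0.1 for a in na)) < 1.0:
                continue  # intrudes into the nucleus
            if any(math.dist(c, c2) < r + r2 + 0.2 for c2, r2 in placed):
                continue  # touching another particle
            placed.append((c, r))
            break
        else:
            raise PlacementError(
                f"could not place particle {len(placed) + 1} of "
                f"{spec.particle_count}")
    return placed


def _place_fragments(spec, half, rng):
    """Detached apoptotic bodies around the main cell body."""
    placed: list[tuple[tuple, float]] = []
    ba = spec.body_radii_um
    # fragment size and stand-off scale with the cell so scaled-down
    # phantoms still fit their grid
    ref = max(ba)
    for _ in range(spec.fragment_count):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            r = rng.uniform(0.18, 0.33) * ref
            phi = rng.uniform(0, 2 * math.pi)
            # radial gap between the body surface and the fragment
            gap = rng.uniform(0.08, 0.22) * ref
            direction = (math.cos(phi), math.sin(phi), 0.0)
            # body surface radius along the direction
            s = 1.0 / _rho(direction, (0, 0, 0), ba)
            d = s + gap + r
            c = (direction[0] * d, direction[1] * d,
                 rng.uniform(-0.3, 0.3) * ba[2])
            if any(abs(ci) + r > h - 1e-9 for ci, h in zip(c, half)):
                continue  # outside the grid
            if _rho(c, (0, 0, 0), ba) < 1.0 + r / min(ba):
                continue  # touches the main body
            if any(math.dist(c, c2) < r + r2 + 0.2 for c2, r2 in placed):
                continue
            placed.append((c, r))
            break
        else:
            raise PlacementError(
                f"could not place fragment {len(placed) + 1} of "
                f"{spec.fragment_count}")
    return placed


# ---------------------------------------------------------------------------
# Cohorts

def _truncated_factor(rng, jitter: float) -> float:
    """Multiplicative jitter factor 1 + jitter*z, z ~ N(0,1) truncated at 2."""
    while True:
        z = rng.standard_normal()
        if abs(z) <= 2.0:
            return 1.0 + jitter * z


def cohort_specs(state: str, n_cells: int, parameter_jitter: float,
                 rng_seed: int, scale: float = 1.0) -> list[PhantomSpec]:
    """Seeded list of jittered specs around the state defaults.

    Geometry parameters (semi-axes, nucleolus radius) and RI *contrasts*
    relative to the medium are jittered independently with multiplicative
    truncated-normal factors; RI sets violating the compartment ordering are
    redrawn.  Counts are jittered and rounded.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= parameter_jitter < 0.5:
        raise ValueError("parameter_jitter must be in [0, 0.5)")
    base = PhantomSpec.for_state(state, scale=scale)
    seeds = np.random.SeedSequence(rng_seed).spawn(n_cells)
    specs = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        if parameter_jitter == 0:
            specs.append(replace(base, rng_seed=cell_seed))
            continue
        j = parameter_jitter
        body = tuple(r * _truncated_factor(rng, j) for r in base.body_radii_um)
        nuc = tuple(min(rn * _truncated_factor(rng, j), 0.92 * rb)
                    for rn, rb in zip(base.nucleus_radii_um, body))
        nol = base.nucleolus_radius_um * _truncated_factor(rng, j)
        while True:
            ris = {name: base.medium_ri
                   + (getattr(base, name) - base.medium_ri)
                   * _truncated_factor(rng, j)
                   for name in ("cytoplasm_ri", "nucleus_ri", "nucleolus_ri")}
            ris["nucleolus_ri"] = max(ris["nucleolus_ri"], ris["nucleus_ri"])
            if base.medium_ri < ris["cytoplasm_ri"] < ris["nucleus_ri"]:
                break
        pc = base.particle_count
        if pc > 0:
            pc = max(1, round(pc * _truncated_factor(rng, j)))
        fc = base.fragment_count
        if fc > 0:
            fc = min(4, max(1, round(fc * _truncated_factor(rng, j))))
        specs.append(replace(
            base, body_radii_um=body, nucleus_radii_um=nuc,
            nucleolus_radius_um=nol, particle_count=pc, fragment_count=fc,
            rng_seed=cell_seed, **ris))
    return specs


def generate_cohort(state: str, n_cells: int, parameter_jitter: float,
                    rng_seed: int, *, scale: float = 1.0,
                    voxel_pitch_um: float = 0.2,
                    grid_shape: tuple[int, int, int] | None = None,
                    ) -> list[tuple[PhantomSpec, RITomogram]]:
    """Generate ``n_cells`` voxelized phantoms of one state.

    The list order and every phantom are deterministic given ``rng_seed``.
    When ``grid_shape`` is None each phantom gets the smallest even grid that
    holds it (see :func:`default_grid_shape`).
    """
    specs = cohort_specs(state, n_cells, parameter_jitter, rng_seed,
                         scale=scale)
    out = []
    for spec in specs:
        shape = grid_shape or default_grid_shape(spec, voxel_pitch_um)
        out.append((spec, generate_phantom(spec, shape, voxel_pitch_um)))
    return out
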