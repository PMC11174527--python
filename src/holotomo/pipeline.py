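"""End-to-end pipeline: simulate -> reconstruct -> segment -> quantify -> report.

A :class:`PipelineConfig` fully determines a run: one global seed is fanned
out deterministically to per-cell child seeds (phantom geometry jitter and
hologram noise), so two runs with the same config produce identical cohort
tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import forward, holography, morphometry, phantoms, reconstruct, segment
from .core import RITomogram
from .stats import full_report, render_report

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter of a full simulated-cohort run."""

    states: tuple[str, ...] = ("normal", "autophagy", "apoptosis",
                               "ferroptosis")
    n_cells_per_state: int = 10
    parameter_jitter: float = 0.1
    phantom_scale: float = 0.45
    grid_n: int = 128
    voxel_pitch_um: float = 0.1
    n_angles: int = 61
    span_deg: tuple[float, float] = (-45.0, 45.0)
    noise_level: float = 0.01
    positivity_iterations: int = 20
    body_ri_threshold: float = 1.34
    z0_policy: str = "max_area"
    statistical_test: str = "mannwhitney"
    holm_correction: bool = False
    seed: int = 0
    output_dir: str = "holotomo_run"
    save_volumes: bool = False
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        for fld in dataclasses.fields(cls):
            if fld.name in data and isinstance(data[fld.name], list):
                data[fld.name] = tuple(data[fld.name])
        return cls(**data)


def simulate_cell(tomo: RITomogram, schedule: forward.IlluminationSchedule,
                  noise_level: float = 0.0, noise_seed: int | None = None,
                  ) -> list[forward.Hologram]:
    """Off-axis holograms of one phantom over the whole schedule."""
    prop = forward.RytovPropagator(tomo, schedule)
    seeds = (np.random.SeedSequence(noise_seed)
             .generate_state(len(schedule.angles_deg)) % (2**31 - 1)
             if noise_seed is not None else
             [None] * len(schedule.angles_deg))
    holos = []
    for ang, s in zip(schedule.angles_deg, seeds):
        f = prop.field(ang)
        holos.append(forward.form_hologram(
            f, noise_level=noise_level,
            noise_seed=None if s is None else int(s)))
    return holos


def reconstruct_cell(holos: list[forward.Hologram],
                     schedule: forward.IlluminationSchedule,
                     grid_n: int,
                     positivity_iterations: int = 0) -> RITomogram:
    """Demodulate, flat-field, unwrap and direct-invert one hologram stack."""
    ref_field = forward.ComplexField2D(
        amplitude=np.ones((grid_n, grid_n)),
        phase=np.zeros((grid_n, grid_n)),
        angle_deg=0.0, pixel_pitch_um=holos[0].pixel_pitch_um)
    ref_holo = forward.form_hologram(
        ref_field, carrier_cyc_per_um=holos[0].carrier_frequency_cyc_per_um)
    fields = (holography.process_hologram(h, ref_holo) for h in holos)
    return reconstruct.reconstruct_tomogram(
        fields, schedule, (grid_n,) * 3, holos[0].pixel_pitch_um,
        positivity_iterations=positivity_iterations)


def process_tomogram(tomo: RITomogram, config: PipelineConfig,
                     cell_id: str = "", state: str = "",
                     ) -> morphometry.MorphologyRecord | None:
    """Segment a tomogram and compute its morphology record."""
    seg_cfg = segment.SegmentationConfig(
        body_ri_threshold=config.body_ri_threshold)
    masks = segment.segment_cell(tomo, seg_cfg)
    if not masks.body.any():
        log.warning("cell %s: empty segmentation, skipped", cell_id)
        return None
    return morphometry.compute_morphology(
        tomo, masks, z0_policy=config.z0_policy, cell_id=cell_id,
        state=state)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the whole pipeline; returns the artifact directory.

    Per state and cell: jittered phantom -> angle-scanned holograms ->
    direct inversion (optionally with positivity iterations) -> threshold
    segmentation -> 16-parameter record.  The cohort table, pairwise
    statistics, box plots and the resolved config are persisted.  Stage
    failures abort with a stage-tagged error; artifacts written so far are
    retained.
    """
    logging.basicConfig(level=config.verbosity)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    schedule = forward.make_schedule(config.n_angles, config.span_deg)
    root_ss = np.random.SeedSequence(config.seed)
    state_seeds = {s: int(ss.generate_state(1)[0] % (2**31 - 1))
                   for s, ss in zip(config.states,
                                    root_ss.spawn(len(config.states)))}
    rows = []
    t_start = time.time()
    for state in config.states:
        specs = phantoms.cohort_specs(
            state, config.n_cells_per_state, config.parameter_jitter,
            state_seeds[state], scale=config.phantom_scale)
        for i, spec in enumerate(specs):
            cell_id = f"{state}_{i:03d}"
            t0 = time.time()
            try:
                tomo = phantoms.generate_phantom(
                    spec, (config.grid_n,) * 3, config.voxel_pitch_um)
                holos = simulate_cell(tomo, schedule, config.noise_level,
                                      noise_seed=spec.rng_seed)
                recon = reconstruct_cell(holos, schedule, config.grid_n,
                                         config.positivity_iterations)
            except Exception as exc:
                raise RuntimeError(
                    f"[simulate/reconstruct] cell {cell_id}: {exc}") from exc
            if config.save_volumes:
                from .io import write_tomogram
                write_tomogram(recon, out / f"{cell_id}_ri.h5",
                               state=state, seed=spec.rng_seed)
            try:
                rec = process_tomogram(recon, config, cell_id, state)
            except Exception as exc:
                raise RuntimeError(
                    f"[segment/quantify] cell {cell_id}: {exc}") from exc
            if rec is not None:
                row = rec.to_row()
                row["true_volume_um3"] = spec.body_volume_um3()
                rows.append(row)
            log.info("cell %s done in %.1f s", cell_id, time.time() - t0)
    table = pd.DataFrame(rows)
    table.to_csv(out / "cohort.csv", index=False, lineterminator="\n")
    try:
        report = full_report(table, test=config.statistical_test,
                             holm=config.holm_correction)
    except ValueError as exc:
        log.warning("statistics skipped: %s", exc)
        report = pd.DataFrame()
    render_report(table.drop(columns=["true_volume_um3"]), report, out)
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return out
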