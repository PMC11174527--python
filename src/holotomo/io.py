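"""Readers and writers for tomograms, hologram stacks, fields and masks.

Volumes travel as 32-bit float multi-page TIFF stacks (metadata in the JSON
ImageDescription) or as HDF5 datasets with attributes; both round-trip the
voxel pitch and medium RI.  Page order of TIFF stacks is z-major (one x-y
section per page).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import RITomogram
from .forward import ComplexField2D, Hologram, IlluminationSchedule


class MetadataError(ValueError):
    """A required metadata attribute is absent from the file."""


def _required(meta: dict, key: str, path) -> float:
    if key not in meta:
        raise MetadataError(f"{path}: missing required attribute {key!r}")
    return meta[key]


def write_tomogram(tomo: RITomogram, path: str | Path, **extra_meta) -> Path:
    """Write a tomogram as TIFF (.tif/.tiff) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    meta = {"voxel_pitch_um": float(tomo.voxel_pitch_um),
            "medium_ri": float(tomo.medium_ri), **extra_meta}
    vol = np.asarray(tomo.values, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        # pages along z
        tifffile.imwrite(path, np.moveaxis(vol, 2, 0),
                         description=json.dumps(meta))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("ri", data=vol)
            for k, v in meta.items():
                ds.attrs[k] = v
    else:
        raise ValueError(f"unsupported tomogram format {path.suffix!r}")
    return path


def read_tomogram(path: str | Path) -> RITomogram:
    """Read a tomogram written by :func:`write_tomogram`.

    Raises :class:`MetadataError` naming any absent required attribute.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            vol = tf.asarray()
            desc = tf.pages[0].description or ""
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        vol = np.moveaxis(vol, 0, 2)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["ri"]
            vol = ds[()]
            meta = dict(ds.attrs)
    else:
        raise ValueError(f"unsupported tomogram format {path.suffix!r}")
    return RITomogram(
        values=np.asarray(vol, dtype=np.float32),
        voxel_pitch_um=float(_required(meta, "voxel_pitch_um", path)),
        medium_ri=float(_required(meta, "medium_ri", path)))


def write_hologram_stack(holos: list[Hologram],
                         schedule: IlluminationSchedule,
                         path: str | Path) -> Path:
    """Hologram stack: TIFF with one page per angle, or an HDF5 group."""
    path = Path(path)
    stack = np.stack([h.intensity for h in holos]).astype(np.float32)
    meta = {
        "pixel_pitch_um": float(holos[0].pixel_pitch_um),
        "angles_deg": [float(h.angle_deg) for h in holos],
        "carrier_cyc_per_um": list(holos[0].carrier_frequency_cyc_per_um),
        "wavelength_um": float(schedule.wavelength_um),
        "detection_na": float(schedule.detection_na),
        "medium_ri": float(schedule.medium_ri),
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack, description=json.dumps(meta))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("holograms")
            g.create_dataset("intensity", data=stack)
            for k, v in meta.items():
                g.attrs[k] = v
    else:
        raise ValueError(f"unsupported hologram format {path.suffix!r}")
    return path


def read_hologram_stack(path: str | Path,
                        ) -> tuple[list[Hologram], dict]:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = json.loads(tf.pages[0].description)
    else:
        with h5py.File(path, "r") as f:
            g = f["holograms"]
            stack = g["intensity"][()]
            meta = {k: (v.tolist() if hasattr(v, "tolist") else v)
                    for k, v in g.attrs.items()}
    if stack.ndim == 2:
        stack = stack[None]
    holos = [Hologram(intensity=np.asarray(img, dtype=np.float64),
                      pixel_pitch_um=float(meta["pixel_pitch_um"]),
                      carrier_frequency_cyc_per_um=tuple(
                          meta["carrier_cyc_per_um"]),
                      angle_deg=float(a))
             for img, a in zip(stack, meta["angles_deg"])]
    return holos, meta


def write_fields(fields: list[ComplexField2D], path: str | Path) -> Path:
    """Per-angle complex fields to HDF5 (amplitude + phase datasets)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("fields")
        g.create_dataset("amplitude",
                         data=np.stack([fl.amplitude for fl in fields]
                                       ).astype(np.float32))
        g.create_dataset("phase",
                         data=np.stack([fl.phase for fl in fields]
                                       ).astype(np.float32))
        g.attrs["angles_deg"] = [fl.angle_deg for fl in fields]
        g.attrs["pixel_pitch_um"] = float(fields[0].pixel_pitch_um)
    return path


def read_fields(path: str | Path) -> list[ComplexField2D]:
    with h5py.File(path, "r") as f:
        g = f["fields"]
        amp = g["amplitude"][()]
        ph = g["phase"][()]
        angles = list(g.attrs["angles_deg"])
        pitch = float(g.attrs["pixel_pitch_um"])
    return [ComplexField2D(amplitude=np.asarray(a, dtype=np.float64),
                           phase=np.asarray(p, dtype=np.float64),
                           angle_deg=float(ang), pixel_pitch_um=pitch)
            for a, p, ang in zip(amp, ph, angles)]


def write_masks(masks, path: str | Path) -> Path:
    """Segmentation masks as 8-bit TIFF stack (pages: body, nucleus,
    cytoplasm along a leading axis) or HDF5 boolean datasets."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for name in ("body", "nucleus", "cytoplasm"):
                f.create_dataset(name, data=getattr(masks, name),
                                 dtype="uint8")
    else:
        stack = np.stack([np.moveaxis(getattr(masks, n), 2, 0)
                          for n in ("body", "nucleus", "cytoplasm")])
        tifffile.imwrite(path, stack.astype(np.uint8))
    return path
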