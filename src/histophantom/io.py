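"""Persistence: phantoms and RF to HDF5, masks to PNG + JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .datatypes import AcousticPhantom, ComponentMasks, RFChannelData

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_rf",
    "load_rf",
    "save_masks",
    "load_masks",
]


def save_phantom(path, phantom: AcousticPhantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("density", data=phantom.density, track_times=False)
        f.create_dataset("sound_speed", data=phantom.sound_speed, track_times=False)
        f.create_dataset("alpha0", data=phantom.absorption, track_times=False)
        f.attrs["y"] = phantom.y
        f.attrs["spacing_um"] = phantom.spacing_um


def load_phantom(path) -> AcousticPhantom:
    with h5py.File(path, "r") as f:
        return AcousticPhantom(
            density=f["density"][...],
            sound_speed=f["sound_speed"][...],
            absorption=f["alpha0"][...],
            y=float(f.attrs["y"]),
            spacing_um=float(f.attrs["spacing_um"]),
        )


def save_rf(path, rf: RFChannelData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf.samples, track_times=False)
        f.attrs["dt"] = rf.dt
        f.attrs["t0"] = rf.t0
        f.attrs["angles_deg"] = rf.angles_deg


def load_rf(path) -> RFChannelData:
    with h5py.File(path, "r") as f:
        return RFChannelData(
            samples=f["rf"][...],
            dt=float(f.attrs["dt"]),
            t0=float(f.attrs["t0"]),
            angles_deg=np.asarray(f.attrs["angles_deg"]),
        )


def save_masks(outdir, masks: ComponentMasks, stem: str = "masks") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("collagen", "cell", "background"):
        arr = (getattr(masks, name).astype(np.uint8)) * 255
        Image.fromarray(arr, mode="L").save(outdir / f"{stem}_{name}.png")
    (outdir / f"{stem}.json").write_text(
        json.dumps({"resolution_um": masks.resolution_um})
    )


def load_masks(outdir, stem: str = "masks") -> ComponentMasks:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}.json").read_text())
    parts = {}
    for name in ("collagen", "cell", "background"):
        parts[name] = (
            np.asarray(Image.open(outdir / f"{stem}_{name}.png")) > 127
        )
    return ComponentMasks(resolution_um=meta["resolution_um"], **parts)
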