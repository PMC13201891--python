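"""End-to-end orchestration with reproducible configs and a run manifest.

A run executes synth -> segment -> build -> simulate -> beamform -> metrics
in dependency order. Every artifact is stamped with the config hash and the
global seed; the manifest records inputs, outputs and SHA-256 checksums so
any output is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .beamform import das_beamform, to_bmode
from .datatypes import PlaneWavePlan, PulseSpec, SegmentationConfig
from .io import save_masks, save_phantom
from .metrics import envelope_histogram, fd_bin_width, speckle_size, tai
from .phantom import assemble_phantom
from .properties import get_tissue
from .search import surrogate_envelope
from .segmentation import downsample_masks, segment_components
from .simulate import simulate
from .synthhist import MicrostructureRecipe, generate_slide
from .transducer import get_transducer, make_grid

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    return {
        "rng_seed": 0,
        "tissue": "muscle",
        "synth": {"size_px": 768, "resolution_um": 3.0,
                  "cell_diameter_um": 180.0, "border_thickness_um": 15.0,
                  "orientation_deg": 0.0},
        # opening radius must stay below half the perimysium thickness or
        # the collagen bands erode away
        "segment": {"n_clusters": 3, "opening_radius_um": 3.0,
                    "closing_radius_um": 3.0},
        "grid_spacing_um": 24.7,
        "simulator": "surrogate",  # or "fullwave"
        "probe": "L11-5v",
        "n_angles": 5,
        "max_angle_deg": 10.0,
        "bmode": {"dynamic_range_db": 60.0, "percentile": 99.0},
    }


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured pipeline; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _hash_config(config)
    seed = int(config["rng_seed"])
    tissue = config["tissue"]
    manifest = {"config_hash": cfg_hash, "seed": seed, "stages": {},
                "outputs": {}}
    (outdir / "config.yaml").write_text(yaml.safe_dump(config))

    # synth
    s = config["synth"]
    recipe = MicrostructureRecipe(
        tissue_label=tissue,
        cell_diameter_um=s["cell_diameter_um"],
        border_thickness_um=s["border_thickness_um"],
        orientation_deg=s.get("orientation_deg", 0.0),
        rng_seed=seed,
    )
    image, truth = generate_slide(recipe, s["size_px"], s["resolution_um"])
    manifest["stages"]["synth"] = {"n_px": int(image.pixels.size)}

    # segment
    g = config["segment"]
    seg_cfg = SegmentationConfig(
        n_clusters=g["n_clusters"],
        opening_radius_um=g["opening_radius_um"],
        closing_radius_um=g["closing_radius_um"],
        rng_seed=seed,
    )
    masks = segment_components(image, seg_cfg)
    masks = downsample_masks(masks, config["grid_spacing_um"])
    save_masks(outdir, masks)
    manifest["stages"]["segment"] = {
        "collagen_fraction": float(masks.collagen.mean())
    }

    # build
    props = get_tissue(tissue)
    phantom = assemble_phantom(masks, props)
    save_phantom(outdir / "phantom.h5", phantom)
    manifest["stages"]["build"] = {
        "mean_density": float(phantom.density.mean()),
        "mean_sound_speed": float(phantom.sound_speed.mean()),
    }

    # simulate + beamform (or fast surrogate envelope)
    probe = get_transducer(config["probe"])
    if config["simulator"] == "fullwave":
        h, w = phantom.shape
        depth_mm = h * phantom.spacing_um * 1e-3
        width_mm = w * phantom.spacing_um * 1e-3
        grid = make_grid(probe, depth_mm, width_mm, props.c_global,
                         max_c=float(phantom.sound_speed.max()))
        plan = PlaneWavePlan.compounding(
            config["n_angles"], config["max_angle_deg"], props.c_global
        )
        pulse = PulseSpec(probe.center_frequency_hz)
        rf = simulate(phantom, probe, pulse, plan, grid)
        img = das_beamform(rf, plan, probe, config["grid_spacing_um"],
                           props.c_global)
        envelope = img.envelope
        spacing_um = config["grid_spacing_um"]
    else:
        envelope = surrogate_envelope(
            phantom.density, phantom.sound_speed, phantom.spacing_um,
            f0_hz=probe.center_frequency_hz,
        )
        spacing_um = phantom.spacing_um
    manifest["stages"]["simulate"] = {"mode": config["simulator"]}

    # metrics + B-mode preview
    env_pos = envelope[envelope.shape[0] // 8 :, :]
    ref = np.percentile(env_pos, config["bmode"]["percentile"])
    bmode = 20 * np.log10(np.maximum(env_pos, 1e-12) / max(ref, 1e-12))
    bmode = np.clip(bmode, -config["bmode"]["dynamic_range_db"], None)
    lam_um = props.c_global / probe.center_frequency_hz * 1e6
    tai_levels = tai(bmode, lam_um, spacing_um)
    hist = envelope_histogram(env_pos)
    metrics = {
        "fd_bin_width": fd_bin_width(env_pos),
        "tai": [
            {"cutoff_per_m": r.cutoff_per_m, "tai": r.tai} for r in tai_levels
        ],
        "histogram_mode_bin": int(np.argmax(hist.masses)),
    }
    try:
        ax_um, lat_um = speckle_size(env_pos, spacing_um)
        metrics["speckle_axial_um"] = ax_um
        metrics["speckle_lateral_um"] = lat_um
    except ValueError:
        pass
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    try:  # B-mode preview PNG (optional, headless backend)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(bmode, cmap="gray", aspect="auto",
                  vmin=-config["bmode"]["dynamic_range_db"], vmax=0)
        ax.set_xlabel("lateral [px]")
        ax.set_ylabel("axial [px]")
        fig.savefig(outdir / "bmode.png", dpi=120)
        plt.close(fig)
    except Exception:
        pass

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _checksum(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
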