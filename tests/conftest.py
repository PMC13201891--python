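"""Shared fixtures.

The two expensive session fixtures run the full-wave solver once and are
reused by solver, beamforming, metrics and acceptance tests:

* ``point_scatterer_run`` — a small water domain with a single weak point
  scatterer, three compounding angles (localization / compounding /
  point-sensor physics checks);
* ``pva_speckle_run`` — a scaled-down version of the PVA speckle-phantom
  acquisition (32 elements, ~10 mm depth, 11 angles at +/-20 deg) used for
  speckle sizing and autofocus.
"""

from __future__ import annotations

import numpy as np
import pytest

from histophantom.datatypes import (
    AcousticPhantom,
    BaselineSpec,
    PlaneWavePlan,
    PulseSpec,
    TissueProperties,
)
from histophantom.beamform import das_beamform
from histophantom.phantom import build_baseline_phantom
from histophantom.simulate import simulate
from histophantom.synthhist import MicrostructureRecipe, generate_slide
from histophantom.transducer import get_transducer, make_grid


def interior_shape(grid):
    iz, ix = grid.interior
    return (iz.stop - iz.start, ix.stop - ix.start)


@pytest.fixture(scope="session")
def small_probe():
    return get_transducer("L11-5v", n_elements=32)


@pytest.fixture(scope="session")
def point_scatterer_run(small_probe):
    """Water + one +5% density point at 5 mm depth, angles (-10, 0, 10)."""
    probe = small_probe
    grid = make_grid(probe, 8, 9.6, 1500.0, record_time=2.1 * 8e-3 / 1500.0)
    nzi, nxi = interior_shape(grid)
    rho = np.full((nzi, nxi), 1000.0)
    c = np.full((nzi, nxi), 1500.0)
    z_idx = int(round(5e-3 / grid.spacing_m))
    x_idx = nxi // 2
    rho[z_idx, x_idx] *= 1.05
    phantom = AcousticPhantom(rho, c, np.zeros_like(rho), 1.1, grid.spacing_um)
    plan = PlaneWavePlan(np.array([-20.0, 0.0, 20.0]), 1500.0)
    pulse = PulseSpec(probe.center_frequency_hz)
    rf = simulate(phantom, probe, pulse, plan, grid)
    true_z = (z_idx + 0.5) * grid.spacing_m
    true_x = (x_idx - (nxi - 1) / 2) * grid.spacing_m
    return {
        "rf": rf,
        "plan": plan,
        "probe": probe,
        "grid": grid,
        "pulse": pulse,
        "true_z": true_z,
        "true_x": true_x,
    }


@pytest.fixture(scope="session")
def pva_speckle_run(small_probe):
    """Scaled-down PVA speckle acquisition: 1000 kg/m^3 background,
    c = 1504 m/s, alpha0 = 0.29 dB/(MHz^y cm), and a 1% rms relative
    density perturbation — the scattering level of a SiC-loaded cryogel.
    (Speckle size does not depend on the perturbation amplitude once the
    speckle dominates boundary artifacts.)"""
    probe = small_probe
    props = TissueProperties(
        name="pva", rho_global=1000.0, c_global=1504.0, alpha0=0.29, y=1.1
    )
    grid = make_grid(probe, 10.0, 9.6, 1500.0, max_c=1570.0)
    phantom = build_baseline_phantom(
        props,
        interior_shape(grid),
        BaselineSpec(speckle_intensity=1e-4, rng_seed=7),
        grid.spacing_um,
    )
    plan = PlaneWavePlan.compounding(11, 20.0, 1504.0)
    pulse = PulseSpec(probe.center_frequency_hz)
    rf = simulate(phantom, probe, pulse, plan, grid)
    img = das_beamform(rf, plan, probe, 50.0, 1504.0, f_number=3.7,
                       depth_mm=(2.0, 9.7))
    return {"rf": rf, "plan": plan, "probe": probe, "grid": grid,
            "pulse": pulse, "image": img, "true_c": 1504.0}


@pytest.fixture(scope="session")
def muscle_slide():
    """Coarse synthetic muscle slide (12 um/px) with ground-truth masks."""
    recipe = MicrostructureRecipe(
        tissue_label="muscle",
        cell_diameter_um=250.0,
        border_thickness_um=40.0,
        orientation_deg=0.0,
        rng_seed=3,
    )
    image, truth = generate_slide(recipe, (512, 384), 12.0)
    return {"recipe": recipe, "image": image, "truth": truth}
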