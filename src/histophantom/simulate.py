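"""Plane-wave acquisition: phantom -> per-angle RF channel data.

The modeled array sits on the first interior grid row (z = 0 of the image).
Each element is a normal-velocity source with band-limited aperture
weights; transmit delays steer unfocused plane waves. Receive is the
aperture-weighted pressure sum per element at every solver time step,
band-limited decimated to ~4 x f0 before beamforming.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .datatypes import (
    AcousticPhantom,
    PlaneWavePlan,
    PulseSpec,
    RFChannelData,
    SimulationGrid,
    TransducerSpec,
)
from .solver import KSpaceSolver, SensorSpec, VelocitySource
from .transducer import element_aperture_weights

__all__ = ["embed_phantom", "simulate"]


def embed_phantom(phantom: AcousticPhantom, grid: SimulationGrid) -> AcousticPhantom:
    """Pad the phantom (which covers the PML-interior) out to the full grid
    by edge replication, so the PML absorbs into a matched medium."""
    iz, ix = grid.interior
    target = (iz.stop - iz.start, ix.stop - ix.start)
    if phantom.shape == (grid.nz, grid.nx):
        return phantom
    if phantom.shape != target:
        raise ValueError(
            f"phantom shape {phantom.shape} matches neither the grid interior "
            f"{target} nor the full grid ({grid.nz}, {grid.nx})"
        )
    p = grid.pml_thickness
    pad = ((p, grid.nz - iz.stop), (p, grid.nx - ix.stop))
    return AcousticPhantom(
        density=np.pad(phantom.density, pad, mode="edge"),
        sound_speed=np.pad(phantom.sound_speed, pad, mode="edge"),
        absorption=np.pad(phantom.absorption, pad, mode="edge"),
        y=phantom.y,
        spacing_um=phantom.spacing_um,
    )


def _source_signals(
    transducer: TransducerSpec,
    pulse: PulseSpec,
    delays: np.ndarray,
    weights_idx: np.ndarray,
    weights: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-grid-column transmit signals for one angle.

    Returns (cols, signals) where signals[k] drives lateral column cols[k].
    Columns shared between neighbouring elements accumulate both
    contributions.
    """
    t_end = delays.max() + pulse.duration
    nt = int(np.ceil(t_end / dt)) + 1
    t = np.arange(nt) * dt
    cols = np.unique(weights_idx)
    col_pos = {c: i for i, c in enumerate(cols)}
    signals = np.zeros((cols.size, nt))
    for e in range(transducer.n_elements):
        sig = pulse.sample(t - delays[e]) * (t >= delays[e])
        for c, w in zip(weights_idx[e], weights[e]):
            if w != 0.0:
                signals[col_pos[c]] += w * sig
    return cols, signals


def simulate(
    phantom: AcousticPhantom,
    transducer: TransducerSpec,
    pulse: PulseSpec,
    plan: PlaneWavePlan,
    grid: SimulationGrid,
    decimate_to_multiple: float | None = 4.0,
    dtype=np.float32,
    verbose: bool = False,
) -> RFChannelData:
    """Run one forward solve per plan angle and collect RF channel data."""
    medium = embed_phantom(phantom, grid)
    if abs(medium.spacing_um - grid.spacing_um) > 1e-6 * grid.spacing_um:
        raise ValueError("phantom spacing does not match the simulation grid")

    idx, wts = element_aperture_weights(transducer, grid)
    solver = KSpaceSolver(grid, medium, dtype=dtype)
    src_row = grid.pml_thickness
    sensor = SensorSpec(
        element_row=src_row, element_cols=idx, element_weights=wts
    )
    delays_all = plan.element_delays(transducer)

    per_angle = []
    for a, delays in enumerate(delays_all):
        cols, signals = _source_signals(
            transducer, pulse, delays, idx, wts, grid.dt
        )
        out = solver.run(
            velocity_source=VelocitySource(src_row, cols, signals),
            sensor=sensor,
        )
        per_angle.append(out["element_rf"])
        if verbose:
            print(f"angle {plan.angles_deg[a]:+.1f} deg done")

    rf = np.stack(per_angle, axis=-1)  # (nt, n_el, n_angle)
    dt_out = grid.dt
    if decimate_to_multiple is not None:
        fs_in = 1.0 / grid.dt
        fs_out = decimate_to_multiple * transducer.center_frequency_hz
        if fs_out < fs_in:
            frac = Fraction(fs_out / fs_in).limit_denominator(64)
            rf = resample_poly(rf, frac.numerator, frac.denominator, axis=0)
            dt_out = grid.dt * frac.denominator / frac.numerator

    # time zero at the pulse centre leaving the zero-delay element; the
    # staggered normal-velocity source sits half a cell proud of the
    # receive row, which advances every echo by dx/(2c) — compensated here
    # with the plan's reference speed
    stagger = grid.spacing_m / (2.0 * plan.reference_c)
    return RFChannelData(
        samples=rf,
        dt=dt_out,
        t0=-pulse.duration / 2.0 + stagger,
        angles_deg=plan.angles_deg,
    )
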