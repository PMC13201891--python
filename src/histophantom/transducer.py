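"""Linear-array modeling: presets, the grid-spacing rule, and band-limited
element aperture weights.

The computational grid uses eight points per wavelength at the centre
frequency (spacing = c / (8 f0)) and a CFL number of 0.3 for the time step.
To reduce staircasing, each rectangular element is represented on the grid
by samples of the spatial-Nyquist band-limited indicator of its width (the
rectangle convolved with the grid sinc kernel), rather than by nearest-grid
rounding of its edges.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sici

from .datatypes import SimulationGrid, TransducerSpec

__all__ = [
    "PRESETS",
    "get_transducer",
    "make_grid",
    "element_aperture_weights",
]

PRESETS: dict[str, TransducerSpec] = {
    "L11-5v": TransducerSpec(
        name="L11-5v",
        n_elements=128,
        pitch_um=300.0,
        element_width_um=270.0,
        center_frequency_hz=7.6e6,
    ),
    "L22-14v": TransducerSpec(
        name="L22-14v",
        n_elements=128,
        pitch_um=100.0,
        element_width_um=80.0,
        center_frequency_hz=18e6,
    ),
}


def get_transducer(name: str, n_elements: int | None = None) -> TransducerSpec:
    spec = PRESETS[name]
    if n_elements is not None and n_elements != spec.n_elements:
        from dataclasses import replace

        spec = replace(spec, n_elements=n_elements)
    return spec


def make_grid(
    transducer: TransducerSpec,
    depth_mm: float,
    width_mm: float,
    reference_c: float = 1500.0,
    max_c: float | None = None,
    record_time: float | None = None,
    pml_thickness: int = 20,
    cfl: float = 0.3,
) -> SimulationGrid:
    """Build the solver grid: spacing = reference_c / (8 f0), dt from the
    CFL condition against the medium's maximum sound speed, grid covering
    the requested extent plus the PML."""
    if depth_mm <= 0 or width_mm <= 0 or reference_c <= 0:
        raise ValueError("dimensions and reference sound speed must be positive")
    f0 = transducer.center_frequency_hz
    spacing_m = reference_c / (8.0 * f0)
    spacing_um = spacing_m * 1e6
    c_max = max_c if max_c is not None else reference_c
    dt = cfl * spacing_m / c_max
    from scipy.fft import next_fast_len

    # round grid dims up to FFT-friendly sizes (extra interior is harmless)
    nz = next_fast_len(int(np.ceil(depth_mm * 1e-3 / spacing_m)) + 2 * pml_thickness)
    nx = next_fast_len(int(np.ceil(width_mm * 1e-3 / spacing_m)) + 2 * pml_thickness)
    if record_time is None:
        record_time = 2.2 * depth_mm * 1e-3 / reference_c
    n_steps = int(np.ceil(record_time / dt))
    return SimulationGrid(
        nz=nz,
        nx=nx,
        spacing_um=spacing_um,
        dt=dt,
        n_steps=n_steps,
        pml_thickness=pml_thickness,
        cfl=cfl,
    )


def _bandlimited_rect(x: np.ndarray, a: float, b: float, dx: float) -> np.ndarray:
    """Samples of the indicator of [a, b] convolved with the grid's Nyquist
    sinc kernel: f(x) = (Si(pi (x - a)/dx) - Si(pi (x - b)/dx)) / pi."""
    sa, _ = sici(np.pi * (x - a) / dx)
    sb, _ = sici(np.pi * (x - b) / dx)
    return (sa - sb) / np.pi


def element_aperture_weights(
    transducer: TransducerSpec,
    grid: SimulationGrid,
    truncate: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element weights over the lateral grid line holding the array.

    Returns ``(x_indices, weights)`` with shape (n_elements, n_support):
    for element i, ``weights[i, j]`` applies at lateral grid column
    ``x_indices[i, j]``. Weights sample the band-limited indicator of the
    element's width (so they sum to ~ element_width / spacing) and are
    truncated where |w| < ``truncate`` x peak.

    A zero-width element degenerates to the sinc interpolation kernel of a
    point source, i.e. a single unit sample when the element centre lies on
    a grid node.
    """
    dx = grid.spacing_m
    x_grid = (np.arange(grid.nx) - (grid.nx - 1) / 2) * dx
    x_el = transducer.element_positions_m()
    half = transducer.element_width_um * 1e-6 / 2.0
    if x_el.min() - half < x_grid[0] or x_el.max() + half > x_grid[-1]:
        raise ValueError("array extends outside the grid")

    idx_rows, w_rows = [], []
    n_keep = 0
    for xc in x_el:
        if half > 0:
            w = _bandlimited_rect(x_grid, xc - half, xc + half, dx)
        else:
            w = np.sinc((x_grid - xc) / dx)
        keep = np.abs(w) >= truncate * np.abs(w).max()
        idx_rows.append(np.nonzero(keep)[0])
        w_rows.append(w[keep])
        n_keep = max(n_keep, keep.sum())

    idx = np.zeros((transducer.n_elements, n_keep), dtype=int)
    wts = np.zeros((transducer.n_elements, n_keep), dtype=float)
    for i, (ii, ww) in enumerate(zip(idx_rows, w_rows)):
        idx[i, : ii.size] = ii
        wts[i, : ii.size] = ww
    return idx, wts
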