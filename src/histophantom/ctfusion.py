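"""Multi-layered scenes from CT: HU -> density -> sound speed, density-interval
classing with per-class speckle texture, connective-tissue edges, thyroid
smoothing, annulus warping of artery-wall masks, and embedding of
histology-based phantoms.

The HU-to-density mapping uses the published five-segment piecewise-linear
stoichiometric calibration (Schneider-style); the seam above HU = 100 is
continuity-adjusted so the mapping is monotone non-decreasing. Sound speed
then follows the Mast relation c = (rho + 349) / 0.893 pixel-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datatypes import AcousticPhantom, ComponentMasks
from .properties import MAST_OFFSET, MAST_SLOPE_INV

__all__ = [
    "CTSlice",
    "DensityIntervalTable",
    "DEFAULT_INTERVALS",
    "CONNECTIVE_TISSUE",
    "THYROID",
    "hu_to_density",
    "density_to_sound_speed",
    "classify_and_texture",
    "add_connective_edges",
    "embed_microstructure",
    "annulus_warp",
    "apply_thyroid_region",
]

# connective tissue assigned to Sobel transition edges
CONNECTIVE_TISSUE = {"density": 1026.0, "sound_speed": 1545.0, "alpha0": 1.17}
# thyroid region properties (applied after Gaussian smoothing of the mask)
THYROID = {
    "density": 1050.0,
    "sound_speed": 1500.0,
    "alpha0": 1.2,
    "speckle_intensity": 5e-7,
    "smooth_sigma_um": 2.96,
}


@dataclass
class CTSlice:
    hu: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU grid contains non-finite values")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class DensityIntervalTable:
    """Half-open density intervals [lo, hi) -> tissue class with per-class
    speckle intensity and absorption. The x50 speckle scaling (matching the
    intensity reached by the histology-based phantoms) is applied on
    evaluation."""

    edges: np.ndarray  # (n+1,) increasing densities, kg/m^3
    labels: list[str]
    speckle_intensity: np.ndarray  # unscaled, per class
    alpha0: np.ndarray  # dB/(MHz^y cm), per class
    speckle_scale: float = 50.0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.speckle_intensity = np.asarray(self.speckle_intensity, dtype=float)
        self.alpha0 = np.asarray(self.alpha0, dtype=float)
        n = self.edges.size - 1
        if not (len(self.labels) == self.speckle_intensity.size
                == self.alpha0.size == n):
            raise ValueError("table arrays are inconsistent")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    def classify(self, density: np.ndarray) -> np.ndarray:
        """Class index per pixel; densities outside the table fall back to
        the nearest interval with a warning."""
        idx = np.searchsorted(self.edges, density, side="right") - 1
        below = idx < 0
        above = idx >= len(self.labels)
        if below.any() or above.any():
            warnings.warn("densities outside the interval table; "
                          "nearest class used", stacklevel=2)
        return np.clip(idx, 0, len(self.labels) - 1)


# editable defaults: broad soft-tissue bands (kg/m^3)
DEFAULT_INTERVALS = DensityIntervalTable(
    edges=np.array([0.0, 300.0, 950.0, 1010.0, 1060.0, 1120.0, 3500.0]),
    labels=["air", "fat", "soft-tissue", "muscle", "connective", "bone"],
    speckle_intensity=np.array([0.0, 2.5e-8, 3.0e-8, 4.7e-8, 3.4e-7, 1.0e-7]),
    alpha0=np.array([0.0, 1.1, 0.6, 0.6, 1.17, 5.0]),
)


def hu_to_density(ct: CTSlice, clip_range=(-1024.0, 3000.0)) -> np.ndarray:
    """Piecewise-linear stoichiometric HU -> mass density (kg/m^3)."""
    hu = ct.hu
    lo, hi = clip_range
    if np.any(hu < lo) or np.any(hu > hi):
        warnings.warn("HU outside plausible range clipped", stacklevel=2)
        hu = np.clip(hu, lo, hi)
    # (upper HU bound, intercept, slope) in g/cm^3; the raw published
    # segments dip slightly at two seams, so each segment is floored at the
    # running max of the previous segments' endpoint values
    segments = [
        (-98.0, 1.031, 1.031e-3),
        (14.0, 1.018, 0.893e-3),
        (23.0, 1.030, 0.0),
        (100.0, 1.003, 1.169e-3),
        (np.inf, 1.017, 0.592e-3),
    ]
    rho = np.empty_like(hu)
    floor = -np.inf
    lower = -np.inf
    for upper, intercept, slope in segments:
        sel = (hu > lower) & (hu <= upper)
        rho[sel] = np.maximum(intercept + slope * hu[sel], floor)
        if np.isfinite(upper):
            floor = max(floor, intercept + slope * upper)
        lower = upper
    rho = np.maximum(rho, 1.2e-3)  # air floor
    return rho * 1000.0


def density_to_sound_speed(density: np.ndarray) -> np.ndarray:
    """Mast relation pixel-wise: c = (rho + 349) / 0.893 (m/s)."""
    rho = np.asarray(density, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    return (rho + MAST_OFFSET) / MAST_SLOPE_INV


def classify_and_texture(
    density: np.ndarray,
    table: DensityIntervalTable = DEFAULT_INTERVALS,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-pixel tissue class, speckle-intensity grid (x50 scaled), and
    absorption grid; a baseline-style relative density perturbation of the
    class's (scaled) speckle intensity is added to the density."""
    if rng is None:
        rng = np.random.default_rng(0)
    labels = table.classify(density)
    intensity = table.speckle_intensity[labels] * table.speckle_scale
    alpha = table.alpha0[labels]
    eps = rng.standard_normal(density.shape)
    textured = density * (1.0 + np.sqrt(intensity) * eps)
    textured = np.clip(textured, 1e-3, None)
    return {
        "labels": labels,
        "legend": dict(enumerate(table.labels)),
        "speckle_intensity": intensity,
        "absorption": alpha,
        "density": textured,
    }


def add_connective_edges(
    density: np.ndarray,
    sound_speed: np.ndarray,
    absorption: np.ndarray,
    threshold: float,
    source: np.ndarray | None = None,
    dilate_px: int = 0,
) -> dict:
    """Assign connective-tissue properties along Sobel transition edges.

    ``source`` (default: the density grid itself, e.g. a speckle-power
    map) is Sobel-filtered; pixels whose gradient magnitude exceeds
    ``threshold`` become a one-pixel edge band (optionally dilated) set to
    (1026 kg/m^3, 1545 m/s, 1.17 dB/(MHz cm)).
    """
    src = density if source is None else source
    gz = ndimage.sobel(src, axis=0, mode="nearest")
    gx = ndimage.sobel(src, axis=1, mode="nearest")
    mag = np.hypot(gz, gx)
    edges = mag > threshold
    if dilate_px > 0:
        edges = ndimage.binary_dilation(edges, iterations=dilate_px)
    density = density.copy()
    sound_speed = sound_speed.copy()
    absorption = absorption.copy()
    density[edges] = CONNECTIVE_TISSUE["density"]
    sound_speed[edges] = CONNECTIVE_TISSUE["sound_speed"]
    absorption[edges] = CONNECTIVE_TISSUE["alpha0"]
    return {
        "density": density,
        "sound_speed": sound_speed,
        "absorption": absorption,
        "edges": edges,
    }


def apply_thyroid_region(
    density: np.ndarray,
    sound_speed: np.ndarray,
    absorption: np.ndarray,
    thyroid_mask: np.ndarray,
    spacing_um: float,
    rng: np.random.Generator | None = None,
) -> dict:
    """Smooth the delineated thyroid mask with a Gaussian (sigma = 2.96 um)
    and assign the thyroid property set inside, with its speckle-intensity
    density perturbation."""
    if rng is None:
        rng = np.random.default_rng(0)
    sigma_px = THYROID["smooth_sigma_um"] / spacing_um
    smooth = ndimage.gaussian_filter(thyroid_mask.astype(float), sigma_px)
    inside = smooth >= 0.5
    density = density.copy()
    sound_speed = sound_speed.copy()
    absorption = absorption.copy()
    eps = rng.standard_normal(density.shape)
    rho_t = THYROID["density"] * (
        1.0 + np.sqrt(THYROID["speckle_intensity"]) * eps
    )
    density[inside] = rho_t[inside]
    sound_speed[inside] = THYROID["sound_speed"]
    absorption[inside] = THYROID["alpha0"]
    return {
        "density": density,
        "sound_speed": sound_speed,
        "absorption": absorption,
        "mask": inside,
    }


def _tile_to_cover(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Mirror-tile an array out to at least ``shape`` then crop (substitute
    for manual texture extension)."""
    out = arr
    while out.shape[0] < shape[0]:
        out = np.concatenate([out, out[::-1]], axis=0)
    while out.shape[1] < shape[1]:
        out = np.concatenate([out, out[:, ::-1]], axis=1)
    return out[: shape[0], : shape[1]]


def embed_microstructure(
    scene_density: np.ndarray,
    scene_sound_speed: np.ndarray,
    phantom: AcousticPhantom,
    region_mask: np.ndarray,
    mu_scale: float,
    rho_global: float,
    c_global: float,
) -> dict:
    """Embed a histology-based phantom inside a scene region.

    Within the region the phantom's deviations from the tissue globals are
    rescaled by ``mu_scale`` (e.g. 0.5 for adipose fat and muscle) and
    written over the scene; the phantom is mirror-tiled if it does not
    cover the region. Outside the region the scene is untouched.
    """
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty embedding region")
    rows = np.any(region, axis=1).nonzero()[0]
    cols = np.any(region, axis=0).nonzero()[0]
    bbox = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    h = bbox[0].stop - bbox[0].start
    w = bbox[1].stop - bbox[1].start
    rho_tile = _tile_to_cover(phantom.density, (h, w))
    c_tile = _tile_to_cover(phantom.sound_speed, (h, w))

    rho_new = rho_global + mu_scale * (rho_tile - rho_global)
    c_new = c_global + mu_scale * (c_tile - c_global)

    density = scene_density.copy()
    sound_speed = scene_sound_speed.copy()
    sub = region[bbox]
    density[bbox][sub] = rho_new[sub]
    sound_speed[bbox][sub] = c_new[sub]
    return {"density": density, "sound_speed": sound_speed}


def annulus_warp(
    masks: ComponentMasks,
    inner_radius_mm: float = 2.5,
    center: tuple[int, int] | None = None,
    out_shape: tuple[int, int] | None = None,
) -> ComponentMasks:
    """Warp a rectangular artery-wall strip onto an annulus.

    The strip's lateral axis maps to angle and its depth axis to radius
    measured outward from ``inner_radius_mm``; sampling is nearest
    neighbour so mask exclusivity is preserved. Pixels inside the lumen
    and outside the outer radius are background.
    """
    res_m = masks.resolution_um * 1e-6
    h, w = masks.shape
    r_in = inner_radius_mm * 1e-3
    r_out = r_in + h * res_m
    n_out = out_shape[0] if out_shape else int(np.ceil(2 * r_out / res_m)) + 1
    if out_shape is None:
        out_shape = (n_out, n_out)
    if center is None:
        center = (out_shape[0] // 2, out_shape[1] // 2)
    cz, cx = center

    zz = (np.arange(out_shape[0]) - cz) * res_m
    xx = (np.arange(out_shape[1]) - cx) * res_m
    Z, X = np.meshgrid(zz, xx, indexing="ij")
    R = np.hypot(Z, X)
    TH = np.arctan2(X, -Z)  # angle 0 at the top, increasing clockwise

    inside = (R >= r_in) & (R < r_out)
    # radius -> strip row; angle -> strip column (wrap), arc-length scaled
    # at the inner radius so the wall thickness is preserved
    rows = np.clip(((R - r_in) / res_m).astype(int), 0, h - 1)
    cols = ((TH + np.pi) / (2 * np.pi) * w).astype(int) % w

    def _warp(mask):
        out = np.zeros(out_shape, dtype=bool)
        out[inside] = mask[rows[inside], cols[inside]]
        return out

    collagen = _warp(masks.collagen)
    cell = _warp(masks.cell)
    background = ~(collagen | cell)
    return ComponentMasks(collagen, cell, background, masks.resolution_um)
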