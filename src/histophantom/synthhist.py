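"""Seeded synthetic histology slides with exact ground-truth masks.

Emulates picrosirius-red stained sections: collagen-rich tissue renders
red, cytoplasm / muscle fibres yellow, and nuclei as sparse gray-brown
dots. Four microanatomies are modeled:

* fat — Voronoi-tessellated adipocytes (yellow interiors) with thin red
  collagen borders and an optional fascia band;
* muscle — elongated fascicles at a configurable fibre orientation,
  separated by red perimysium lines;
* artery — intima / media / adventitia layers with circumferential fibre
  texture in the media;
* skin — epidermis and dermis strata stacked over a fat (hypodermis)
  recipe.

The returned masks are the generator's own geometry, so they are exact and
exclusive/exhaustive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import ComponentMasks, HistologyImage

__all__ = ["MicrostructureRecipe", "generate_slide"]

# stain palette (RGB, uint8)
_COLLAGEN_RGB = np.array([178, 34, 52], dtype=float)
_CELL_RGB = np.array([228, 196, 90], dtype=float)
_NUCLEUS_RGB = np.array([96, 78, 70], dtype=float)
_BACKGROUND_RGB = np.array([242, 240, 238], dtype=float)


@dataclass
class MicrostructureRecipe:
    """Geometry knobs for one synthetic slide (lengths in micrometres)."""

    tissue_label: str = "fat"
    cell_diameter_um: float = 80.0
    cell_diameter_sd_um: float = 10.0
    border_thickness_um: float = 4.0
    orientation_deg: float = 0.0
    fascia_position: float | None = None  # fractional depth of fascia band
    fascia_thickness_um: float = 20.0
    layer_fractions: tuple[float, ...] = field(default_factory=tuple)
    nucleus_density: float = 2e-5  # nuclei per um^2 of cell area
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_diameter_um <= 0 or self.border_thickness_um <= 0:
            raise ValueError("diameters and thicknesses must be > 0")


def _smooth_profile(rng: np.random.Generator, amplitude: float, scale_um: float):
    """Random band-limited 1-D profile f(u_um), periodic-free, seeded."""
    # cosine modes only (even in u), so mirrored coordinates give the same
    # wobble and a 0/90-degree slide pair is an exact transpose
    n_modes = 6
    freqs = rng.uniform(0.2, 1.0, n_modes) / scale_um
    amps = amplitude * rng.uniform(0.3, 1.0, n_modes) / np.sqrt(n_modes)

    def f(u_um: np.ndarray) -> np.ndarray:
        out = np.zeros_like(u_um, dtype=float)
        for a, fr in zip(amps, freqs):
            out += a * np.cos(2 * np.pi * fr * u_um)
        return out

    return f


def _voronoi_fat(
    recipe: MicrostructureRecipe,
    shape: tuple[int, int],
    resolution_um: float,
    rng: np.random.Generator,
):
    """Collagen border mask of a Voronoi adipocyte tessellation, plus the
    generating sites (um coordinates) for geometric oracles."""
    h, w = shape
    h_um, w_um = h * resolution_um, w * resolution_um
    cell_area = np.pi * (recipe.cell_diameter_um / 2) ** 2
    n_sites = max(int(round(h_um * w_um / cell_area)), 1)
    if min(h_um, w_um) < recipe.cell_diameter_um / 2:
        raise ValueError("slide too small for a single cell")
    sites = rng.uniform([0, 0], [h_um, w_um], size=(n_sites, 2))
    tree = cKDTree(sites)
    zz = (np.arange(h) + 0.5) * resolution_um
    xx = (np.arange(w) + 0.5) * resolution_um
    pts = np.stack(np.meshgrid(zz, xx, indexing="ij"), axis=-1).reshape(-1, 2)
    dist, idx = tree.query(pts, k=2)
    # exact perpendicular distance to the bisector between the two nearest
    # sites: (d2^2 - d1^2) / (2 |s2 - s1|), giving a band of width t
    gap = np.linalg.norm(sites[idx[:, 1]] - sites[idx[:, 0]], axis=1)
    e = (dist[:, 1] ** 2 - dist[:, 0] ** 2) / (2.0 * np.maximum(gap, 1e-9))
    border = e < recipe.border_thickness_um / 2.0
    return border.reshape(h, w), sites


def _nuclei(rng, cell_mask, shape, resolution_um, density):
    h, w = shape
    area_um2 = cell_mask.sum() * resolution_um**2
    n = rng.poisson(density * area_um2)
    nuc = np.zeros(shape, dtype=bool)
    if n == 0:
        return nuc
    zi = rng.integers(0, h, n)
    xi = rng.integers(0, w, n)
    r_px = max(int(round(3.0 / resolution_um)), 1)  # ~6 um nuclei
    zz, xx = np.ogrid[-r_px : r_px + 1, -r_px : r_px + 1]
    disk = zz**2 + xx**2 <= r_px**2
    for z, x in zip(zi, xi):
        if not cell_mask[z, x]:
            continue
        z0, z1 = max(z - r_px, 0), min(z + r_px + 1, h)
        x0, x1 = max(x - r_px, 0), min(x + r_px + 1, w)
        nuc[z0:z1, x0:x1] |= disk[
            z0 - (z - r_px) : disk.shape[0] - ((z + r_px + 1) - z1),
            x0 - (x - r_px) : disk.shape[1] - ((x + r_px + 1) - x1),
        ]
    return nuc & cell_mask


def _banded_collagen(
    shape,
    resolution_um,
    period_um,
    thickness_um,
    orientation_deg,
    rng,
    wobble_amplitude_um,
):
    """Collagen lines perpendicular to the band-normal axis; the fibre axis
    is at ``orientation_deg`` from the lateral (x) axis. Wobble varies along
    the fibre axis so a 0 vs 90 degree pair is an exact transpose."""
    h, w = shape
    zz = (np.arange(h) + 0.5) * resolution_um
    xx = (np.arange(w) + 0.5) * resolution_um
    Z, X = np.meshgrid(zz, xx, indexing="ij")
    th = np.deg2rad(orientation_deg)
    # u: along-fibre coordinate, v: across-fibre coordinate (v = Z at 0 deg,
    # v = X at 90 deg, making the two slides exact transposes)
    u = X * np.cos(th) - Z * np.sin(th)
    v = X * np.sin(th) + Z * np.cos(th)
    wob = _smooth_profile(rng, wobble_amplitude_um, period_um * 6)
    phase = (v + wob(u)) % period_um
    d = np.minimum(phase, period_um - phase)
    return d < thickness_um / 2


def generate_slide(
    recipe: MicrostructureRecipe,
    size_px: tuple[int, int] | int = 2048,
    resolution_um: float = 0.43,
) -> tuple[HistologyImage, ComponentMasks]:
    """Render one synthetic slide and its exact component masks."""
    if isinstance(size_px, int):
        shape = (size_px, size_px)
    else:
        shape = tuple(size_px)
    rng = np.random.default_rng(recipe.rng_seed)
    label = recipe.tissue_label

    if label == "fat":
        collagen = _fat_collagen(recipe, shape, resolution_um, rng)
        background = np.zeros(shape, dtype=bool)
    elif label == "muscle":
        collagen = _banded_collagen(
            shape,
            resolution_um,
            period_um=recipe.cell_diameter_um,
            thickness_um=recipe.border_thickness_um,
            orientation_deg=recipe.orientation_deg,
            rng=rng,
            wobble_amplitude_um=recipe.cell_diameter_um * 0.15,
        )
        background = np.zeros(shape, dtype=bool)
    elif label == "artery":
        collagen, background = _artery_collagen(recipe, shape, resolution_um, rng)
    elif label == "skin":
        collagen, background = _skin_collagen(recipe, shape, resolution_um, rng)
    else:
        raise ValueError(f"unknown tissue_label {label!r}")

    cell = ~collagen & ~background
    masks = ComponentMasks(collagen, cell, background, resolution_um)
    masks.validate_partition()

    nuclei = _nuclei(rng, cell, shape, resolution_um, recipe.nucleus_density)
    img = np.empty((*shape, 3), dtype=float)
    img[background] = _BACKGROUND_RGB
    img[cell] = _CELL_RGB
    img[collagen] = _COLLAGEN_RGB
    img[nuclei] = _NUCLEUS_RGB
    img += rng.normal(0, 4.0, img.shape)  # stain / sensor noise
    img = np.clip(img, 0, 255).astype(np.uint8)
    return HistologyImage(img, resolution_um, label), masks


def _fat_collagen(recipe, shape, resolution_um, rng):
    border, _ = _voronoi_fat(recipe, shape, resolution_um, rng)
    if recipe.fascia_position is not None:
        h = shape[0]
        z0 = int(recipe.fascia_position * h)
        t_px = max(int(round(recipe.fascia_thickness_um / resolution_um)), 1)
        border = border.copy()
        border[z0 : z0 + t_px, :] = True
    return border


def _artery_collagen(recipe, shape, resolution_um, rng):
    """Intima (thin, collagen), media (circumferential fibre texture),
    adventitia (collagen-rich blobs). Layers stacked along depth; lumen
    (background) above the wall."""
    h, w = shape
    fr = recipe.layer_fractions or (0.1, 0.08, 0.42, 0.4)  # lumen/int/med/adv
    edges = np.cumsum(np.asarray(fr) / np.sum(fr)) * h
    lum_e, int_e, med_e = (int(e) for e in edges[:3])
    background = np.zeros(shape, dtype=bool)
    background[:lum_e] = True
    collagen = np.zeros(shape, dtype=bool)
    collagen[lum_e:int_e] = True  # intima: collagen-dense thin rim
    media = _banded_collagen(
        (med_e - int_e, w),
        resolution_um,
        period_um=recipe.cell_diameter_um * 0.4,
        thickness_um=recipe.border_thickness_um,
        orientation_deg=0.0,
        rng=rng,
        wobble_amplitude_um=recipe.cell_diameter_um * 0.05,
    )
    collagen[int_e:med_e] = media
    # adventitia: dense wavy collagen bundles
    adv = _banded_collagen(
        (h - med_e, w),
        resolution_um,
        period_um=recipe.cell_diameter_um * 0.6,
        thickness_um=recipe.cell_diameter_um * 0.3,
        orientation_deg=0.0,
        rng=rng,
        wobble_amplitude_um=recipe.cell_diameter_um * 0.2,
    )
    collagen[med_e:] = adv
    collagen &= ~background
    return collagen, background


def _skin_collagen(recipe, shape, resolution_um, rng):
    """Epidermis (cell-dense), dermis (collagen-rich), hypodermis (fat)."""
    h, w = shape
    fr = recipe.layer_fractions or (0.08, 0.35, 0.57)  # epi/dermis/hypo
    edges = np.cumsum(np.asarray(fr) / np.sum(fr)) * h
    epi_e, der_e = int(edges[0]), int(edges[1])
    collagen = np.zeros(shape, dtype=bool)
    dermis = _banded_collagen(
        (der_e - epi_e, w),
        resolution_um,
        period_um=recipe.cell_diameter_um * 0.5,
        thickness_um=recipe.cell_diameter_um * 0.2,
        orientation_deg=0.0,
        rng=rng,
        wobble_amplitude_um=recipe.cell_diameter_um * 0.25,
    )
    collagen[epi_e:der_e] = dermis
    hypo_shape = (h - der_e, w)
    if min(hypo_shape) * resolution_um > recipe.cell_diameter_um:
        hypo, _ = _voronoi_fat(recipe, hypo_shape, resolution_um, rng)
        collagen[der_e:] = hypo
    background = np.zeros(shape, dtype=bool)
    return collagen, background
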