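"""Acoustic phantom construction from component masks and tissue properties.

A phantom carries co-registered density, sound-speed and absorption grids.
Density inside a microstructural component is the tissue's global density
scaled by that component's heterogeneity multiplier mu; the component's
sound speed follows the Mast density/sound-speed relation, applied as an
offset from the tissue's global speed so the background retains the
literature value. The isotropic baseline phantom replaces structure with an
i.i.d. Gaussian relative-density perturbation ("speckle intensity").
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    AcousticPhantom,
    BaselineSpec,
    ComponentMasks,
    TissueProperties,
)
from .properties import WATER, mast_sound_speed

__all__ = [
    "build_density_map",
    "build_sound_speed_map",
    "assemble_phantom",
    "build_baseline_phantom",
    "layered_skin_phantom",
]

# realized IQR of a standard normal sample (Phi^-1(.75) - Phi^-1(.25))
_NORMAL_IQR = 1.3489795003921634


def build_density_map(masks: ComponentMasks, props: TissueProperties) -> np.ndarray:
    """Spatial density: rho_global on background, rho_global * mu inside
    each microstructural component."""
    masks.validate_partition()
    rho = np.full(masks.shape, props.rho_global, dtype=float)
    rho[masks.collagen] = props.rho_global * props.mu_collagen
    rho[masks.cell] = props.rho_global * props.mu_cell
    return rho


def build_sound_speed_map(masks: ComponentMasks, props: TissueProperties) -> np.ndarray:
    """Sound speed: c_global on background; inside a component the Mast
    local speed replaces it via the offset construction
    c_global + (c_local - c_global)."""
    masks.validate_partition()
    c = np.full(masks.shape, props.c_global, dtype=float)
    c_col = mast_sound_speed(props.rho_global, props.mu_collagen)
    c_cel = mast_sound_speed(props.rho_global, props.mu_cell)
    c[masks.collagen] = props.c_global + (c_col - props.c_global)
    c[masks.cell] = props.c_global + (c_cel - props.c_global)
    return c


def assemble_phantom(
    masks: ComponentMasks,
    props: TissueProperties,
    domain_shape: tuple[int, int] | None = None,
    spacing_um: float | None = None,
    placement: tuple[int, int] = (0, 0),
    surrounding: TissueProperties = WATER,
) -> AcousticPhantom:
    """Embed a tissue's component masks in a (water-filled) domain.

    The tissue occupies ``masks.shape`` at ``placement`` (row, col offset);
    everything outside is the surrounding medium. Absorption is uniform per
    tissue and the power-law exponent y = 1.1 everywhere.
    """
    spacing = spacing_um if spacing_um is not None else masks.resolution_um
    if domain_shape is None:
        domain_shape = masks.shape
    r0, c0 = placement
    h, w = masks.shape
    if r0 < 0 or c0 < 0 or r0 + h > domain_shape[0] or c0 + w > domain_shape[1]:
        raise ValueError("masks do not fit within the domain at this placement")

    density = np.full(domain_shape, surrounding.rho_global, dtype=float)
    sound_speed = np.full(domain_shape, surrounding.c_global, dtype=float)
    absorption = np.full(domain_shape, surrounding.alpha0, dtype=float)

    sl = (slice(r0, r0 + h), slice(c0, c0 + w))
    density[sl] = build_density_map(masks, props)
    sound_speed[sl] = build_sound_speed_map(masks, props)
    absorption[sl] = props.alpha0
    return AcousticPhantom(
        density=density,
        sound_speed=sound_speed,
        absorption=absorption,
        y=props.y,
        spacing_um=spacing,
    )


def layered_skin_phantom(
    skin_masks: ComponentMasks,
    fat_masks: ComponentMasks,
    skin_props: TissueProperties,
    fat_props: TissueProperties,
    epidermis_dermis_rows: int,
    domain_shape: tuple[int, int] | None = None,
    placement: tuple[int, int] = (0, 0),
    surrounding: TissueProperties = WATER,
) -> AcousticPhantom:
    """Multilayered skin: the top ``epidermis_dermis_rows`` of the tissue
    block use the skin parameters, the hypodermis below uses the adipose
    fat parameters (subcutaneous fat). Both mask sets must share shape and
    resolution; the boundary is horizontal."""
    if skin_masks.shape != fat_masks.shape:
        raise ValueError("skin and fat masks must share a shape")
    top = assemble_phantom(skin_masks, skin_props, domain_shape, None, placement,
                           surrounding)
    bottom = assemble_phantom(fat_masks, fat_props, domain_shape, None, placement,
                              surrounding)
    split = placement[0] + int(epidermis_dermis_rows)
    density = top.density.copy()
    c = top.sound_speed.copy()
    a = top.absorption.copy()
    density[split:], c[split:], a[split:] = (
        bottom.density[split:],
        bottom.sound_speed[split:],
        bottom.absorption[split:],
    )
    return AcousticPhantom(density, c, a, skin_props.y, top.spacing_um)


def build_baseline_phantom(
    props: TissueProperties,
    domain_shape: tuple[int, int],
    spec: BaselineSpec,
    spacing_um: float,
) -> AcousticPhantom:
    """Isotropic structure-free speckle phantom.

    density = rho_global * (1 + eps) with eps i.i.d. N(0, speckle_intensity).
    If ``spec.target_density_iqr`` is given the perturbation is instead
    scaled so the realized density IQR matches it. Sound speed follows the
    Mast relation pixel-wise, applied as an offset about the global speed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    eps = rng.standard_normal(domain_shape)
    if spec.target_density_iqr is not None:
        # N(0,1) IQR is 1.3490; scale so rho_global * scale * IQR(eps) hits
        # the target on this realization
        realized = np.subtract(*np.percentile(eps, [75, 25]))
        scale = (
            spec.target_density_iqr / (props.rho_global * realized)
            if realized > 0
            else 0.0
        )
    else:
        scale = np.sqrt(spec.speckle_intensity)
    density = props.rho_global * (1.0 + scale * eps)
    if np.any(density <= 0):
        warnings.warn("non-positive densities clipped in baseline phantom",
                      stacklevel=2)
        density = np.clip(density, 1e-3 * props.rho_global, None)
    sound_speed = props.c_global + (
        mast_sound_speed(density) - mast_sound_speed(props.rho_global)
    )
    absorption = np.full(domain_shape, props.alpha0, dtype=float)
    return AcousticPhantom(density, sound_speed, absorption, props.y, spacing_um)
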