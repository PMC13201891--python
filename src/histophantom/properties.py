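"""Tissue acoustic property presets and the Mast density/sound-speed relation.

Global properties (density, sound speed, absorption) are literature-derived
per tissue; local heterogeneity multipliers (mu) and baseline speckle
intensities are the estimated per-component values. Water is the coupling /
surrounding medium. The power-law absorption exponent y = 1.1 throughout.
"""

from __future__ import annotations

import numpy as np

from .datatypes import TissueProperties

__all__ = [
    "MAST_OFFSET",
    "MAST_SLOPE_INV",
    "mast_sound_speed",
    "WATER",
    "TISSUE_TABLE",
    "get_tissue",
]

# c = (rho + 349) / 0.893 — empirical linear soft-tissue relation (Mast)
MAST_OFFSET = 349.0
MAST_SLOPE_INV = 0.893


def mast_sound_speed(rho_global: float | np.ndarray, mu: float | np.ndarray = 1.0):
    """Local sound speed (m/s) from global density (kg/m^3) and heterogeneity.

    Implements c_local = (rho_global * mu + 349) / 0.893.
    """
    rho = np.asarray(rho_global, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    out = (rho * mu + MAST_OFFSET) / MAST_SLOPE_INV
    return float(out) if out.ndim == 0 else out


WATER = TissueProperties(
    name="water", rho_global=1000.0, c_global=1480.0, alpha0=2.2e-3, y=1.1
)

# Per-tissue globals + estimated component heterogeneity and the speckle
# intensity used by the isotropic baseline phantoms.
TISSUE_TABLE: dict[str, TissueProperties] = {
    "artery": TissueProperties(
        name="artery",
        rho_global=1085.0,
        c_global=1565.0,
        alpha0=0.6,
        mu_collagen=1.05,
        mu_cell=1.035,
        speckle_intensity=2.70e-8,
    ),
    "fat": TissueProperties(
        name="fat",
        rho_global=911.0,
        c_global=1440.0,
        alpha0=1.1,  # empirically derived
        mu_collagen=1.14,
        mu_cell=1.035,
        speckle_intensity=2.49e-8,
    ),
    "muscle": TissueProperties(
        name="muscle",
        rho_global=1085.0,
        c_global=1585.0,
        alpha0=0.6,
        mu_collagen=1.07,
        mu_cell=1.005,
        speckle_intensity=4.73e-8,
    ),
    "skin": TissueProperties(
        name="skin",
        rho_global=1100.0,
        c_global=1600.0,
        alpha0=0.8,
        mu_collagen=1.15,
        mu_cell=1.020,
        speckle_intensity=3.40e-7,
    ),
    "water": WATER,
}


def get_tissue(name: str, **overrides) -> TissueProperties:
    """Fetch a tissue preset, optionally overriding fields."""
    try:
        base = TISSUE_TABLE[name]
    except KeyError as exc:
        raise KeyError(
            f"unknown tissue {name!r}; choose from {sorted(TISSUE_TABLE)}"
        ) from exc
    if not overrides:
        return base
    from dataclasses import replace

    return replace(base, **overrides)
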