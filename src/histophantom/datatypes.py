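"""Core containers shared across the phantom/simulation/metrics pipeline.

Coordinate convention (repo-wide): axis 0 = axial (z, increasing with
depth), axis 1 = lateral (x); 0-based indices; values live at pixel
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HistologyImage",
    "SegmentationConfig",
    "ComponentMasks",
    "TissueProperties",
    "AcousticPhantom",
    "BaselineSpec",
    "TransducerSpec",
    "PulseSpec",
    "PlaneWavePlan",
    "SimulationGrid",
    "RFChannelData",
    "BeamformedImage",
]


@dataclass
class HistologyImage:
    """An RGB histology raster with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        RGB values, either uint8 in [0, 255] or float in [0, 1].
    resolution_um : float
        Pixel size in micrometres per pixel (isotropic).
    tissue_label : str
        One of ``fat``, ``artery``, ``muscle``, ``skin``.
    """

    pixels: np.ndarray
    resolution_um: float
    tissue_label: str = "fat"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("histology image must be an (H, W, 3) RGB raster")
        if self.pixels.size == 0:
            raise ValueError("histology image is empty")
        if not self.resolution_um > 0:
            raise ValueError("resolution_um must be > 0")


@dataclass
class SegmentationConfig:
    """Clustering and morphology settings for component segmentation.

    ``collagen_cluster_ids`` / ``cell_cluster_ids`` select which k-means
    clusters are merged into each component; leave both empty to use the
    automatic chromaticity-based assignment (reddest cluster -> collagen,
    yellowest -> cells, lightest -> background).
    """

    n_clusters: int = 4
    collagen_cluster_ids: tuple[int, ...] = ()
    cell_cluster_ids: tuple[int, ...] = ()
    opening_radius_um: float = 2.0
    closing_radius_um: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        col = set(self.collagen_cluster_ids)
        cel = set(self.cell_cluster_ids)
        if col & cel:
            raise ValueError("collagen and cell cluster id sets must be disjoint")
        ids = col | cel
        if ids and not ids <= set(range(self.n_clusters)):
            raise ValueError("cluster ids must lie in [0, n_clusters)")
        if self.opening_radius_um < 0 or self.closing_radius_um < 0:
            raise ValueError("morphology radii must be >= 0")


@dataclass
class ComponentMasks:
    """Mutually exclusive, jointly exhaustive binary component maps.

    ``microstructure`` (collagen | cell) and ``background`` are the two
    spatial indicator maps the density construction uses.
    """

    collagen: np.ndarray
    cell: np.ndarray
    background: np.ndarray
    resolution_um: float

    def __post_init__(self) -> None:
        self.collagen = np.asarray(self.collagen, dtype=bool)
        self.cell = np.asarray(self.cell, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if not (self.collagen.shape == self.cell.shape == self.background.shape):
            raise ValueError("component masks must share a shape")
        if not self.resolution_um > 0:
            raise ValueError("resolution_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.collagen.shape

    @property
    def microstructure(self) -> np.ndarray:
        return self.collagen | self.cell

    def validate_partition(self, strict: bool = True) -> bool:
        total = (
            self.collagen.astype(np.uint8)
            + self.cell.astype(np.uint8)
            + self.background.astype(np.uint8)
        )
        ok = bool(np.all(total == 1))
        if strict and not ok:
            raise ValueError("masks are not a partition of the pixel grid")
        return ok


@dataclass
class TissueProperties:
    """Global acoustic properties of one tissue plus component heterogeneity.

    ``alpha0`` is the power-law absorption prefactor in dB/(MHz^y cm);
    ``mu_collagen`` / ``mu_cell`` are the unitless local heterogeneity
    multipliers applied to the global density inside each component.
    """

    name: str
    rho_global: float
    c_global: float
    alpha0: float
    y: float = 1.1
    mu_collagen: float = 1.0
    mu_cell: float = 1.0
    speckle_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_global <= 0 or self.c_global <= 0:
            raise ValueError("global density and sound speed must be positive")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")
        if self.mu_collagen <= 0 or self.mu_cell <= 0:
            raise ValueError("heterogeneity multipliers must be > 0")


@dataclass
class AcousticPhantom:
    """Co-registered density / sound-speed / absorption grids."""

    density: np.ndarray  # kg/m^3
    sound_speed: np.ndarray  # m/s
    absorption: np.ndarray  # dB/(MHz^y cm)
    y: float
    spacing_um: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.sound_speed = np.asarray(self.sound_speed, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if not (
            self.density.shape == self.sound_speed.shape == self.absorption.shape
        ):
            raise ValueError("phantom grids must share a shape")
        for g, name in ((self.density, "density"), (self.sound_speed, "sound_speed")):
            if not np.all(np.isfinite(g)):
                raise ValueError(f"{name} contains non-finite values")
            if not np.all(g > 0):
                raise ValueError(f"{name} must be strictly positive")
        if not np.all(np.isfinite(self.absorption)):
            raise ValueError("absorption contains non-finite values")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape


@dataclass
class BaselineSpec:
    """Isotropic (structure-free) speckle phantom settings.

    ``speckle_intensity`` is interpreted as the variance of the relative
    density perturbation; alternatively a target density IQR (kg/m^3) may
    be given, in which case the perturbation is scaled to realize it.
    """

    speckle_intensity: float = 0.0
    target_density_iqr: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_intensity < 0:
            raise ValueError("speckle_intensity must be >= 0")
        if self.target_density_iqr is not None and self.target_density_iqr < 0:
            raise ValueError("target_density_iqr must be >= 0")


@dataclass
class TransducerSpec:
    """Linear-array geometry (all lengths in micrometres)."""

    name: str
    n_elements: int
    pitch_um: float
    element_width_um: float
    center_frequency_hz: float

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.element_width_um > self.pitch_um:
            raise ValueError("element width cannot exceed pitch")
        if self.center_frequency_hz <= 0:
            raise ValueError("center frequency must be positive")

    @property
    def aperture_um(self) -> float:
        return (self.n_elements - 1) * self.pitch_um + self.element_width_um

    def element_positions_m(self) -> np.ndarray:
        """Lateral element-center positions (m), array centred on x = 0."""
        x = (np.arange(self.n_elements) - (self.n_elements - 1) / 2) * self.pitch_um
        return x * 1e-6


@dataclass
class PulseSpec:
    """Transmit pulse: Gaussian-enveloped toneburst."""

    center_frequency_hz: float
    fractional_bandwidth: float = 0.65
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional bandwidth must be in (0, 2)")

    @property
    def sigma_t(self) -> float:
        """Envelope std dev (s): -6 dB two-sided spectral width = bw * f0."""
        sigma_f = self.fractional_bandwidth * self.center_frequency_hz / (
            2.0 * np.sqrt(2.0 * np.log(2.0))
        )
        return 1.0 / (2.0 * np.pi * sigma_f)

    @property
    def duration(self) -> float:
        """Support used when sampling: +/- 4 sigma about the centre."""
        return 8.0 * self.sigma_t

    def sample(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate the pulse at times ``t`` (s); centred at duration/2."""
        tc = np.asarray(t, dtype=float) - self.duration / 2.0
        return (
            self.amplitude
            * np.exp(-0.5 * (tc / self.sigma_t) ** 2)
            * np.sin(2 * np.pi * self.center_frequency_hz * tc)
        )

    def waveform(self, dt: float) -> np.ndarray:
        n = int(np.ceil(self.duration / dt)) + 1
        return self.sample(np.arange(n) * dt)


@dataclass
class PlaneWavePlan:
    """Steering plan for unfocused plane-wave transmissions."""

    angles_deg: np.ndarray
    reference_c: float = 1540.0

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))

    @classmethod
    def compounding(
        cls, n_angles: int, max_angle_deg: float, reference_c: float = 1540.0
    ) -> "PlaneWavePlan":
        return cls(
            np.linspace(-max_angle_deg, max_angle_deg, n_angles), reference_c
        )

    def element_delays(self, transducer: TransducerSpec) -> np.ndarray:
        """Per-angle, per-element transmit delays (s), min delay = 0."""
        x = transducer.element_positions_m()
        delays = (
            x[None, :] * np.sin(np.deg2rad(self.angles_deg))[:, None]
        ) / self.reference_c
        return delays - delays.min(axis=1, keepdims=True)


@dataclass
class SimulationGrid:
    """Uniform computational grid for the pseudospectral solver."""

    nz: int
    nx: int
    spacing_um: float
    dt: float
    n_steps: int
    pml_thickness: int = 20
    cfl: float = 0.3

    def __post_init__(self) -> None:
        if self.nz <= 2 * self.pml_thickness or self.nx <= 2 * self.pml_thickness:
            raise ValueError("grid smaller than its PML")
        if self.dt <= 0 or self.spacing_um <= 0:
            raise ValueError("dt and spacing must be positive")

    @property
    def spacing_m(self) -> float:
        return self.spacing_um * 1e-6

    @property
    def interior(self) -> tuple[slice, slice]:
        p = self.pml_thickness
        return slice(p, self.nz - p), slice(p, self.nx - p)


@dataclass
class RFChannelData:
    """Received RF: (time, element, angle) with sampling metadata."""

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:
            self.samples = self.samples[:, :, None]
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF contains non-finite samples")
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))


@dataclass
class BeamformedImage:
    """Envelope / B-mode reconstruction on a regular image grid."""

    envelope: np.ndarray
    grid_spacing_um: float
    reconstruction_c: float
    z0_m: float = 0.0
    x0_m: float = 0.0
    bmode_db: np.ndarray | None = None
    dynamic_range_db: float = 60.0

    def pixel_coords_m(self) -> tuple[np.ndarray, np.ndarray]:
        """(z, x) centre coordinates of the image grid, in metres."""
        dz = self.grid_spacing_um * 1e-6
        nz, nx = self.envelope.shape
        return self.z0_m + np.arange(nz) * dz, self.x0_m + np.arange(nx) * dz

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")
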