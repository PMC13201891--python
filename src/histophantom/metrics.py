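"""Speckle realism metrics.

First-order statistics: histograms of 99th-percentile-normalized envelope
data with a fixed bin width (0.03, chosen by the Freedman-Diaconis rule at
the minimum ROI of 25 x 25 wavelengths) compared with the Jensen-Shannon
divergence (base-2 logs, bounded [0, 1]).

Texture: a multi-level texture anisotropy index (TAI). The ROI is low-pass
filtered by an isotropic radial fourth-order Butterworth filter at several
cutoffs, Sobel gradients are collected into the gradient (inertia) tensor
C = Wc' Wc / (N - 1), and TAI = 1 - lambda_min / lambda_max.

Second-order: speckle size as the axis-aligned FWHM ellipse of the central
peak of the normalized envelope autocovariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ProbabilityHistogram",
    "TAIResult",
    "envelope_histogram",
    "fd_bin_width",
    "jsd",
    "jsd_map",
    "tai",
    "speckle_size",
    "speckle_size_profile",
    "estimate_attenuation",
]

DEFAULT_BIN_WIDTH = 0.03


@dataclass
class ProbabilityHistogram:
    """A discrete probability mass function over contiguous bins."""

    bin_edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.bin_edges.size != self.masses.size + 1:
            raise ValueError("need one more edge than masses")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.masses < 0):
            raise ValueError("masses must be non-negative")
        total = self.masses.sum()
        if abs(total - 1.0) > 1e-12:
            if total <= 0:
                raise ValueError("histogram has zero total mass")
            self.masses = self.masses / total


@dataclass
class TAIResult:
    cutoff_per_m: float
    lambda_max: float
    lambda_min: float
    tai: float
    degenerate: bool = False


def envelope_histogram(
    envelope_roi: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    percentile: float = 99.0,
    n_bins: int | None = None,
) -> ProbabilityHistogram:
    """Histogram of the 99th-percentile-normalized envelope.

    Bins are [0, w, 2w, ...] covering the maximum normalized value (or
    ``n_bins`` fixed bins, for building comparable histogram pairs).
    """
    env = np.asarray(envelope_roi, dtype=float).ravel()
    if env.size == 0:
        raise ValueError("empty ROI")
    ref = np.percentile(env, percentile)
    if ref <= 0:
        warnings.warn("all-zero ROI: degenerate single-bin histogram",
                      stacklevel=2)
        return ProbabilityHistogram(np.array([0.0, bin_width]), np.array([1.0]))
    norm = env / ref
    if n_bins is None:
        n_bins = max(int(np.ceil(norm.max() / bin_width + 1e-12)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(np.clip(norm, 0, edges[-1] - 1e-12), bins=edges)
    return ProbabilityHistogram(edges, counts / counts.sum())


def fd_bin_width(envelope_roi: np.ndarray, percentile: float = 99.0) -> float:
    """Freedman-Diaconis width 2 IQR n^(-1/3) of the normalized envelope."""
    env = np.asarray(envelope_roi, dtype=float).ravel()
    if env.size < 2:
        raise ValueError("need at least two pixels")
    ref = np.percentile(env, percentile)
    if ref <= 0:
        raise ValueError("degenerate (all-zero) envelope")
    norm = env / ref
    iqr = np.subtract(*np.percentile(norm, [75, 25]))
    if iqr <= 0:
        raise ValueError("zero IQR: bin width undefined")
    return float(2.0 * iqr * env.size ** (-1.0 / 3.0))


def _align(p: ProbabilityHistogram, q: ProbabilityHistogram):
    """Return mass vectors on a shared bin grid (union of uniform grids)."""
    wp = np.diff(p.bin_edges)
    wq = np.diff(q.bin_edges)
    if np.allclose(p.bin_edges[: q.bin_edges.size], q.bin_edges[: p.bin_edges.size]):
        n = max(p.masses.size, q.masses.size)
        pm = np.zeros(n)
        qm = np.zeros(n)
        pm[: p.masses.size] = p.masses
        qm[: q.masses.size] = q.masses
        return pm, qm
    if not (np.allclose(wp, wp[0]) and np.allclose(wq, wq[0])
            and np.isclose(wp[0], wq[0])
            and np.isclose(p.bin_edges[0] % wp[0], q.bin_edges[0] % wq[0])):
        raise ValueError("histograms have non-alignable bin edges")
    w = wp[0]
    lo = min(p.bin_edges[0], q.bin_edges[0])
    hi = max(p.bin_edges[-1], q.bin_edges[-1])
    n = int(round((hi - lo) / w))
    pm = np.zeros(n)
    qm = np.zeros(n)
    op = int(round((p.bin_edges[0] - lo) / w))
    oq = int(round((q.bin_edges[0] - lo) / w))
    pm[op : op + p.masses.size] = p.masses
    qm[oq : oq + q.masses.size] = q.masses
    return pm, qm


def jsd(p: ProbabilityHistogram, q: ProbabilityHistogram) -> float:
    """Jensen-Shannon divergence in bits: JSD = (KL(P||M) + KL(Q||M)) / 2,
    M = (P + Q)/2, with the convention 0 log(0/x) = 0."""
    pm, qm = _align(p, q)
    m = 0.5 * (pm + qm)

    def _kl(a, b):
        sel = a > 0
        return float(np.sum(a[sel] * np.log2(a[sel] / b[sel])))

    return 0.5 * (_kl(pm, m) + _kl(qm, m))


def jsd_map(
    reference_roi: np.ndarray,
    search_area: np.ndarray,
    roi_size: tuple[int, int],
    overlap: float = 0.2,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict:
    """Tile a search area into ROIs with fractional ``overlap`` and compute
    the JSD of each tile's envelope histogram against the reference ROI's.

    Returns {"values", "median", "origins"}.
    """
    sh, sw = search_area.shape
    rh, rw = roi_size
    if sh < rh or sw < rw:
        raise ValueError("search area smaller than the ROI")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    n_bins = 2 + int(
        np.ceil(
            max(
                _max_norm(reference_roi),
                _max_norm(search_area),
            )
            / bin_width
        )
    )
    p_ref = envelope_histogram(reference_roi, bin_width, n_bins=n_bins)
    step_h = max(int(round(rh * (1 - overlap))), 1)
    step_w = max(int(round(rw * (1 - overlap))), 1)
    values, origins = [], []
    for r0 in range(0, sh - rh + 1, step_h):
        for c0 in range(0, sw - rw + 1, step_w):
            tile = search_area[r0 : r0 + rh, c0 : c0 + rw]
            q = envelope_histogram(tile, bin_width, n_bins=n_bins)
            values.append(jsd(p_ref, q))
            origins.append((r0, c0))
    return {
        "values": np.asarray(values),
        "median": float(np.median(values)),
        "origins": origins,
    }


def _max_norm(env: np.ndarray) -> float:
    ref = np.percentile(env, 99.0)
    return float(env.max() / ref) if ref > 0 else 1.0


def _butterworth_lowpass(roi: np.ndarray, cutoff_per_m: float, spacing_m: float):
    """Isotropic radial 4th-order Butterworth: |H(f)|^2 = 1/(1+(f/fc)^8)."""
    h, w = roi.shape
    fz = np.fft.fftfreq(h, spacing_m)[:, None]
    fx = np.fft.rfftfreq(w, spacing_m)[None, :]
    f = np.sqrt(fz**2 + fx**2)
    H = 1.0 / np.sqrt(1.0 + (f / cutoff_per_m) ** 8)
    return np.fft.irfft2(np.fft.rfft2(roi) * H, roi.shape)


def tai(
    bmode_roi: np.ndarray,
    wavelength_um: float,
    grid_spacing_um: float,
    cutoffs_per_m: list[float] | None = None,
    prefilter: bool = True,
) -> list[TAIResult]:
    """Multi-level texture anisotropy index of a (dB-domain) B-mode ROI.

    Default cutoffs: (16 lambda)^-1, (8 lambda)^-1, (4 lambda)^-1,
    (2 lambda)^-1. Sobel gradients (3x3) along the axial and lateral axes
    feed the 2x2 gradient covariance; TAI = 1 - lambda_min / lambda_max,
    defined as 0 (flagged) for a constant ROI.
    """
    roi = np.asarray(bmode_roi, dtype=float)
    lam_m = wavelength_um * 1e-6
    spacing_m = grid_spacing_um * 1e-6
    if cutoffs_per_m is None:
        cutoffs_per_m = [1 / (16 * lam_m), 1 / (8 * lam_m), 1 / (4 * lam_m),
                         1 / (2 * lam_m)]
    results = []
    for fc in cutoffs_per_m:
        f = _butterworth_lowpass(roi, fc, spacing_m) if prefilter else roi
        g_ax = ndimage.sobel(f, axis=0, mode="reflect")
        g_lat = ndimage.sobel(f, axis=1, mode="reflect")
        wc = np.stack([g_lat.ravel(), g_ax.ravel()], axis=1)
        wc = wc - wc.mean(axis=0, keepdims=True)
        n = wc.shape[0]
        cov = wc.T @ wc / (n - 1)
        evals = np.linalg.eigvalsh(cov)
        lmin, lmax = float(evals[0]), float(evals[1])
        lmin = max(lmin, 0.0)
        if lmax <= 0:
            results.append(TAIResult(fc, 0.0, 0.0, 0.0, degenerate=True))
        else:
            results.append(TAIResult(fc, lmax, lmin, 1.0 - lmin / lmax))
    return results


def speckle_size(
    envelope_roi: np.ndarray, grid_spacing_um: float
) -> tuple[float, float]:
    """Speckle size (axial FWHM um, lateral FWHM um) from the normalized
    envelope autocovariance.

    The mean-removed autocorrelation is computed spectrally (zero-padded,
    so it is a true linear autocovariance), normalized by its zero-lag
    value; the 0.5-level contour of the central peak is extracted with
    sub-pixel (bilinear) contouring and fit by least squares to an
    axis-aligned ellipse.
    """
    env = np.asarray(envelope_roi, dtype=float)
    h, w = env.shape
    x = env - env.mean()
    F = np.fft.rfft2(x, s=(2 * h, 2 * w))
    ac = np.fft.irfft2(np.abs(F) ** 2, (2 * h, 2 * w))
    ac = np.fft.fftshift(ac)[h // 2 : h // 2 + h + 1, w // 2 : w // 2 + w + 1]
    cz, cx = np.unravel_index(np.argmax(ac), ac.shape)
    ac = ac / ac[cz, cx]

    contours = measure.find_contours(ac, 0.5)
    central = None
    for cont in contours:
        # closed contour enclosing the peak
        if (
            np.allclose(cont[0], cont[-1])
            and cont[:, 0].min() < cz < cont[:, 0].max()
            and cont[:, 1].min() < cx < cont[:, 1].max()
        ):
            central = cont
            break
    if central is None:
        raise ValueError("no closed 0.5-level contour around the central peak")

    dz = central[:, 0] - cz
    dx = central[:, 1] - cx
    # axis-aligned ellipse (dz/b)^2 + (dx/a)^2 = 1, least squares in
    # (1/b^2, 1/a^2)
    A = np.stack([dz**2, dx**2], axis=1)
    coef, *_ = np.linalg.lstsq(A, np.ones(A.shape[0]), rcond=None)
    if np.any(coef <= 0):
        raise ValueError("degenerate ellipse fit")
    b = 1.0 / np.sqrt(coef[0])  # axial semi-axis (rows)
    a = 1.0 / np.sqrt(coef[1])  # lateral semi-axis (cols)
    return 2.0 * b * grid_spacing_um, 2.0 * a * grid_spacing_um


def speckle_size_profile(
    envelope: np.ndarray,
    grid_spacing_um: float,
    wavelength_um: float,
    roi_wavelengths: float = 20.0,
    axial_overlap: float = 0.8,
) -> list[dict]:
    """Depth-resolved speckle sizing: square ROIs of ``roi_wavelengths`` per
    side tiled over depth with the given axial overlap (and laterally with
    20% overlap), each fed to :func:`speckle_size`.

    Returns a list of {"origin", "axial_um", "lateral_um"}; ROIs whose
    autocovariance lacks a closed half-level contour are skipped.
    """
    side = int(round(roi_wavelengths * wavelength_um / grid_spacing_um))
    h, w = envelope.shape
    if side > min(h, w):
        raise ValueError("ROI larger than the image")
    step_ax = max(int(round(side * (1 - axial_overlap))), 1)
    step_lat = max(int(round(side * 0.8)), 1)
    out = []
    for r0 in range(0, h - side + 1, step_ax):
        for c0 in range(0, w - side + 1, step_lat):
            roi = envelope[r0 : r0 + side, c0 : c0 + side]
            try:
                ax_um, lat_um = speckle_size(roi, grid_spacing_um)
            except ValueError:
                continue
            out.append({"origin": (r0, c0), "axial_um": ax_um,
                        "lateral_um": lat_um})
    return out


def estimate_attenuation(
    rf_samples: np.ndarray,
    dt: float,
    c: float,
    f0_hz: float,
    depth_range_m: tuple[float, float] | None = None,
) -> float:
    """Attenuation in dB/(MHz cm) from the depth decay of mean RF intensity.

    Mean intensity across channels is computed per sample, mapped to depth
    z = c t / 2, log-transformed and fit by least squares; the round-trip
    slope is halved (one-way) and divided by f0 in MHz.
    """
    rf = np.asarray(rf_samples, dtype=float)
    if rf.ndim == 3:
        rf = rf[..., 0]
    n_t = rf.shape[0]
    t = np.arange(n_t) * dt
    depth = c * t / 2.0
    intensity = np.mean(rf**2, axis=1)
    if depth_range_m is not None:
        sel = (depth >= depth_range_m[0]) & (depth <= depth_range_m[1])
    else:
        sel = depth > 0
    sel &= intensity > 0
    if sel.sum() < 10:
        raise ValueError("insufficient depth span for the attenuation fit")
    z_cm = depth[sel] * 100.0
    level_db = 10.0 * np.log10(intensity[sel])
    slope, _ = np.polyfit(z_cm, level_db, 1)
    # slope is round-trip dB/cm (negative for decay); one-way magnitude
    return float(-slope / 2.0 / (f0_hz / 1e6))
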