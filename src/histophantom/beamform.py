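"""Delay-and-sum reconstruction of plane-wave RF channel data.

Per angle, the transmit delay to a pixel follows the plane-wave law
t_tx = (z cos(theta) + x sin(theta)) / c plus the steering offset that
accounts for delays being normalized to start at zero on the first-firing
element. Receive delays are the element-to-pixel path; the receive
aperture is limited by a fixed f-number (half-aperture = depth / (2 F)),
with rectangular apodization. Angle images are summed coherently and the
envelope is the analytic-signal magnitude along the axial dimension.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .datatypes import (
    BeamformedImage,
    PlaneWavePlan,
    RFChannelData,
    TransducerSpec,
)

__all__ = ["das_beamform", "to_bmode", "autofocus_sound_speed"]


def das_beamform(
    rf: RFChannelData,
    plan: PlaneWavePlan,
    transducer: TransducerSpec,
    grid_spacing_um: float,
    reconstruction_c: float,
    f_number: float = 3.7,
    depth_mm: tuple[float, float] | None = None,
    width_mm: float | None = None,
) -> BeamformedImage:
    """Reconstruct a compounded image on a regular grid.

    ``depth_mm`` is the (start, stop) axial extent; by default it spans
    from one wavelength to the depth matching the recorded time span.
    ``width_mm`` defaults to the array aperture.
    """
    if f_number <= 0:
        raise ValueError("f_number must be positive")
    c = float(reconstruction_c)
    dt = rf.dt
    n_t, n_el, n_ang = rf.samples.shape
    if n_ang != plan.angles_deg.size:
        raise ValueError("plan angle count does not match RF data")
    x_el = transducer.element_positions_m()

    t_max = rf.t0 + (n_t - 1) * dt
    z_hi_data = c * t_max / 2.0
    lam = c / transducer.center_frequency_hz
    if depth_mm is None:
        z_lo, z_hi = lam, z_hi_data
    else:
        z_lo, z_hi = depth_mm[0] * 1e-3, depth_mm[1] * 1e-3
        if z_hi > z_hi_data + 1e-9:
            warnings.warn(
                "requested depth exceeds the recorded time span; truncated",
                stacklevel=2,
            )
            z_hi = z_hi_data
    half_w = (
        width_mm * 1e-3 / 2.0 if width_mm is not None else transducer.aperture_um
        * 1e-6 / 2.0
    )
    dz = grid_spacing_um * 1e-6
    # the axial RF carrier sits at 2 f0 / c; the display grid may undersample
    # it (e.g. 50 um vs a 99 um carrier period), so delays are evaluated on an
    # axially oversampled grid, the envelope is detected there, and only then
    # decimated to the requested spacing (the envelope itself is band-limited
    # well below the display Nyquist)
    dz_carrier = c / (8.0 * transducer.center_frequency_hz)
    ax_os = max(1, int(np.ceil(dz / dz_carrier)))
    dz_fine = dz / ax_os
    zs = np.arange(z_lo, z_hi, dz_fine)
    xs = np.arange(-half_w, half_w + dz / 2, dz)
    Z = zs[:, None]
    X = xs[None, :]

    x_span = np.abs(x_el).max()
    img = np.zeros((zs.size, xs.size))
    t_axis0 = rf.t0
    for a, th_deg in enumerate(np.atleast_1d(plan.angles_deg)):
        th = np.deg2rad(th_deg)
        t_shift = x_span * abs(np.sin(th)) / c
        t_tx = (Z * np.cos(th) + X * np.sin(th)) / c + t_shift
        acc = np.zeros_like(img)
        pitch_m = transducer.pitch_um * 1e-6
        half_ap = Z / (2.0 * f_number)
        for e in range(n_el):
            # rectangular apodization with a one-pitch feathered edge: the
            # boundary element enters with fractional weight, avoiding the
            # lateral ripple of discrete element-set switching in small
            # (shallow) apertures
            ap_w = np.clip(
                (half_ap - np.abs(x_el[e] - X)) / pitch_m + 0.5, 0.0, 1.0
            )
            if not np.any(ap_w > 0):
                continue
            t_rx = np.sqrt(Z**2 + (X - x_el[e]) ** 2) / c
            s = (t_tx + t_rx - t_axis0) / dt
            s0 = np.floor(s).astype(int)
            frac = s - s0
            valid = (s0 >= 0) & (s0 < n_t - 1)
            s0c = np.clip(s0, 0, n_t - 2)
            trace = rf.samples[:, e, a]
            vals = trace[s0c] * (1 - frac) + trace[s0c + 1] * frac
            acc += np.where(valid, ap_w * vals, 0.0)
        img += acc

    envelope = np.abs(hilbert(img, axis=0))[::ax_os]
    return BeamformedImage(
        envelope=envelope,
        grid_spacing_um=grid_spacing_um,
        reconstruction_c=c,
        z0_m=z_lo,
        x0_m=float(xs[0]),
    )


def to_bmode(
    img: BeamformedImage,
    dynamic_range_db: float = 60.0,
    percentile: float = 99.0,
) -> np.ndarray:
    """Log-compress: 20 log10(env / p99), clipped at -dynamic_range."""
    env = img.envelope
    ref = np.percentile(env, percentile)
    if ref <= 0:
        bmode = np.full(env.shape, -dynamic_range_db)
    else:
        with np.errstate(divide="ignore"):
            bmode = 20.0 * np.log10(env / ref)
        bmode = np.clip(bmode, -dynamic_range_db, None)
    img.bmode_db = bmode
    img.dynamic_range_db = dynamic_range_db
    return bmode


def autofocus_sound_speed(
    rf: RFChannelData,
    plan: PlaneWavePlan,
    transducer: TransducerSpec,
    candidate_cs,
    grid_spacing_um: float = 50.0,
    f_number: float = 3.7,
    roi_fraction: float = 0.5,
) -> float:
    """Global speed-of-sound autofocus: beamform at each candidate and
    return the one maximizing mean envelope power in a central ROI.

    The ROI is gated in *time* (the central fraction of the recorded
    span), so every candidate integrates the same physical echoes and the
    comparison isolates the coherent-summation gain; a fixed-depth ROI
    would instead favour whichever candidate maps it to stronger
    (shallower, less attenuated) echoes."""
    candidates = np.atleast_1d(np.asarray(candidate_cs, dtype=float))
    if candidates.size == 1:
        return float(candidates[0])
    n_t = rf.samples.shape[0]
    t_hi = rf.t0 + (n_t - 1) * rf.dt
    t1 = t_hi * (0.5 - roi_fraction / 2)
    t2 = t_hi * (0.5 + roi_fraction / 2)
    powers = []
    for c in candidates:
        img = das_beamform(
            rf, plan, transducer, grid_spacing_um, c, f_number=f_number,
            depth_mm=(c * t1 / 2 * 1e3, c * t2 / 2 * 1e3),
        )
        env = img.envelope
        w = env.shape[1]
        roi = env[:, w // 4 : 3 * w // 4]
        powers.append(float(np.mean(roi**2)))
    powers = np.asarray(powers)
    if np.allclose(powers, powers[0]):
        warnings.warn("flat autofocus objective; returning lowest candidate",
                      stacklevel=2)
        return float(candidates.min())
    return float(candidates[np.argmax(powers)])
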