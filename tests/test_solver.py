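"""Physics checks for the k-space pseudospectral solver and the
band-limited element aperture model."""

import numpy as np
import pytest
from scipy.signal import hilbert

from histophantom.datatypes import (
    AcousticPhantom,
    PulseSpec,
    SimulationGrid,
    TransducerSpec,
)
from histophantom.simulate import _source_signals
from histophantom.solver import (
    KSpaceSolver,
    PressureSource,
    SensorSpec,
    VelocitySource,
)
from histophantom.transducer import element_aperture_weights


def _grid(nz=128, nx=128, spacing_um=24.7, c_max=1500.0, n_steps=100, pml=20):
    spacing_m = spacing_um * 1e-6
    return SimulationGrid(
        nz=nz, nx=nx, spacing_um=spacing_um,
        dt=0.3 * spacing_m / c_max, n_steps=n_steps, pml_thickness=pml,
    )


def _water(grid, c=1500.0):
    shape = (grid.nz, grid.nx)
    return AcousticPhantom(
        np.full(shape, 1000.0), np.full(shape, c), np.zeros(shape), 1.1,
        grid.spacing_um,
    )


class TestApertureWeights:
    def _probe(self, width_um, pitch_um=296.4, n_el=4):
        return TransducerSpec("toy", n_el, pitch_um, width_um, 7.6e6)

    def test_weight_sum_matches_width(self):
        grid = _grid(nz=64, nx=256)
        dx_um = grid.spacing_um
        probe = self._probe(width_um=11 * dx_um, pitch_um=12 * dx_um)
        _, wts = element_aperture_weights(probe, grid)
        # integral of the band-limited indicator equals the physical width
        assert np.allclose(wts.sum(axis=1), 11.0, atol=0.01)

    def test_numeric_integration_oracle(self):
        # the continuous band-limited rectangle integrates to its width
        from histophantom.transducer import _bandlimited_rect

        dx = 1.0
        x = np.linspace(-60, 60, 24001)
        f = _bandlimited_rect(x, -3.5, 3.5, dx)
        integral = np.trapezoid(f, x)
        assert integral == pytest.approx(7.0, abs=0.01)

    def test_zero_width_single_unit_sample(self):
        grid = _grid(nz=64, nx=255)  # odd nx puts a node at x = 0
        probe = TransducerSpec("pt", 2, 4 * grid.spacing_um, 0.0, 7.6e6)
        # place elements symmetrically on nodes: pitch = 4 dx keeps centres
        # on half-grid; use 2 elements at +/- 2 dx
        idx, wts = element_aperture_weights(probe, grid)
        for row in wts:
            nz_w = row[np.abs(row) > 1e-9]
            assert nz_w.size == 1
            assert nz_w[0] == pytest.approx(1.0, abs=1e-6)

    def test_tail_decays_beyond_edge(self):
        grid = _grid(nz=64, nx=256)
        dx_um = grid.spacing_um
        probe = self._probe(width_um=11 * dx_um, pitch_um=40 * dx_um, n_el=2)
        idx, wts = element_aperture_weights(probe, grid, truncate=1e-6)
        # envelope of |w| shrinks with distance beyond the physical edge
        row_idx, row_w = idx[0], wts[0]
        x_grid = (np.arange(grid.nx) - (grid.nx - 1) / 2) * dx_um
        x_el = probe.element_positions_m()[0] * 1e6
        beyond = x_grid[row_idx] > x_el + 5.5 * dx_um + 0.5 * dx_um
        tail = np.abs(row_w[beyond])
        if tail.size >= 6:
            assert tail[:3].max() > tail[-3:].max()


class TestWavePhysics:
    def test_travel_time_and_quiet_after_transit(self):
        """Plane-wave arrival at depth matches d/c to a few time steps
        (matched-filter timing; the residual is finite-aperture diffraction
        skew, not grid dispersion); the differential arrival between two
        depths agrees with (d2-d1)/c to < 0.5%; with nothing to scatter,
        the late-time element signal is below -60 dB of the transmit."""
        grid = _grid(nz=375, nx=432, n_steps=1500)
        medium = _water(grid)
        probe = TransducerSpec("toy", 32, 296.4, 271.4, 7.6e6)
        idx, wts = element_aperture_weights(probe, grid)
        pulse = PulseSpec(7.6e6)
        cols, signals = _source_signals(
            probe, pulse, np.zeros(32), idx, wts, grid.dt
        )
        src_row = grid.pml_thickness
        d1, d2 = 4e-3, 7e-3
        r1 = src_row + int(round(d1 / grid.spacing_m))
        r2 = src_row + int(round(d2 / grid.spacing_m))
        col = grid.nx // 2
        solver = KSpaceSolver(grid, medium)
        out = solver.run(
            velocity_source=VelocitySource(src_row, cols, signals),
            sensor=SensorSpec(
                element_row=src_row, element_cols=idx, element_weights=wts,
                points=[(r1, col), (r2, col)],
            ),
        )

        w = pulse.waveform(grid.dt)
        stagger = 0.5 * grid.spacing_m / 1500.0

        def arrival(trace):
            xc = np.correlate(trace, w, mode="full")
            env = np.abs(hilbert(xc))
            k = int(np.argmax(env))
            y0, y1, y2 = env[k - 1 : k + 2]
            frac = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
            return (k - (len(w) - 1) + frac) * grid.dt

        t1 = arrival(out["point_rf"][:, 0])
        t2 = arrival(out["point_rf"][:, 1])
        assert abs(t1 - (d1 / 1500.0 - stagger)) <= 3 * grid.dt
        assert abs(t2 - (d2 / 1500.0 - stagger)) <= 3 * grid.dt

        # numerical dispersion bound on the differential arrival
        expected_lag = (d2 - d1) / 1500.0
        assert abs((t2 - t1) - expected_lag) / expected_lag < 0.005

        # quiet after the transmit passes: nothing scatters back
        rf = out["element_rf"][:, 16]
        peak = np.abs(rf).max()
        transit = int((pulse.duration * 2) / grid.dt)
        late = np.abs(rf[transit:]).max()
        assert late < 1e-3 * peak

    def test_energy_conserved_closed_lossless(self):
        grid = _grid(nz=128, nx=128, n_steps=1100, pml=20)
        medium = _water(grid)
        solver = KSpaceSolver(grid, medium, use_pml=False, dtype=np.float64)
        z, x = np.indices((grid.nz, grid.nx))
        p0 = np.exp(-(((z - 64) ** 2 + (x - 64) ** 2) / (2 * 6.0**2)))
        out50 = solver.run(n_steps=50, p0=p0)
        out1050 = solver.run(n_steps=1050, p0=p0)
        e50 = solver.acoustic_energy(out50["final_state"])
        e1050 = solver.acoustic_energy(out1050["final_state"])
        assert abs(e1050 - e50) / e50 < 1e-6

    def test_linearity_in_source_amplitude(self):
        grid = _grid(nz=96, nx=96, n_steps=200)
        medium = _water(grid)
        solver = KSpaceSolver(grid, medium)
        sig = PulseSpec(7.6e6).waveform(grid.dt)[None, :]
        cols = np.array([48])
        row = grid.pml_thickness
        sensor = SensorSpec(points=[(70, 48)])
        a = solver.run(
            velocity_source=VelocitySource(row, cols, sig), sensor=sensor
        )["point_rf"]
        b = solver.run(
            velocity_source=VelocitySource(row, cols, 2.0 * sig), sensor=sensor
        )["point_rf"]
        assert np.max(np.abs(b - 2 * a)) <= 1e-6 * np.max(np.abs(b))

    def test_reciprocity_heterogeneous(self):
        grid = _grid(nz=160, nx=160, n_steps=500, c_max=1600.0)
        rng = np.random.default_rng(0)
        from scipy import ndimage

        f = ndimage.gaussian_filter(rng.standard_normal((160, 160)), 8)
        c = np.clip(1500.0 + 30.0 * f / f.std(), 1400, 1600)
        rho = 1000.0 * (c / 1500.0)  # correlated heterogeneity
        medium = AcousticPhantom(rho, c, np.zeros_like(c), 1.1, grid.spacing_um)
        solver = KSpaceSolver(grid, medium, use_pml=False, dtype=np.float64)
        sig = PulseSpec(7.6e6).waveform(grid.dt)
        A, B = (50, 60), (110, 100)
        out_ab = solver.run(
            pressure_source=PressureSource([A], sig),
            sensor=SensorSpec(points=[B]),
        )["point_rf"][:, 0]
        out_ba = solver.run(
            pressure_source=PressureSource([B], sig),
            sensor=SensorSpec(points=[A]),
        )["point_rf"][:, 0]
        denom = np.linalg.norm(out_ab)
        assert np.linalg.norm(out_ab - out_ba) / denom < 0.01

    def test_cfl_violation_rejected(self):
        spacing_m = 24.7e-6
        grid = SimulationGrid(
            nz=96, nx=96, spacing_um=24.7,
            dt=0.5 * spacing_m / 1500.0,  # CFL 0.5 > 0.3
            n_steps=10,
        )
        with pytest.raises(ValueError, match="CFL"):
            KSpaceSolver(grid, _water(grid))
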