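"""Loop vector potential, flux, on-axis field, and induced-E evaluation."""

import numpy as np
import pytest

from coilassay import coil_model as cm
from coilassay import drive_circuit as dc
from coilassay import field_solver as fs
from coilassay.constants import MU0

from conftest import segment_A_unit


class TestLoopAUnit:
    def test_on_axis_is_zero(self):
        assert fs.loop_A_unit(5e-3, 0.0, 0.0) == 0.0
        assert fs.loop_A_unit(5e-3, 0.0, 0.02) == 0.0

    def test_matches_segment_oracle(self):
        # pins down the elliptic-integral parameter convention (m = k^2)
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.uniform(2e-3, 8e-3)
            rho = rng.uniform(1e-3, 4e-2)
            z = rng.uniform(-5e-2, 5e-2)
            if abs(rho - a) < 5e-4 and abs(z) < 5e-4:
                continue
            assert fs.loop_A_unit(a, rho, z) == pytest.approx(
                segment_A_unit(a, rho, z), rel=1e-6
            )

    def test_far_field_dipole_limit(self):
        a = 5e-3
        rho = 1.0
        dipole = MU0 * a**2 * rho / (4 * (rho**2) ** 1.5)
        assert fs.loop_A_unit(a, rho, 0.0) == pytest.approx(dipole, rel=1e-3)

    def test_filament_point_rejected(self):
        with pytest.raises(ValueError):
            fs.loop_A_unit(5e-3, 5e-3, 0.0)


class TestStackFlux:
    def test_zero_current(self, ref_stack):
        assert fs.stack_flux(ref_stack, 2e-3, 0.0, 0.0) == 0.0

    def test_single_loop_disc_integration_oracle(self):
        # flux through a concentric circle, oracle: integrate B_z (from a
        # Biot-Savart segment sum) over the disc
        a, rho_c, z = 10e-3, 5e-3, 3e-3
        stack = cm.WindingStack(radii=np.array([a]), z=np.array([0.0]))
        n_seg, n_rad = 4000, 400
        phi = (np.arange(n_seg) + 0.5) * (2 * np.pi / n_seg)
        rr = np.linspace(0, rho_c, n_rad)
        # B_z at (r, 0, z) from loop segments (cross product z-component)
        r = rr[:, None]
        sx, sy = a * np.cos(phi)[None, :], a * np.sin(phi)[None, :]
        dlx, dly = -np.sin(phi)[None, :] * a * (2 * np.pi / n_seg), np.cos(phi)[
            None, :
        ] * a * (2 * np.pi / n_seg)
        rx, ry, rz = r - sx, -sy, z
        dist3 = (rx**2 + ry**2 + rz**2) ** 1.5
        bz = MU0 / (4 * np.pi) * np.sum((dlx * ry - dly * rx) / dist3, axis=1)
        oracle = np.trapezoid(2 * np.pi * rr * bz, rr)
        assert fs.stack_flux(stack, rho_c, z, 1.0) == pytest.approx(oracle, rel=1e-4)

    def test_infinite_solenoid_interior_limit(self):
        # long single-layer solenoid: interior flux density approaches mu0*n*i
        n_per_m, length, a = 1000, 10.0, 5e-3
        n_loops = int(n_per_m * length)
        z = -length / 2 + (np.arange(n_loops) + 0.5) * (length / n_loops)
        stack = cm.WindingStack(radii=np.full(n_loops, a), z=z)
        rho = 2e-3
        flux = fs.stack_flux(stack, rho, 0.0, 1.0)
        assert flux / (np.pi * rho**2) == pytest.approx(MU0 * n_per_m, rel=1e-3)


class TestAxisBz:
    def test_zero_current(self, ref_stack):
        assert fs.axis_Bz(ref_stack, 0.0, 0.0) == 0.0

    def test_single_loop_center(self):
        a = 10e-3
        stack = cm.WindingStack(radii=np.array([a]), z=np.array([0.0]))
        assert fs.axis_Bz(stack, 0.0, 1.0) == pytest.approx(MU0 / (2 * a), rel=1e-12)

    def test_symmetric_stack_even_in_z(self, ref_stack):
        zs = np.array([0.01, 0.03, 0.06])
        np.testing.assert_allclose(
            fs.axis_Bz(ref_stack, zs, 1.0), fs.axis_Bz(ref_stack, -zs, 1.0),
            rtol=1e-12,
        )


class TestInducedE:
    def test_zero_didt_gives_zero_field(self, ref_stack):
        t = np.arange(64) * 1.0
        tr = dc.CurrentTrace(t=t, v_source=np.ones(64), i=np.ones(64),
                             di_dt=np.zeros(64), period=64.0)
        fmap = fs.induced_E(ref_stack, [fs.FieldPoint(9e-3, 0.0)], tr)
        assert np.all(fmap.E_theta == 0.0)

    def test_faraday_consistency(self, ref_stack, sine_trace):
        # 2*pi*rho*E equals -dPhi/dt with the flux differentiated by finite
        # differences in time (independent of the spectral di/dt route)
        tr = sine_trace
        dt = tr.t[1] - tr.t[0]
        for rho in [0.5e-3, 1.2e-3, 9e-3, 2e-2]:
            fmap = fs.induced_E(ref_stack, [fs.FieldPoint(rho, 0.0)], tr)
            lhs = 2 * np.pi * rho * fmap.E_theta[0]
            phi_t = 2 * np.pi * rho * fmap.A_unit[0] * tr.i
            rhs = -(np.roll(phi_t, -1) - np.roll(phi_t, 1)) / (2 * dt)
            assert np.max(np.abs(lhs - rhs)) < 1e-3 * np.max(np.abs(lhs))

    def test_monotone_radial_decay_beyond_winding(self, ref_stack,
                                                  ref_sawtooth_trace):
        rhos = np.linspace(7.5e-3, 4e-2, 12)
        pts = [fs.FieldPoint(r, 0.0) for r in rhos]
        fmap = fs.induced_E(ref_stack, pts, ref_sawtooth_trace)
        peaks = fmap.max_abs_E()
        assert np.all(np.diff(peaks) < 0)

    def test_mirror_symmetry(self, ref_stack, ref_sawtooth_trace):
        up = fs.induced_E(ref_stack, [fs.FieldPoint(9e-3, 0.02)],
                          ref_sawtooth_trace)
        dn = fs.induced_E(ref_stack, [fs.FieldPoint(9e-3, -0.02)],
                          ref_sawtooth_trace)
        scale = np.max(np.abs(up.E_theta))
        np.testing.assert_allclose(up.E_theta, dn.E_theta, atol=1e-9 * scale)

    def test_bilinearity_in_didt_and_turn_scale(self, ref_stack,
                                                ref_sawtooth_trace):
        tr = ref_sawtooth_trace
        tr2 = dc.CurrentTrace(t=tr.t, v_source=2 * tr.v_source, i=2 * tr.i,
                              di_dt=2 * tr.di_dt, period=tr.period)
        p = [fs.FieldPoint(9e-3, 0.0)]
        e1 = fs.induced_E(ref_stack, p, tr).E_theta
        e2 = fs.induced_E(ref_stack, p, tr2).E_theta
        scale = np.max(np.abs(e1))
        np.testing.assert_allclose(e2, 2 * e1, atol=1e-12 * scale)
        scaled = cm.WindingStack(radii=ref_stack.radii, z=ref_stack.z,
                                 effective_turn_scale=3.0,
                                 filament_clearance=ref_stack.filament_clearance)
        e3 = fs.induced_E(scaled, p, tr).E_theta
        np.testing.assert_allclose(e3, 3 * e1, atol=1e-11 * scale)

    def test_time_average_zero_everywhere(self, ref_stack, ref_sawtooth_trace):
        pts = [fs.FieldPoint(9e-3, 0.0), fs.FieldPoint(2e-2, 0.03)]
        fmap = fs.induced_E(ref_stack, pts, ref_sawtooth_trace)
        E = fmap.E_theta
        assert np.all(np.abs(E.mean(axis=1)) < 1e-6 * np.max(np.abs(E)))

    def test_far_field_log_slope(self, ref_stack, ref_sawtooth_trace):
        rhos = np.geomspace(0.5, 2.0, 6)
        pts = [fs.FieldPoint(r, 0.0) for r in rhos]
        fmap = fs.induced_E(ref_stack, pts, ref_sawtooth_trace)
        slope = np.polyfit(np.log(rhos), np.log(fmap.max_abs_E()), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.05)

    def test_near_filament_point_rejected_with_index(self, ref_stack,
                                                     ref_sawtooth_trace):
        pts = [fs.FieldPoint(9e-3, 0.0), fs.FieldPoint(ref_stack.radii[0],
                                                       ref_stack.z[0])]
        with pytest.raises(ValueError, match="1"):
            fs.induced_E(ref_stack, pts, ref_sawtooth_trace)
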