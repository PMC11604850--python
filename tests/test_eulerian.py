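import numpy as np
import pytest

from pcmrisim.eulerian import (
    BoundarySpec,
    ConfigurationError,
    EulerianState,
    IntegrationBlowupError,
    RelaxationParams,
    advance,
    bloch_rhs,
    cfl_timestep,
    weno5_advection_term,
)
from pcmrisim.phantoms import GridSpec, VelocityField
from pcmrisim.sequence import ScanProtocol, build_segment

from conftest import make_plug_field, make_static_field


def uniform_flow_x(speed, extent, shape):
    grid = GridSpec.centered(list(extent), list(shape))
    z = np.zeros(shape)
    return VelocityField(
        grid, np.full(shape, speed), z.copy(), z.copy(), np.ones(shape, bool)
    )


class TestWeno5:
    def test_uniform_scalar_gives_zero(self):
        # uniform scalar with a matching inlet ghost value: all differences
        # vanish identically, everywhere including the boundary layers
        f = uniform_flow_x(0.3, (16e-3, 8e-3, 8e-3), (16, 4, 4))
        adv = weno5_advection_term(np.full((16, 4, 4), 2.5), f, inlet_value=2.5)
        np.testing.assert_allclose(adv, 0.0, atol=1e-12)

    @pytest.mark.parametrize("speed", [0.2, -0.2])
    def test_linear_scalar_is_exact_in_interior(self, speed):
        f = uniform_flow_x(speed, (16e-3, 8e-3, 8e-3), (16, 4, 4))
        X, _, _ = f.grid.meshgrid()
        adv = weno5_advection_term(X.copy(), f)
        # WENO5 reconstructs polynomials exactly away from the Dirichlet ghosts
        np.testing.assert_allclose(adv[4:-4], -speed, rtol=1e-10)

    def test_smooth_profile_convergence_order(self):
        # Richardson: tanh profile (monotone, no critical points), halving h
        speed, order_floor = 0.25, 4.5
        errs = []
        for n in (64, 128):
            f = uniform_flow_x(speed, (20e-3, 4e-3, 4e-3), (n, 4, 4))
            X, _, _ = f.grid.meshgrid()
            q = np.tanh(X / 2e-3)
            exact = -speed / 2e-3 / np.cosh(X / 2e-3) ** 2
            adv = weno5_advection_term(q, f)
            m = n // 8
            errs.append(np.abs(adv[m:-m] - exact[m:-m]).max())
        order = np.log2(errs[0] / errs[1])
        assert order >= order_floor

    def test_grid_too_small_for_stencil(self):
        f = uniform_flow_x(0.1, (6e-3, 8e-3, 8e-3), (3, 4, 4))
        with pytest.raises(ConfigurationError):
            weno5_advection_term(np.zeros((3, 4, 4)), f)


class TestBlochRelaxation:
    def test_transverse_decay_closed_form(self, relax):
        f = make_static_field()
        shape = tuple(f.grid.shape)
        st = EulerianState(f.grid, np.zeros(shape), np.full(shape, 7.0), np.zeros(shape))
        out = advance(st, f, None, relax, 0.0, 0.1)
        np.testing.assert_allclose(out.mr, 7.0 * np.exp(-0.1 / relax.t2), rtol=1e-6)

    def test_longitudinal_recovery_closed_form(self, relax):
        f = make_static_field()
        shape = tuple(f.grid.shape)
        ms = 63.0
        st = EulerianState(f.grid, np.full(shape, ms), np.zeros(shape), np.zeros(shape))
        out = advance(st, f, None, relax, 0.0, 0.25)
        expect = relax.m0 + (ms - relax.m0) * np.exp(-0.25 / relax.t1)
        np.testing.assert_allclose(out.mz, expect, rtol=1e-6)

    def test_phase_accrual_under_gradient(self, relax, small_protocol):
        # static spins: linear phase -gamma GR x t over half the readout
        # plateau, and exactly zero again at the echo (prephaser cancellation)
        p = small_protocol
        f = make_static_field()
        seg = build_segment(p, 0, "off")
        shape = tuple(f.grid.shape)
        st = EulerianState(f.grid, np.zeros(shape), np.ones(shape), np.zeros(shape))
        out = advance(st, f, seg, relax, p.te - p.ts / 2, p.te, gamma_rad=p.gamma_rad)
        X, _, _ = f.grid.meshgrid()
        expect = -p.gamma_rad * p.readout_amplitude * X * (p.ts / 2)
        np.testing.assert_allclose(out.phi, expect, rtol=1e-9)
        st2 = EulerianState(f.grid, np.zeros(shape), np.ones(shape), np.zeros(shape))
        out2 = advance(st2, f, seg, relax, p.te - p.ts, p.te, gamma_rad=p.gamma_rad)
        np.testing.assert_allclose(out2.phi, 0.0, atol=1e-9)

    def test_rhs_terms_match_definition(self, relax):
        f = make_plug_field(0.1, shape=(8, 8, 8), extent=(16e-3, 16e-3, 16e-3))
        shape = tuple(f.grid.shape)
        rng = np.random.default_rng(0)
        st = EulerianState(
            f.grid, rng.normal(size=shape), np.abs(rng.normal(size=shape)), rng.normal(size=shape)
        )
        bz = rng.normal(size=shape) * 1e-6
        dmz, dmr, dphi = bloch_rhs(st, f, bz, relax, gamma_rad=1e7)
        adv_phi = weno5_advection_term(st.phi, f)
        np.testing.assert_allclose(dphi, adv_phi - 1e7 * bz, rtol=1e-10)
        adv_mr = weno5_advection_term(st.mr, f)
        np.testing.assert_allclose(dmr, adv_mr - st.mr / relax.t2, rtol=1e-10)
        adv_mz = weno5_advection_term(st.mz, f, inlet_value=relax.m0)
        np.testing.assert_allclose(
            dmz, adv_mz + (relax.m0 - st.mz) / relax.t1, rtol=1e-10
        )


class TestCfl:
    def test_cap_and_arithmetic(self):
        f = make_plug_field(0.1, shape=(8, 8, 8))
        grid = f.grid
        # uncapped would be 0.5 * h_z / v; the sampling pitch caps it
        dt = cfl_timestep(f, grid, 0.5, sampling_pitch=1e-5)
        assert dt == pytest.approx(1e-5)
        uncapped = cfl_timestep(f, grid, 0.5, sampling_pitch=1e3)
        assert uncapped == pytest.approx(0.5 * grid.spacing[2] / 0.1)
        assert cfl_timestep(f, grid, 0.8, sampling_pitch=1e3) == pytest.approx(
            1.6 * uncapped
        )

    def test_zero_velocity_returns_pitch(self):
        f = make_static_field()
        assert cfl_timestep(f, f.grid, 0.5, sampling_pitch=1e-5) == 1e-5

    def test_courant_must_be_fractional(self):
        f = make_static_field()
        with pytest.raises(ValueError):
            cfl_timestep(f, f.grid, 1.5)


class TestAdvection:
    def test_gaussian_blob_translates_exactly(self, long_relax):
        # characteristic oracle: constant v translates the profile rigidly
        speed, t = 0.1, 0.05
        f = make_plug_field(speed, extent=(8e-3, 8e-3, 80e-3), shape=(4, 4, 160))
        grid = f.grid
        _, _, Z = grid.meshgrid()
        sigma = 2.5e-3
        blob = lambda z: np.exp(-((z + 15e-3) ** 2) / (2 * sigma**2))
        st = EulerianState(grid, np.zeros(tuple(grid.shape)), blob(Z), np.zeros(tuple(grid.shape)))
        out = advance(st, f, None, long_relax, 0.0, t, courant=0.4)
        expect = blob(Z - speed * t)
        assert out.mr.max() == pytest.approx(1.0, abs=0.01)  # peak preserved within 1%
        assert np.abs(out.mr - expect).max() < 0.01

    def test_mass_conservation_drift_is_small_and_convergent(self, long_relax):
        speed, t = 0.1, 0.02
        drifts = []
        for nz in (80, 160):
            f = make_plug_field(speed, extent=(8e-3, 8e-3, 80e-3), shape=(4, 4, nz))
            grid = f.grid
            _, _, Z = grid.meshgrid()
            mr = np.exp(-((Z + 10e-3) ** 2) / (2 * (4e-3) ** 2))
            st = EulerianState(grid, np.zeros(tuple(grid.shape)), mr.copy(), np.zeros(tuple(grid.shape)))
            out = advance(st, f, None, long_relax, 0.0, t, courant=0.4)
            drifts.append(abs(out.mr.sum() / mr.sum() - 1.0))
        # advective-form WENO conserves only asymptotically: the drift must be
        # small and collapse at high order under refinement
        assert drifts[0] < 2e-4
        assert drifts[1] < drifts[0] / 16

    def test_long_run_is_stable_and_bounded(self, relax, pipe_field):
        # thousands of CFL-limited steps on the pipe phantom: no blow-up and
        # max |Mr| can only shrink (advection + T2 decay)
        grid = pipe_field.grid
        shape = tuple(grid.shape)
        mr0 = 4.0 * pipe_field.lumen_mask.astype(float)
        st = EulerianState(grid, np.full(shape, 60.0), mr0.copy(), np.zeros(shape))
        dt_cfl = 0.5 * grid.spacing[2] / 0.1
        out = advance(st, pipe_field, None, relax, 0.0, 2000 * dt_cfl, courant=0.5)
        assert np.isfinite(out.mr).all()
        assert out.mr.max() <= mr0.max() + 1e-12

    def test_nan_state_raises_blowup(self, relax):
        f = make_plug_field(0.1)
        shape = tuple(f.grid.shape)
        mr = np.zeros(shape)
        mr[4, 4, 4] = np.nan
        st = EulerianState(f.grid, np.zeros(shape), mr, np.zeros(shape))
        with pytest.raises(IntegrationBlowupError):
            advance(st, f, None, relax, 0.0, 1e-3)


class TestBoundarySpec:
    def test_inferred_faces_for_pipe(self, pipe_field):
        b = BoundarySpec.infer(pipe_field)
        assert b.faces["z-"] == "inlet"
        assert b.faces["z+"] == "outlet"
        assert b.faces["x-"] == b.faces["y+"] == "wall"

    def test_all_faces_required(self):
        with pytest.raises(ValueError):
            BoundarySpec({"x-": "wall"})

    def test_inlet_refreshes_longitudinal_magnetization(self, long_relax):
        # unsaturated spins (Mz = M0) convect in from the inlet ghost layer
        f = make_plug_field(0.1, extent=(8e-3, 8e-3, 40e-3), shape=(4, 4, 40))
        grid = f.grid
        shape = tuple(grid.shape)
        st = EulerianState(grid, np.full(shape, 60.0), np.zeros(shape), np.zeros(shape))
        out = advance(st, f, None, long_relax, 0.0, 0.1, courant=0.4)  # 10 mm travel
        assert out.mz[:, :, 0].mean() > 99.0
        assert out.mz[:, :, -1].mean() == pytest.approx(60.0, abs=0.5)


def test_state_nifti_export(tmp_path, pipe_field):
    import nibabel as nib

    from pcmrisim.eulerian import export_state_nifti

    shape = tuple(pipe_field.grid.shape)
    st = EulerianState(
        pipe_field.grid, np.full(shape, 60.0), np.ones(shape), np.zeros(shape)
    )
    written = export_state_nifti(st, tmp_path, "snap")
    img = nib.load(tmp_path / "snap_mr.nii")
    np.testing.assert_allclose(np.asarray(img.dataobj), 1.0)
    assert len(written) == 3
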