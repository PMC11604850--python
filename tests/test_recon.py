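import numpy as np
import pytest

from pcmrisim.eulerian import EulerianState
from pcmrisim.lagrangian import ParticleEnsemble
from pcmrisim.phantoms import GridSpec, VelocityField
from pcmrisim.recon import (
    acquire_kspace,
    displacement_prediction,
    error_metrics,
    image_grid_for,
    ivsd_map,
    reconstruct_image,
    sample_signal,
    velocity_from_phase,
)
from pcmrisim.sequence import ScanProtocol, build_segment

from conftest import make_static_field


class TestSampleSignal:
    def test_uniform_transverse_state_integrates_to_volume(self):
        f = make_static_field(extent=(16e-3, 16e-3, 16e-3), shape=(9, 9, 9))
        g = f.grid
        shape = tuple(g.shape)
        vol = np.prod([(n - 1) * h for n, h in zip(shape, g.spacing)])
        st = EulerianState(g, np.zeros(shape), np.ones(shape), np.zeros(shape))
        s = sample_signal(st)
        assert s.real == pytest.approx(vol, rel=1e-12)
        assert s.imag == pytest.approx(0.0, abs=1e-18)
        st.phi[:] = np.pi / 2
        s = sample_signal(st)
        assert s.imag == pytest.approx(vol, rel=1e-12)
        assert s.real == pytest.approx(0.0, abs=1e-9 * vol)

    def test_antiphase_particles_cancel(self):
        ens = ParticleEnsemble(
            positions=np.zeros((2, 3)),
            mz=np.zeros(2),
            mr=np.ones(2),
            phi=np.array([0.0, np.pi]),
            particle_volume=2e-9,
            rng_seed=0,
        )
        s = sample_signal(ens)
        assert abs(s) == pytest.approx(0.0, abs=1e-22)
        ens.phi[1] = 0.0
        assert sample_signal(ens).real == pytest.approx(2 * 2e-9)


class _PointSourceEngine:
    """Analytic oracle backend: one static unit spin at a fixed position.

    The accrued phase is the exact gradient-area integral, so acquiring with
    this engine must produce a pure Fourier phase ramp (shift theorem) and the
    reconstruction a delta at the source voxel.
    """

    def __init__(self, pos, gamma_rad):
        self.pos = np.asarray(pos, float)
        self.gamma_rad = gamma_rad

    def reset(self):
        self.phi = 0.0
        self.t = 0.0

    def excite(self):
        self.phi = 0.0

    def spoil(self):
        self.phi = 0.0

    def run_interval(self, segment, t0, t1):
        area = np.zeros(3)
        for ev in segment.events:
            a, b = max(ev.start, t0), min(ev.stop, t1)
            if b > a:
                area[ev.axis] += ev.amplitude * (b - a)
        self.phi -= self.gamma_rad * float(area @ self.pos)

    def sample(self):
        return complex(np.cos(self.phi), np.sin(self.phi))


class TestAcquisitionConventions:
    @pytest.mark.parametrize("src", [(0.0, 0.0), (4e-3, 0.0), (-2e-3, 6e-3)])
    def test_point_source_lands_on_its_voxel(self, src):
        # end-to-end oracle: sequence events + sampling + centred inverse DFT
        # must image a point source at voxel ((i - N/2) dx, (j - N/2) dy)
        p = ScanProtocol(
            tr=5e-3, te=4e-3, matrix=(16, 16), fov=(16e-3, 16e-3),
            slice_thickness=5e-3, flip_angle=0.1, venc=0.1,
        )
        eng = _PointSourceEngine((src[0], src[1], 0.0), p.gamma_rad)
        eng.reset()
        k = acquire_kspace(eng, p, "off")
        img = reconstruct_image(k)
        j, i = np.unravel_index(np.argmax(np.abs(img)), img.shape)
        dx, dy = p.voxel_size
        assert (i - 8) * dx == pytest.approx(src[0], abs=dx / 2)
        assert (j - 8) * dy == pytest.approx(src[1], abs=dy / 2)
        # a perfect point source concentrates all energy in one voxel
        assert np.abs(img[j, i]) == pytest.approx(1.0, rel=1e-9)

    def test_point_source_kspace_is_shift_ramp(self):
        p = ScanProtocol(
            tr=5e-3, te=4e-3, matrix=(8, 8), fov=(16e-3, 16e-3),
            slice_thickness=5e-3, flip_angle=0.1, venc=0.1,
        )
        d = 2e-3  # one voxel off-centre in x
        eng = _PointSourceEngine((d, 0.0, 0.0), p.gamma_rad)
        eng.reset()
        k = acquire_kspace(eng, p, "off")
        kx = 2 * np.pi / p.fov[0] * (np.arange(8) - 4)
        np.testing.assert_allclose(k[4], np.exp(-1j * kx * d), rtol=1e-9)

    def test_zero_magnetization_gives_zero_kspace(self, small_protocol, relax):
        from pcmrisim.eulerian import EulerianEngine

        f = make_static_field()
        eng = EulerianEngine(f, relax, small_protocol)
        # suppress the RF so no transverse magnetization is ever created
        eng.excite = lambda: None
        k = acquire_kspace(eng, small_protocol, "off")
        np.testing.assert_allclose(np.abs(k), 0.0, atol=1e-18)


class TestReconstruct:
    def test_flat_kspace_is_centred_delta(self):
        img = reconstruct_image(np.ones((8, 8), complex))
        assert abs(img[4, 4]) == pytest.approx(1.0)
        off = img.copy()
        off[4, 4] = 0
        np.testing.assert_allclose(np.abs(off), 0.0, atol=1e-12)

    def test_parseval_with_backward_normalization(self):
        rng = np.random.default_rng(2)
        k = rng.normal(size=(8, 12)) + 1j * rng.normal(size=(8, 12))
        img = reconstruct_image(k)
        assert np.sum(np.abs(img) ** 2) * k.size == pytest.approx(
            np.sum(np.abs(k) ** 2), rel=1e-12
        )

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            reconstruct_image(np.ones(8, complex))


class TestVelocityFromPhase:
    def test_identical_images_give_zero(self):
        img = np.full((4, 4), 2.0 + 1.0j)
        v = velocity_from_phase(img, {"z": img.copy()}, venc=0.12)
        np.testing.assert_allclose(v.components["z"], 0.0, atol=1e-15)

    def test_linear_phase_to_velocity(self):
        ref = np.ones((3, 3), complex)
        enc = np.exp(1j * np.pi / 2) * ref
        v = velocity_from_phase(ref, {"z": enc}, venc=0.12)
        np.testing.assert_allclose(v.components["z"], 0.06, rtol=1e-12)

    def test_aliasing_wraps_to_negative(self):
        ref = np.ones((2, 2), complex)
        enc = np.exp(1j * 1.5 * np.pi) * ref  # true v = 1.5 venc
        v = velocity_from_phase(ref, {"z": enc}, venc=0.1)
        np.testing.assert_allclose(v.components["z"], -0.05, rtol=1e-12)

    def test_noise_floor_masks_voxels(self):
        ref = np.ones((2, 2), complex)
        ref[0, 0] = 1e-4
        v = velocity_from_phase(ref, {"z": ref * 1j}, venc=0.1)
        assert np.isnan(v.components["z"][0, 0])
        assert np.isfinite(v.components["z"][1, 1])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            velocity_from_phase(
                np.ones((2, 2), complex), {"z": np.ones((3, 3), complex)}, 0.1
            )


class TestIvsd:
    def test_equal_magnitudes_give_zero(self):
        i0 = np.full((2, 2), 3.0 + 0j)
        np.testing.assert_allclose(ivsd_map(i0, i0, venc=1.5), 0.0)

    def test_known_ratio(self):
        i0 = np.full((2, 2), np.exp(0.5) + 0j)
        ib = np.ones((2, 2), complex)
        got = ivsd_map(i0, ib, venc=1.5)
        np.testing.assert_allclose(got, 1.5 / np.pi, rtol=1e-12)

    def test_inverted_ratio_floors_at_zero(self):
        i0 = np.ones((2, 2), complex)
        ib = np.full((2, 2), 2.0 + 0j)
        np.testing.assert_allclose(ivsd_map(i0, ib, venc=1.5), 0.0)

    def test_gaussian_spread_signal_ratio(self):
        # Monte-Carlo spin ensemble: |E exp(i pi v / venc)| = exp(-pi^2 s^2 / 2 venc^2)
        rng = np.random.default_rng(8)
        venc, sigma = 1.5, 0.3
        v = rng.normal(0.2, sigma, size=200_000)
        ib = np.array([[np.abs(np.mean(np.exp(1j * np.pi * v / venc)))]], dtype=complex)
        i0 = np.array([[1.0 + 0j]])
        got = ivsd_map(i0, ib, venc)[0, 0]
        assert got == pytest.approx(sigma, rel=0.02)


class TestDisplacementPrediction:
    def _protocol(self, te=4e-3, tc=1e-3):
        return ScanProtocol(
            tr=6e-3, te=te, matrix=(12, 12), fov=(12e-3, 12e-3),
            slice_thickness=2e-3, flip_angle=0.1, venc=1.0, tc=tc,
        )

    def _field(self, fz):
        shape = (24, 24, 24)
        grid = GridSpec.centered([16e-3, 16e-3, 16e-3], list(shape))
        X, Y, Z = grid.meshgrid()
        return VelocityField(
            grid,
            np.zeros(shape),
            np.zeros(shape),
            fz(X, Y, Z),
            np.ones(shape, bool),
            analytic_form=lambda x, y, z: (
                np.zeros(np.shape(x)),
                np.zeros(np.shape(x)),
                fz(np.asarray(x), np.asarray(y), np.asarray(z)),
            ),
        )

    def test_uniform_field_predicts_itself(self):
        f = self._field(lambda x, y, z: np.full(np.shape(x), 0.25))
        pred = displacement_prediction(f, self._protocol())
        np.testing.assert_allclose(pred, 0.25, rtol=1e-12)

    def test_zero_field_is_identity(self):
        f = self._field(lambda x, y, z: np.zeros(np.shape(x)))
        pred = displacement_prediction(f, self._protocol())
        np.testing.assert_allclose(pred, 0.0, atol=1e-15)

    def test_linear_accelerating_field_closed_form(self):
        # v = (a x, 0, 0): streamlines x(t) = x0 exp(a t); the value a x(TC)
        # deposited at x(TE) gives the map P(X) = a X exp(-a (TE - TC))
        a = 40.0  # 1/s
        shape = (48, 8, 8)
        grid = GridSpec.centered([40e-3, 16e-3, 16e-3], list(shape))
        X, _, _ = grid.meshgrid()
        f = VelocityField(
            grid, a * X, np.zeros(shape), np.zeros(shape), np.ones(shape, bool),
            analytic_form=lambda x, y, z: (
                a * np.asarray(x, float),
                np.zeros(np.shape(x)),
                np.zeros(np.shape(x)),
            ),
        )
        p = self._protocol(te=4e-3, tc=1e-3)
        pred = displacement_prediction(
            f, p, component=0, seeds_per_voxel_axis=8, n_substeps=256
        )
        xs = (np.arange(12) - 6) * 1e-3
        expect = a * xs * np.exp(-a * (p.te - p.tc))
        row = pred[6]
        ok = np.isfinite(row)
        np.testing.assert_allclose(row[ok], expect[ok], atol=0.02 * a * 6e-3)


class TestErrorMetrics:
    def test_exact_match(self):
        v = np.random.default_rng(0).normal(size=(4, 4))
        _, mean, mx = error_metrics(v, v, vmax=0.1)
        assert mean == 0.0 and mx == 0.0

    def test_constant_bias(self):
        ref = np.zeros((5, 5))
        err, mean, mx = error_metrics(ref + 1e-3, ref, vmax=0.1)
        assert mean == pytest.approx(0.01)
        assert mx == pytest.approx(0.01)
        np.testing.assert_allclose(err, 0.01)

    def test_single_outlier(self):
        ref = np.zeros((5, 5))
        v = ref.copy()
        v[2, 2] = 5e-3
        _, mean, mx = error_metrics(v, ref, vmax=0.1)
        assert mx == pytest.approx(0.05)
        assert mean == pytest.approx(0.05 / 25)

    def test_mask_restricts_statistics(self):
        ref = np.zeros((3, 3))
        v = ref.copy()
        v[0, 0] = 1.0
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        _, mean, _ = error_metrics(v, ref, vmax=1.0, mask=mask)
        assert mean == 0.0
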