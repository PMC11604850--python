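"""k-space acquisition, image reconstruction, velocity / IVSD maps, metrics.

Image and k-space arrays are indexed ``[row, col] = [ky or y, kx or x]`` with
the frequency origin at the matrix centre (even-N convention: index N//2).
The inverse DFT uses the backward 1/(Nx*Ny) normalization, so Parseval reads
``sum |image|^2 = sum |k|^2 / (Nx*Ny)``.  Voxel (row j, col i) maps to the
spatial position ``((i - Nx//2) * Lx/Nx, (j - Ny//2) * Ly/Ny)`` relative to
the FOV centre (the gradient isocentre by default).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np

from .phantoms import GridSpec, VelocityField
from .sequence import ScanProtocol, build_segment

__all__ = [
    "KSpaceSet",
    "VelocityImage",
    "sample_signal",
    "acquire_kspace",
    "reconstruct_image",
    "velocity_from_phase",
    "ivsd_map",
    "displacement_prediction",
    "error_metrics",
    "image_grid_for",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclasses.dataclass
class KSpaceSet:
    """Complex k-space matrices per velocity-encoding segment."""

    data: Dict[str, np.ndarray]  # label -> (Ny, Nx) complex
    protocol: ScanProtocol
    sample_times: np.ndarray

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) > 1:
            raise ValueError("all k-space matrices must share one shape")

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for label, arr in self.data.items():
                f.create_dataset(f"kspace/{label}", data=arr)
            f.create_dataset("sample_times", data=self.sample_times)
            g = f.create_group("protocol")
            for k, v in dataclasses.asdict(self.protocol).items():
                g.attrs[k] = v if not isinstance(v, tuple) else list(v)

    @staticmethod
    def load_h5(path) -> dict:
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for label in f["kspace"]:
                out[label] = f[f"kspace/{label}"][()]
        return out


@dataclasses.dataclass
class VelocityImage:
    """Reconstructed per-voxel velocity components plus magnitude (and IVSD)."""

    components: Dict[str, np.ndarray]  # 'x'/'y'/'z' -> (Ny, Nx), m/s (NaN = masked)
    magnitude: np.ndarray
    venc: float
    ivsd: Optional[Dict[str, np.ndarray]] = None


def sample_signal(state_or_engine, mask=None) -> complex:
    """Volume integral of the transverse magnetization as a complex number.

    Dispatches on the backend: fixed-grid states integrate Mr(cos phi, sin phi)
    by trapezoidal (cell-linear) quadrature; particle ensembles sum
    Mr * exp(i phi) * particle volume.
    """
    from .eulerian import EulerianState, _signal_sum
    from .lagrangian import ParticleEnsemble, _particle_signal

    if hasattr(state_or_engine, "sample") and not isinstance(
        state_or_engine, (EulerianState, ParticleEnsemble)
    ):
        return state_or_engine.sample()
    if isinstance(state_or_engine, EulerianState):
        st = state_or_engine
        w = 1.0
        grid = st.grid
        for axis in range(3):
            wa = np.ones(grid.shape[axis])
            if grid.shape[axis] > 1:
                wa[0] = wa[-1] = 0.5
            wa = wa * grid.spacing[axis]
            w = np.multiply.outer(w, wa) if axis else wa
        mr = st.mr if mask is None else st.mr * mask
        sre, sim = _signal_sum(
            np.ascontiguousarray(mr).ravel(),
            np.ascontiguousarray(st.phi).ravel(),
            np.ascontiguousarray(w.reshape(tuple(grid.shape))).ravel(),
        )
        return complex(sre, sim)
    if isinstance(state_or_engine, ParticleEnsemble):
        ens = state_or_engine
        mr = ens.mr if mask is None else ens.mr * mask
        sre, sim = _particle_signal(
            np.ascontiguousarray(mr), ens.phi, ens.particle_volume
        )
        return complex(sre, sim)
    raise TypeError(f"cannot sample signal from {type(state_or_engine)!r}")


def acquire_kspace(
    engine,
    protocol: ScanProtocol,
    bpg_state: str = "off",
    reinitialize_per_tr: bool = False,
    reset: bool = True,
) -> np.ndarray:
    """Acquire one full sequentially ordered k-space matrix (Ny, Nx).

    For every phase line: RF excitation at the start of the TR, integration
    through the encode and readout events with Nx samples at the sampling
    pitch centred on TE, then ideal spoiling.  Under ``reinitialize_per_tr``
    the whole backend state (positions included, for particles) is restored to
    its steady-state initial condition before each repetition.
    """
    nx, ny = protocol.matrix
    k = np.empty((ny, nx), dtype=complex)
    lines = protocol.line_indices()
    if reset:
        engine.reset()
    for row, line in enumerate(lines):
        if reinitialize_per_tr:
            engine.reset()
        segment = build_segment(protocol, int(line), bpg_state)
        engine.excite()
        times = segment.breakpoints()
        sample_times = segment.sample_times
        si = 0
        for t0, t1 in zip(times[:-1], times[1:]):
            try:
                engine.run_interval(segment, t0, t1)
            except FloatingPointError as exc:
                raise type(exc)(f"phase line {line}: {exc}") from exc
            while si < nx and abs(sample_times[si] - t1) < 1e-12:
                k[row, si] = engine.sample()
                si += 1
        if si != nx:
            raise RuntimeError(
                f"line {line}: only {si}/{nx} readout samples were hit"
            )
        engine.spoil()
    return k


def reconstruct_image(k: np.ndarray) -> np.ndarray:
    """Centred 2-D inverse DFT of one k-space matrix."""
    k = np.asarray(k)
    if k.ndim != 2:
        raise ValueError("k-space matrix must be 2-D")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k)))


def image_grid_for(
    protocol: ScanProtocol, fov_center: tuple[float, float] = (0.0, 0.0)
) -> GridSpec:
    """Voxel-centre lattice of the reconstructed image (z = slice centre,
    z-spacing = slice thickness)."""
    nx, ny = protocol.matrix
    dx, dy = protocol.voxel_size
    return GridSpec(
        origin=(
            fov_center[0] - (nx // 2) * dx,
            fov_center[1] - (ny // 2) * dy,
            protocol.slice_center,
        ),
        spacing=(dx, dy, protocol.slice_thickness),
        shape=(nx, ny, 1),
    )


def velocity_from_phase(
    reference: np.ndarray,
    encoded: Dict[str, np.ndarray],
    venc: float,
    noise_floor: float = 0.01,
) -> VelocityImage:
    """Phase-difference velocity reconstruction (two- or four-point).

    v_d = venc * wrap(arg(encoded_d) - arg(reference)) / pi per direction d;
    the wrap maps phase differences to (-pi, pi], so true velocities beyond
    venc alias with period 2 venc.  Voxels whose reference magnitude falls
    below ``noise_floor`` times the maximum are masked (NaN), not extrapolated.
    """
    mag = np.abs(reference)
    bad = mag < noise_floor * mag.max()
    comps = {}
    for d, enc in encoded.items():
        if enc.shape != reference.shape:
            raise ValueError("encoded/reference image shape mismatch")
        dphi = np.angle(enc * np.conj(reference))
        v = venc * dphi / np.pi
        v[bad] = np.nan
        comps[d] = v
    return VelocityImage(components=comps, magnitude=mag, venc=venc)


def ivsd_map(
    reference: np.ndarray, encoded: np.ndarray, venc: float, noise_floor: float = 0.01
) -> np.ndarray:
    """Intravoxel velocity SD from the magnitude ratio of the compensated and
    velocity-encoded signals under a Gaussian intravoxel velocity model:

        IVSD = (venc / pi) * sqrt(2 ln(|I0| / |I_BPG|)),

    floored at zero where |I_BPG| > |I0| and masked (NaN) where either
    magnitude is below the noise floor.
    """
    m0 = np.abs(reference)
    mb = np.abs(encoded)
    floor = noise_floor * m0.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(m0 / mb)
    ratio = np.clip(ratio, 0.0, None)
    out = (venc / np.pi) * np.sqrt(2.0 * ratio)
    out[(m0 < floor) | (mb <= 0)] = np.nan
    return out


def displacement_prediction(
    field: VelocityField,
    protocol: ScanProtocol,
    fov_center: tuple[float, float] = (0.0, 0.0),
    component: int = 2,
    seeds_per_voxel_axis: int = 4,
    n_substeps: int = 64,
) -> np.ndarray:
    """Theory-predicted displaced velocity map.

    Seed points tiling the excited slab are traced through the (steady) flow
    field; the velocity sampled at the seed's position at TC is deposited at
    its in-plane position at TE and voxel-averaged, which predicts where the
    scan will display each velocity value.  Voxels receiving no magnetization
    are NaN.
    """
    if not protocol.tc < protocol.te:
        raise ValueError("displacement prediction requires TC < TE")
    from .lagrangian import interpolate_velocity

    nx, ny = protocol.matrix
    dx, dy = protocol.voxel_size
    m = seeds_per_voxel_axis
    # voxel i is centred at (i - N//2) * d and spans +- d/2 about that
    xs = fov_center[0] + ((np.arange(nx * m) + 0.5) / m - nx // 2 - 0.5) * dx
    ys = fov_center[1] + ((np.arange(ny * m) + 0.5) / m - ny // 2 - 0.5) * dy
    nz = max(2, m)
    zs = protocol.slice_center + protocol.slice_thickness * (
        (np.arange(nz) + 0.5) / nz - 0.5
    )
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pos = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = field.inside(pos[:, 0], pos[:, 1], pos[:, 2])
    pos = pos[inside]
    if len(pos) == 0:
        return np.full((ny, nx), np.nan)

    if field.analytic_form is not None:
        def vel(p):
            vx, vy, vz = field.analytic_form(p[:, 0], p[:, 1], p[:, 2])
            return np.stack([vx, vy, vz], axis=1)
    else:
        vel = lambda p: interpolate_velocity(field, p)

    def rk4(p, t_end):
        dt = t_end / n_substeps
        for _ in range(n_substeps):
            k1 = vel(p)
            k2 = vel(p + 0.5 * dt * k1)
            k3 = vel(p + 0.5 * dt * k2)
            k4 = vel(p + dt * k3)
            p = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        return p

    p_tc = rk4(pos, protocol.tc)
    v_tc = vel(p_tc)[:, component]
    p_te = rk4(p_tc, protocol.te - protocol.tc)

    ix = np.floor((p_te[:, 0] - fov_center[0]) / dx + nx // 2 + 0.5).astype(int)
    iy = np.floor((p_te[:, 1] - fov_center[1]) / dy + ny // 2 + 0.5).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    acc = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx))
    np.add.at(acc, (iy[ok], ix[ok]), v_tc[ok])
    np.add.at(cnt, (iy[ok], ix[ok]), 1.0)
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    out[cnt == 0] = np.nan
    return out


def error_metrics(
    v_mri: np.ndarray,
    reference: np.ndarray,
    vmax: float,
    mask: Optional[np.ndarray] = None,
):
    """Per-voxel normalized velocity error (v_MRI - v_ref) / vmax, and the mean
    and max of its absolute value over the evaluation mask."""
    v_mri = np.asarray(v_mri, float)
    reference = np.asarray(reference, float)
    if v_mri.shape != reference.shape:
        raise ValueError("velocity/reference lattice shapes differ")
    err = (v_mri - reference) / vmax
    if mask is None:
        mask = np.isfinite(err)
    else:
        mask = mask & np.isfinite(err)
    abs_err = np.abs(err[mask])
    if abs_err.size == 0:
        return err, np.nan, np.nan
    return err, float(abs_err.mean()), float(abs_err.max())


def lumen_evaluation_mask(
    field: VelocityField,
    protocol: ScanProtocol,
    fov_center: tuple[float, float] = (0.0, 0.0),
    interior_only: bool = True,
) -> np.ndarray:
    """(Ny, Nx) mask of voxels whose centres lie in spin-bearing fluid and (by
    default) whose full in-plane extent does too — the partial-volume rim at
    the lumen wall and the empty FOV margin outside the computational domain
    are excluded from error statistics."""
    grid = image_grid_for(protocol, fov_center)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    z = protocol.slice_center
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    g = field.grid
    hull = lambda x, y: (
        (x >= g.lower[0] - g.spacing[0] / 2)
        & (x <= g.upper[0] + g.spacing[0] / 2)
        & (y >= g.lower[1] - g.spacing[1] / 2)
        & (y <= g.upper[1] + g.spacing[1] / 2)
    )
    inside = lambda x, y: (
        np.asarray(field.inside(x, y, np.full_like(np.asarray(x, float), z)), bool)
        & hull(x, y)
    )
    mask = inside(X, Y)
    if interior_only:
        dx, dy = protocol.voxel_size
        for sx in (-0.5, 0.5):
            for sy in (-0.5, 0.5):
                mask &= inside(X + sx * dx, Y + sy * dy)
    return mask
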