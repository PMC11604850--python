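"""Particle-based reference backend: magnetization-carrying tracers.

Massless particles seeded uniformly at random over the fluid domain carry
(Mz, Mr, phi) and move with the trilinearly interpolated background velocity:

    dx/dt  = v(x, t)
    dMz/dt = (M0 - Mz)/T1,  dMr/dt = -Mr/T2,  dphi/dt = -gamma_rad Bz(x, t)

integrated with the same fixed-step Dormand-Prince stage combination as the
fixed-grid backend, with position and phase updated stage-synchronously.
Particles are never created or destroyed; those leaving the velocity-grid
hull coast with the clamped boundary velocity and are counted.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numba
import numpy as np

from .phantoms import VelocityField
from .sequence import EncodingSegment

__all__ = [
    "ParticleEnsemble",
    "seed_particles",
    "interpolate_velocity",
    "advance_particles",
    "LagrangianEngine",
]


@dataclasses.dataclass
class ParticleEnsemble:
    """Positions (N, 3) plus per-particle magnetization attributes."""

    positions: np.ndarray
    mz: np.ndarray
    mr: np.ndarray
    phi: np.ndarray
    particle_volume: float
    rng_seed: int
    time: float = 0.0
    clamped_steps: int = 0
    static: Optional[np.ndarray] = None  # spins whose interpolated velocity is 0

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n == 0:
            raise ValueError("ensemble must contain at least one particle")
        for name in ("mz", "mr", "phi"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n(self) -> int:
        return len(self.positions)

    def to_dataframe(self):
        """Columnar snapshot (x, y, z, mz, mr, phi) for export/inspection."""
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "mz": self.mz,
                "mr": self.mr,
                "phi": self.phi,
            }
        )

    def export(self, path) -> None:
        """Write the snapshot as CSV (.csv) or HDF5 (anything else)."""
        df = self.to_dataframe()
        if str(path).endswith(".csv"):
            df.to_csv(path, index=False)
        else:
            import h5py

            with h5py.File(path, "w") as f:
                for col in df.columns:
                    f.create_dataset(col, data=df[col].to_numpy())
                f.attrs["particle_volume"] = self.particle_volume
                f.attrs["rng_seed"] = self.rng_seed

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(
            self.positions.copy(),
            self.mz.copy(),
            self.mr.copy(),
            self.phi.copy(),
            self.particle_volume,
            self.rng_seed,
            self.time,
            self.clamped_steps,
            None if self.static is None else self.static.copy(),
        )


def seed_particles(
    field: VelocityField,
    density: float,
    voxel_volume: float,
    seed: int,
    bounds: Optional[tuple] = None,
    initial_mz: float = 0.0,
    fluid_only: bool = False,
    stratified: bool = False,
) -> ParticleEnsemble:
    """Uniform-random seeding over the spin-bearing domain.

    With ``stratified=True`` positions are drawn as a jittered near-cubic
    lattice instead (one particle per cell); the default is plain uniform
    sampling.

    ``round(density * V / voxel_volume)`` positions are drawn uniformly over
    the grid hull (intersected with ``bounds`` when given) with a
    counter-based Philox generator, so the expected particle count per image
    voxel is ``density``.  The whole rectangular domain carries spins — the
    material outside the lumen is simply static; pass ``fluid_only=True`` to
    restrict seeding to the lumen instead.  The particle volume is
    voxel_volume / density.
    """
    if density < 1:
        raise ValueError("density must be >= 1 particle per voxel")
    grid = field.grid
    lo = np.array(grid.lower) - np.array(grid.spacing) / 2
    hi = np.array(grid.upper) + np.array(grid.spacing) / 2
    if bounds is not None:
        blo, bhi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
        lo, hi = np.maximum(lo, blo), np.minimum(hi, bhi)
    vol = float(np.prod(hi - lo))
    if vol <= 0:
        raise ValueError("seeding domain has zero volume")
    n_draw = int(round(density * vol / voxel_volume))
    rng = np.random.Generator(np.random.Philox(seed))
    if stratified:
        # jittered lattice: one particle per near-cubic cell, reducing the
        # shot noise of the per-voxel particle count
        target = (n_draw / vol) ** (1.0 / 3.0)
        counts = np.maximum(1, np.round((hi - lo) * target).astype(int))
        cells = np.stack(
            np.meshgrid(*(np.arange(c) for c in counts), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        width = (hi - lo) / counts
        pts = lo + (cells + rng.random(cells.shape)) * width
    else:
        pts = lo + (hi - lo) * rng.random((n_draw, 3))
    if fluid_only:
        keep = field.inside(pts[:, 0], pts[:, 1], pts[:, 2])
        pts = pts[keep]
    pts = np.ascontiguousarray(pts)
    n = len(pts)
    return ParticleEnsemble(
        positions=pts,
        mz=np.full(n, float(initial_mz)),
        mr=np.zeros(n),
        phi=np.zeros(n),
        particle_volume=voxel_volume / density,
        rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# trilinear interpolation
# ---------------------------------------------------------------------------


@numba.njit(inline="always")
def _cell(x, o, h, n):
    f = (x - o) / h
    if f < 0.0:
        f = 0.0
    elif f > n - 1.0:
        f = n - 1.0
    i = int(f)
    if i > n - 2:
        i = n - 2
    return i, f - i


@numba.njit(inline="always")
def _trilerp(v, i, tx, j, ty, k, tz):
    c00 = v[i, j, k] * (1 - tx) + v[i + 1, j, k] * tx
    c10 = v[i, j + 1, k] * (1 - tx) + v[i + 1, j + 1, k] * tx
    c01 = v[i, j, k + 1] * (1 - tx) + v[i + 1, j, k + 1] * tx
    c11 = v[i, j + 1, k + 1] * (1 - tx) + v[i + 1, j + 1, k + 1] * tx
    return (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (c01 * (1 - ty) + c11 * ty) * tz


def interpolate_velocity(field: VelocityField, positions: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of each velocity component at (N, 3) positions.

    Positions outside the grid hull are clamped to the boundary value.
    """
    pos = np.atleast_2d(np.asarray(positions, float))
    grid = field.grid
    out = np.empty((len(pos), 3))
    idx, frac = [], []
    for a in range(3):
        f = (pos[:, a] - grid.origin[a]) / grid.spacing[a]
        f = np.clip(f, 0.0, grid.shape[a] - 1.0)
        i = np.minimum(f.astype(int), max(grid.shape[a] - 2, 0))
        idx.append(i)
        frac.append(f - i)
    i, j, k = idx
    tx, ty, tz = frac
    for c, comp in enumerate(field.components):
        c00 = comp[i, j, k] * (1 - tx) + comp[i + 1, j, k] * tx
        c10 = comp[i, j + 1, k] * (1 - tx) + comp[i + 1, j + 1, k] * tx
        c01 = comp[i, j, k + 1] * (1 - tx) + comp[i + 1, j, k + 1] * tx
        c11 = comp[i, j + 1, k + 1] * (1 - tx) + comp[i + 1, j + 1, k + 1] * tx
        out[:, c] = (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (
            c01 * (1 - ty) + c11 * ty
        ) * tz
    return out


# ---------------------------------------------------------------------------
# fixed-step Dormand-Prince particle kernel (constant gradient per interval)
# ---------------------------------------------------------------------------

_A21 = 1 / 5
_A31, _A32 = 3 / 40, 9 / 40
_A41, _A42, _A43 = 44 / 45, -56 / 15, 32 / 9
_A51, _A52, _A53, _A54 = 19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729
_A61, _A62, _A63, _A64, _A65 = (
    9017 / 3168,
    -355 / 33,
    46732 / 5247,
    49 / 176,
    -5103 / 18656,
)
_B1, _B3, _B4, _B5, _B6 = 35 / 384, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84


@numba.njit(fastmath=True, error_model="numpy")
def _advance_kernel(
    px, py, pz, pmz, pmr, pphi, static,
    vx, vy, vz, use_x, use_y, use_z,
    ox, oy, oz, hx, hy, hz, nx, ny, nz,
    gx, gy, gz, gamma_rad, m0, inv_t1, inv_t2,
    dt, nsub,
):
    n = px.size
    n_clamped = 0
    t_total = dt * nsub
    e1 = math.exp(-t_total * inv_t1)
    e2 = math.exp(-t_total * inv_t2)
    for p in range(n):
        if static[p]:
            # static spins never move; relaxation is applied in closed form
            # and the constant-Bz phase accrues linearly
            pphi[p] += t_total * (-gamma_rad) * (gx * px[p] + gy * py[p] + gz * pz[p])
            pmz[p] = m0 + (pmz[p] - m0) * e1
            pmr[p] *= e2
            continue
        x, y, z = px[p], py[p], pz[p]
        mzv, mrv, phv = pmz[p], pmr[p], pphi[p]
        for _ in range(nsub):
            kx = np.empty(6)
            ky = np.empty(6)
            kz = np.empty(6)
            kp = np.empty(6)
            kmz = np.empty(6)
            kmr = np.empty(6)
            xs, ys, zs = x, y, z
            mzs, mrs = mzv, mrv
            for s in range(6):
                if s == 1:
                    c1 = _A21
                    xs = x + dt * c1 * kx[0]
                    ys = y + dt * c1 * ky[0]
                    zs = z + dt * c1 * kz[0]
                    mzs = mzv + dt * c1 * kmz[0]
                    mrs = mrv + dt * c1 * kmr[0]
                elif s == 2:
                    xs = x + dt * (_A31 * kx[0] + _A32 * kx[1])
                    ys = y + dt * (_A31 * ky[0] + _A32 * ky[1])
                    zs = z + dt * (_A31 * kz[0] + _A32 * kz[1])
                    mzs = mzv + dt * (_A31 * kmz[0] + _A32 * kmz[1])
                    mrs = mrv + dt * (_A31 * kmr[0] + _A32 * kmr[1])
                elif s == 3:
                    xs = x + dt * (_A41 * kx[0] + _A42 * kx[1] + _A43 * kx[2])
                    ys = y + dt * (_A41 * ky[0] + _A42 * ky[1] + _A43 * ky[2])
                    zs = z + dt * (_A41 * kz[0] + _A42 * kz[1] + _A43 * kz[2])
                    mzs = mzv + dt * (_A41 * kmz[0] + _A42 * kmz[1] + _A43 * kmz[2])
                    mrs = mrv + dt * (_A41 * kmr[0] + _A42 * kmr[1] + _A43 * kmr[2])
                elif s == 4:
                    xs = x + dt * (_A51 * kx[0] + _A52 * kx[1] + _A53 * kx[2] + _A54 * kx[3])
                    ys = y + dt * (_A51 * ky[0] + _A52 * ky[1] + _A53 * ky[2] + _A54 * ky[3])
                    zs = z + dt * (_A51 * kz[0] + _A52 * kz[1] + _A53 * kz[2] + _A54 * kz[3])
                    mzs = mzv + dt * (_A51 * kmz[0] + _A52 * kmz[1] + _A53 * kmz[2] + _A54 * kmz[3])
                    mrs = mrv + dt * (_A51 * kmr[0] + _A52 * kmr[1] + _A53 * kmr[2] + _A54 * kmr[3])
                elif s == 5:
                    xs = x + dt * (_A61 * kx[0] + _A62 * kx[1] + _A63 * kx[2] + _A64 * kx[3] + _A65 * kx[4])
                    ys = y + dt * (_A61 * ky[0] + _A62 * ky[1] + _A63 * ky[2] + _A64 * ky[3] + _A65 * ky[4])
                    zs = z + dt * (_A61 * kz[0] + _A62 * kz[1] + _A63 * kz[2] + _A64 * kz[3] + _A65 * kz[4])
                    mzs = mzv + dt * (_A61 * kmz[0] + _A62 * kmz[1] + _A63 * kmz[2] + _A64 * kmz[3] + _A65 * kmz[4])
                    mrs = mrv + dt * (_A61 * kmr[0] + _A62 * kmr[1] + _A63 * kmr[2] + _A64 * kmr[3] + _A65 * kmr[4])
                i, tx = _cell(xs, ox, hx, nx)
                j, ty = _cell(ys, oy, hy, ny)
                k, tz = _cell(zs, oz, hz, nz)
                kx[s] = _trilerp(vx, i, tx, j, ty, k, tz) if use_x else 0.0
                ky[s] = _trilerp(vy, i, tx, j, ty, k, tz) if use_y else 0.0
                kz[s] = _trilerp(vz, i, tx, j, ty, k, tz) if use_z else 0.0
                kp[s] = -gamma_rad * (gx * xs + gy * ys + gz * zs)
                kmz[s] = (m0 - mzs) * inv_t1
                kmr[s] = -mrs * inv_t2
            x += dt * (_B1 * kx[0] + _B3 * kx[2] + _B4 * kx[3] + _B5 * kx[4] + _B6 * kx[5])
            y += dt * (_B1 * ky[0] + _B3 * ky[2] + _B4 * ky[3] + _B5 * ky[4] + _B6 * ky[5])
            z += dt * (_B1 * kz[0] + _B3 * kz[2] + _B4 * kz[3] + _B5 * kz[4] + _B6 * kz[5])
            phv += dt * (_B1 * kp[0] + _B3 * kp[2] + _B4 * kp[3] + _B5 * kp[4] + _B6 * kp[5])
            mzv += dt * (_B1 * kmz[0] + _B3 * kmz[2] + _B4 * kmz[3] + _B5 * kmz[4] + _B6 * kmz[5])
            mrv += dt * (_B1 * kmr[0] + _B3 * kmr[2] + _B4 * kmr[3] + _B5 * kmr[4] + _B6 * kmr[5])
        if (
            x < ox or x > ox + hx * (nx - 1)
            or y < oy or y > oy + hy * (ny - 1)
            or z < oz or z > oz + hz * (nz - 1)
        ):
            n_clamped += 1
        px[p], py[p], pz[p] = x, y, z
        pmz[p], pmr[p], pphi[p] = mzv, mrv, phv
    return n_clamped


@numba.njit(fastmath=True, error_model="numpy")
def _particle_signal(mr, phi, dv):
    sre = 0.0
    sim = 0.0
    for p in range(mr.size):
        m = mr[p]
        if m != 0.0:
            sre += m * math.cos(phi[p])
            sim += m * math.sin(phi[p])
    return sre * dv, sim * dv


def advance_particles(
    ens: ParticleEnsemble,
    field: VelocityField,
    segment: Optional[EncodingSegment],
    relax,
    t0: float,
    t1: float,
    courant: float = 0.5,
    gamma_rad: float = 2 * np.pi * 42.58e6,
) -> ParticleEnsemble:
    """Advance the ensemble from t0 to t1 (in place; also returned).

    The interval is split at gradient-lobe edges; within each sub-interval the
    gradient vector is constant and fixed Dormand-Prince steps bounded by the
    advective CFL limit of the underlying grid are taken.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    grid = field.grid
    vmax = field.max_speed_per_axis()
    dt_cfl = np.inf
    for axis in range(3):
        if vmax[axis] > 0:
            dt_cfl = min(dt_cfl, courant * grid.spacing[axis] / vmax[axis])
    # resolve relaxation of the moving spins even when advection permits
    # large steps (static spins take a closed-form path regardless)
    dt_cfl = min(dt_cfl, relax.t2 / 5.0)

    edges = [t0, t1]
    if segment is not None:
        for ev in segment.events:
            for t in (ev.start, ev.stop):
                if t0 < t < t1:
                    edges.append(t)
    edges = sorted(set(edges))

    pos = ens.positions
    use = vmax > 0
    if ens.static is None:
        # a spin with zero interpolated velocity never moves, hence stays static
        v = interpolate_velocity(field, pos)
        ens.static = np.ascontiguousarray((v == 0.0).all(axis=1).astype(np.uint8))
    for ta, tb in zip(edges[:-1], edges[1:]):
        g = segment.gradient_vector(0.5 * (ta + tb)) if segment is not None else np.zeros(3)
        nsub = max(1, int(math.ceil((tb - ta) / dt_cfl))) if np.isfinite(dt_cfl) else 1
        dt = (tb - ta) / nsub
        ens.clamped_steps += _advance_kernel(
            pos[:, 0], pos[:, 1], pos[:, 2], ens.mz, ens.mr, ens.phi, ens.static,
            field.vx, field.vy, field.vz, use[0], use[1], use[2],
            grid.origin[0], grid.origin[1], grid.origin[2],
            grid.spacing[0], grid.spacing[1], grid.spacing[2],
            grid.shape[0], grid.shape[1], grid.shape[2],
            g[0], g[1], g[2], gamma_rad, relax.m0, 1.0 / relax.t1, 1.0 / relax.t2,
            dt, nsub,
        )
    ens.time = t1
    if not (
        np.isfinite(ens.mz).all()
        and np.isfinite(ens.mr).all()
        and np.isfinite(ens.phi).all()
        and np.isfinite(pos).all()
    ):
        raise FloatingPointError(f"non-finite particle state at t = {t1:.6e} s")
    return ens


# ---------------------------------------------------------------------------
# scan-facing engine
# ---------------------------------------------------------------------------


class LagrangianEngine:
    """Stateful particle backend driving a scan.

    Seeds ``density`` particles per image voxel over the fluid domain
    (restricted to ``seed_bounds`` when margins are configured) with the
    saturated steady-state longitudinal magnetization.
    """

    name = "lagrangian"

    def __init__(
        self,
        field: VelocityField,
        relax,
        protocol,
        density: float,
        seed: int,
        seed_bounds: Optional[tuple] = None,
        courant: float = 0.5,
        fov_center: tuple[float, float] = (0.0, 0.0),
    ):
        from .sequence import saturation_magnetization

        self.field = field
        self.relax = relax
        self.protocol = protocol
        self.courant = courant
        self.fov_center = fov_center
        self.ms = saturation_magnetization(
            relax.m0, protocol.tr, relax.t1, protocol.flip_angle
        )
        dx, dy = protocol.voxel_size
        voxel_volume = dx * dy * protocol.slice_thickness
        self._initial = seed_particles(
            field,
            density,
            voxel_volume,
            seed,
            bounds=seed_bounds,
            initial_mz=self.ms,
        )
        self.ens = self._initial.copy()

    def reset(self) -> None:
        self.ens = self._initial.copy()

    def _fov_mask(self) -> np.ndarray:
        p = self.protocol
        pos = self.ens.positions
        lx, ly = p.fov
        return (
            (np.abs(pos[:, 0] - self.fov_center[0]) <= lx / 2)
            & (np.abs(pos[:, 1] - self.fov_center[1]) <= ly / 2)
            & (np.abs(pos[:, 2] - p.slice_center) <= p.slice_thickness / 2)
        )

    def excite(self) -> None:
        m = self._fov_mask()
        alpha = self.protocol.flip_angle
        mz = self.ens.mz
        self.ens.mr = np.where(m, mz * np.sin(alpha), self.ens.mr)
        self.ens.phi = np.where(m, 0.0, self.ens.phi)
        self.ens.mz = np.where(m, mz * np.cos(alpha), mz)

    def spoil(self) -> None:
        self.ens.mr = np.zeros_like(self.ens.mr)
        self.ens.phi = np.zeros_like(self.ens.phi)

    def run_interval(self, segment: EncodingSegment, t0: float, t1: float) -> None:
        advance_particles(
            self.ens,
            self.field,
            segment,
            self.relax,
            t0,
            t1,
            courant=self.courant,
            gamma_rad=self.protocol.gamma_rad,
        )

    def sample(self) -> complex:
        sre, sim = _particle_signal(
            self.ens.mr, self.ens.phi, self.ens.particle_volume
        )
        return complex(sre, sim)

    def snapshot(self):
        return self.ens.copy()

    def restore(self, snap) -> None:
        self.ens = snap.copy()
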