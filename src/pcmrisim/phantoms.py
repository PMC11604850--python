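"""Flow phantoms: geometries, prescribed velocity fields, and voxel-averaged references.

All quantities are SI (metres, seconds, m/s).  Velocity lattices are indexed
``[ix, iy, iz]``; the static magnetic field and the main flow direction are
both along z unless a geometry says otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "GridSpec",
    "CylinderGeometry",
    "StenosisGeometry",
    "VelocityField",
    "poiseuille_field",
    "stenosis_radius",
    "stenosis_radius_slope",
    "synthetic_stenotic_field",
    "add_solenoidal_perturbation",
    "voxel_average_reference",
    "divergence",
    "export_nifti",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class DomainError(ValueError):
    """Raised when a geometry is incompatible with the computational grid."""


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Rectangular Cartesian node lattice.

    Nodes sit at ``origin + i * spacing`` per axis.  The finite-difference
    advection stencil needs at least 4 nodes on any axis it acts along.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @classmethod
    def centered(
        cls,
        extent: Sequence[float],
        shape: Sequence[int],
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "GridSpec":
        """Cell-centred lattice of ``shape`` nodes spanning ``extent`` about ``center``."""
        spacing = tuple(e / n for e, n in zip(extent, shape))
        origin = tuple(
            c - e / 2 + h / 2 for c, e, h in zip(center, extent, spacing)
        )
        return cls(origin, spacing, tuple(int(n) for n in shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    @property
    def lower(self) -> tuple[float, float, float]:
        return self.origin

    @property
    def upper(self) -> tuple[float, float, float]:
        return tuple(
            self.origin[a] + self.spacing[a] * (self.shape[a] - 1) for a in range(3)
        )

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))


@dataclasses.dataclass(frozen=True)
class CylinderGeometry:
    """Straight circular cylinder, axis-aligned."""

    radius_r0: float
    axial_length: float
    axis: str = "z"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_r0 <= 0:
            raise ValueError("radius_r0 must be positive")
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}")


@dataclasses.dataclass(frozen=True)
class StenosisGeometry:
    """Axisymmetric cylinder (axis z) with a smooth cosine constriction at z = 0.

    The lumen radius is the reference radius ``rhat0`` away from the throat and
    narrows to ``0.5 * rhat0`` at ``z = 0`` over the characteristic length ``L``
    (one diameter, ``L = 2 * rhat0``, on either side).
    """

    reference_radius_rhat0: float
    characteristic_length_L: float
    anterior_extent: float = 0.0  # 0 -> default 2 L
    posterior_extent: float = 0.0  # 0 -> default 13 L
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.reference_radius_rhat0 <= 0 or self.characteristic_length_L <= 0:
            raise ValueError("stenosis radii and lengths must be positive")
        if self.anterior_extent == 0.0:
            object.__setattr__(self, "anterior_extent", 2 * self.characteristic_length_L)
        if self.posterior_extent == 0.0:
            object.__setattr__(self, "posterior_extent", 13 * self.characteristic_length_L)

    def lumen_radius_profile(self, z: np.ndarray) -> np.ndarray:
        return stenosis_radius(z, self)


@dataclasses.dataclass
class VelocityField:
    """Divergence-free 3-D vector field sampled on a Cartesian node lattice.

    ``analytic_form(x, y, z) -> (vx, vy, vz)`` (broadcastable) is kept when an
    exact expression exists; samplers prefer it over trilinear interpolation.
    ``lumen_form(x, y, z) -> bool array`` is the exact lumen membership test.
    """

    grid: GridSpec
    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    lumen_mask: np.ndarray
    analytic_form: Optional[Callable] = None
    lumen_form: Optional[Callable] = None

    def __post_init__(self) -> None:
        shape = tuple(self.grid.shape)
        for name in ("vx", "vy", "vz", "lumen_mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")

    @property
    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.vx, self.vy, self.vz

    def max_speed_per_axis(self) -> np.ndarray:
        return np.array(
            [np.abs(self.vx).max(), np.abs(self.vy).max(), np.abs(self.vz).max()]
        )

    def inside(self, x, y, z) -> np.ndarray:
        """Lumen membership, exact where a closed form is known."""
        if self.lumen_form is not None:
            return np.asarray(self.lumen_form(x, y, z), dtype=bool)
        # fall back to nearest-node lookup of the mask
        idx = []
        for axis, c in enumerate((x, y, z)):
            i = np.rint(
                (np.asarray(c) - self.grid.origin[axis]) / self.grid.spacing[axis]
            ).astype(int)
            idx.append(np.clip(i, 0, self.grid.shape[axis] - 1))
        return self.lumen_mask[tuple(idx)]


def poiseuille_field(
    geom: CylinderGeometry, vmax: float, grid: GridSpec
) -> VelocityField:
    """Fully developed laminar pipe flow: parabolic axial profile, no-slip wall.

    The axial component is ``vmax * (1 - (r / r0)**2)`` inside the lumen and
    zero outside; the cross-axial components vanish identically.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    ax = _AXES[geom.axis]
    t1, t2 = [a for a in range(3) if a != ax]
    # the lumen must overlap the grid cross-section: either the cylinder sits
    # inside the domain (wall resolved in the image) or the domain is a window
    # inside a wider pipe (only the core flow is imaged); a lumen missing the
    # domain entirely is a configuration mistake
    for t in (t1, t2):
        lo = grid.lower[t] - grid.spacing[t] / 2
        hi = grid.upper[t] + grid.spacing[t] / 2
        if geom.center[t] + geom.radius_r0 < lo or geom.center[t] - geom.radius_r0 > hi:
            raise DomainError("cylinder lumen does not intersect the grid domain")

    c = geom.center
    r0 = geom.radius_r0

    def analytic(x, y, z):
        coords = (np.asarray(x, float), np.asarray(y, float), np.asarray(z, float))
        r2 = (coords[t1] - c[t1]) ** 2 + (coords[t2] - c[t2]) ** 2
        va = np.where(r2 < r0**2, vmax * (1.0 - r2 / r0**2), 0.0)
        out = [np.zeros(np.broadcast(*coords).shape) for _ in range(3)]
        out[ax] = va
        return tuple(out)

    def lumen(x, y, z):
        coords = (np.asarray(x, float), np.asarray(y, float), np.asarray(z, float))
        return (coords[t1] - c[t1]) ** 2 + (coords[t2] - c[t2]) ** 2 < r0**2

    X, Y, Z = grid.meshgrid()
    comps = analytic(X, Y, Z)
    return VelocityField(
        grid,
        *(np.ascontiguousarray(v) for v in comps),
        lumen_mask=lumen(X, Y, Z),
        analytic_form=analytic,
        lumen_form=lumen,
    )


def stenosis_radius(z, geom: StenosisGeometry):
    """Lumen radius r̂(z): cosine throat, 50 % reduction at z = 0, continuous in z."""
    z = np.asarray(z, dtype=float) - geom.center[2]
    L = geom.characteristic_length_L
    rhat0 = geom.reference_radius_rhat0
    profile = np.where(
        np.abs(z) < L,
        1.0 - (1.0 + np.cos(np.pi * z / L)) / 4.0,
        1.0,
    )
    return rhat0 * profile


def stenosis_radius_slope(z, geom: StenosisGeometry):
    """d r̂ / d z of the throat profile (continuous; zero for |z| >= L)."""
    z = np.asarray(z, dtype=float) - geom.center[2]
    L = geom.characteristic_length_L
    rhat0 = geom.reference_radius_rhat0
    return np.where(
        np.abs(z) < L,
        rhat0 * np.pi / (4.0 * L) * np.sin(np.pi * z / L),
        0.0,
    )


def synthetic_stenotic_field(
    geom: StenosisGeometry, mean_inlet_speed: float, grid: GridSpec
) -> VelocityField:
    """Exactly mass-conserving axisymmetric flow through the stenosis.

    Built from the Stokes stream function psi(r, z) = v0 * rhat0^2 * (s^2 - s^4/2)
    with s = r / r̂(z), which yields

        vz = 2 v0 (rhat0 / r̂)^2 (1 - s^2)
        vr = 2 v0 (rhat0 / r̂)^2 r̂'(z) s (1 - s^2)

    inside the lumen and zero outside.  On the inlet (r̂ = rhat0, r̂' = 0) this
    reduces to a parabolic profile with mean speed ``mean_inlet_speed``; the
    axial volumetric flux pi rhat0^2 v0 is independent of z by construction.
    The field satisfies no-slip (v = 0) on the moving wall s = 1.
    """
    if mean_inlet_speed <= 0:
        raise ValueError("mean inlet speed must be positive")
    v0 = mean_inlet_speed
    rhat0 = geom.reference_radius_rhat0
    cx, cy, _ = geom.center
    # throat must be resolved by >= 8 nodes across the minimum diameter
    min_diam = 2 * 0.5 * rhat0
    if min_diam / min(grid.spacing[0], grid.spacing[1]) < 8:
        raise DomainError("grid does not resolve the throat with >= 8 nodes")

    def analytic(x, y, z):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        rhat = stenosis_radius(z, geom)
        slope = stenosis_radius_slope(z, geom)
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        s = r / rhat
        inside = s < 1.0
        amp = 2.0 * v0 * (rhat0 / rhat) ** 2
        vz = np.where(inside, amp * (1.0 - s**2), 0.0)
        vr = np.where(inside, amp * slope * s * (1.0 - s**2), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ex = np.where(r > 0, dx / np.maximum(r, 1e-300), 0.0)
            ey = np.where(r > 0, dy / np.maximum(r, 1e-300), 0.0)
        return vr * ex, vr * ey, vz

    def lumen(x, y, z):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        rhat = stenosis_radius(z, geom)
        return (x - cx) ** 2 + (y - cy) ** 2 < rhat**2

    X, Y, Z = grid.meshgrid()
    comps = analytic(X, Y, Z)
    return VelocityField(
        grid,
        *(np.ascontiguousarray(v) for v in comps),
        lumen_mask=lumen(X, Y, Z),
        analytic_form=analytic,
        lumen_form=lumen,
    )


def add_solenoidal_perturbation(
    field: VelocityField,
    amplitude: float,
    n_modes: int = 8,
    seed: int = 0,
    z_range: Optional[tuple[float, float]] = None,
    geom: Optional[StenosisGeometry] = None,
) -> VelocityField:
    """Superpose seeded divergence-free velocity disturbances on a base field.

    A random vector potential A (sum of ``n_modes`` sinusoidal modes, windowed
    to vanish well inside the lumen wall and outside ``z_range``) is sampled on
    the grid and its centred-difference curl is added to the base field.
    Because centred differences commute, the discrete curl is exactly
    divergence-free under the matching centred divergence stencil.

    ``amplitude`` scales the RMS of the added velocity over the windowed region.
    The analytic form is dropped (the perturbed field is grid-defined).
    """
    rng = np.random.default_rng(seed)
    grid = field.grid
    X, Y, Z = grid.meshgrid()
    if geom is not None:
        rhat = stenosis_radius(Z, geom)
        cx, cy, _ = geom.center
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        w = np.clip(1.0 - r2 / (0.8 * rhat) ** 2, 0.0, None) ** 2
    else:
        w = field.lumen_mask.astype(float)
    if z_range is not None:
        z0, z1 = z_range
        zc, zw = 0.5 * (z0 + z1), 0.5 * (z1 - z0)
        w = w * np.clip(1.0 - ((Z - zc) / zw) ** 2, 0.0, None) ** 2

    extent = [grid.spacing[a] * grid.shape[a] for a in range(3)]
    A = np.zeros((3,) + tuple(grid.shape))
    for _ in range(n_modes):
        k = np.array(
            [rng.integers(1, 5) * 2 * np.pi / extent[a] for a in range(3)], float
        )
        phase = rng.uniform(0, 2 * np.pi, size=3)
        coeff = rng.normal(size=3)
        arg = k[0] * X + k[1] * Y + k[2] * Z
        for c in range(3):
            A[c] += coeff[c] * np.sin(arg + phase[c])
    A *= w

    def ddx(q, axis):
        out = np.zeros_like(q)
        h = grid.spacing[axis]
        sl = [slice(None)] * 3
        lo, hi = [slice(None)] * 3, [slice(None)] * 3
        sl[axis] = slice(1, -1)
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        out[tuple(sl)] = (q[tuple(hi)] - q[tuple(lo)]) / (2 * h)
        return out

    ux = ddx(A[2], 1) - ddx(A[1], 2)
    uy = ddx(A[0], 2) - ddx(A[2], 0)
    uz = ddx(A[1], 0) - ddx(A[0], 1)
    rms = np.sqrt(np.mean(ux**2 + uy**2 + uz**2, where=w > 0))
    if rms > 0:
        scale = amplitude / rms
        ux, uy, uz = ux * scale, uy * scale, uz * scale
    return VelocityField(
        grid,
        field.vx + ux,
        field.vy + uy,
        field.vz + uz,
        lumen_mask=field.lumen_mask,
        analytic_form=None,
        lumen_form=field.lumen_form,
    )


# ---------------------------------------------------------------------------
# voxel-averaged reference and discrete operators
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(4)


def voxel_average_reference(
    field: VelocityField, image_grid: GridSpec, component: int = 2
) -> np.ndarray:
    """Volume average of one velocity component over each image voxel.

    Image-grid nodes are taken as voxel centres with the grid spacing as the
    voxel size.  A fixed 4x4x4 Gauss-Legendre rule per voxel is used, which is
    exact for the quadratic parabolic profile.  The analytic form is preferred;
    a grid-defined field is sampled by trilinear interpolation.
    """
    shape = tuple(image_grid.shape)
    if field.analytic_form is not None:
        sample = lambda x, y, z: field.analytic_form(x, y, z)[component]
    else:
        from .lagrangian import interpolate_velocity

        def sample(x, y, z):
            pos = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
            return interpolate_velocity(field, pos)[:, component].reshape(x.shape)

    centers = [image_grid.axis_coords(a) for a in range(3)]
    h = image_grid.spacing
    # tensor-product quadrature points offsets in each axis
    off = [0.5 * h[a] * _GL_NODES for a in range(3)]
    wts = [0.5 * _GL_WEIGHTS for _ in range(3)]
    out = np.zeros(shape)
    # evaluate axis-by-axis outer products lazily to keep memory modest
    for iq, (ox, wx) in enumerate(zip(off[0], wts[0])):
        for jq, (oy, wy) in enumerate(zip(off[1], wts[1])):
            for kq, (oz, wz) in enumerate(zip(off[2], wts[2])):
                X, Y, Z = np.meshgrid(
                    centers[0] + ox, centers[1] + oy, centers[2] + oz, indexing="ij"
                )
                out += wx * wy * wz * sample(X, Y, Z)
    return out


def divergence(field: VelocityField) -> np.ndarray:
    """Second-order centred-difference divergence (interior nodes; edges zero)."""
    out = np.zeros(tuple(field.grid.shape))
    for axis, comp in enumerate(field.components):
        h = field.grid.spacing[axis]
        sl = [slice(None)] * 3
        lo, hi = [slice(None)] * 3, [slice(None)] * 3
        sl[axis] = slice(1, -1)
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        out[tuple(sl)] += (comp[tuple(hi)] - comp[tuple(lo)]) / (2 * h)
    return out


def export_nifti(field: VelocityField, outdir, prefix: str = "phantom") -> list:
    """Write velocity components and lumen mask as NIfTI volumes + JSON sidecar."""
    import nibabel as nib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(np.asarray(field.grid.spacing) * 1e3) + [1.0])
    affine[:3, 3] = np.asarray(field.grid.origin) * 1e3  # mm
    written = []
    for name, arr in zip(
        ("vx", "vy", "vz", "mask"),
        (field.vx, field.vy, field.vz, field.lumen_mask.astype(np.uint8)),
    ):
        p = outdir / f"{prefix}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), p)
        written.append(p)
    sidecar = outdir / f"{prefix}.json"
    sidecar.write_text(
        json.dumps(
            {
                "origin_m": list(field.grid.origin),
                "spacing_m": list(field.grid.spacing),
                "shape": list(field.grid.shape),
                "units": {"velocity": "m/s", "affine": "mm"},
            },
            indent=2,
        )
    )
    written.append(sidecar)
    return written
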