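# Methods

`pcmrisim` simulates 2-D phase-contrast MRI (PC-MRI) scans of prescribed,
steady, incompressible flow fields and reconstructs velocity and
intravoxel-velocity-SD maps from the simulated k-space.  This note records
the model, its assumptions, the numerical choices, and what the built-in
phantoms do and do not probe.

## Physical model

The magnetization is written in transverse-cylindrical form,
`Mx = Mr cos(phi)`, `My = Mr sin(phi)`, and evolves under the Bloch equation
with an advection term.  Because only the z-component of the applied field is
nonzero between RF pulses (`Bz = G(t) . x`), the system splits into three
scalar transport equations:

    dMz/dt + v.grad(Mz) = (M0 - Mz)/T1
    dMr/dt + v.grad(Mr) = -Mr/T2
    dphi/dt + v.grad(phi) = -gamma_rad Bz

with `gamma_rad = 2 pi gamma_bar`, `gamma_bar = 42.58 MHz/T`.  The whole
rectangular computational domain is spin-bearing; outside the lumen the
material is simply static (`v = 0`).  This matters: it means the magnitude
image has no artificial vacuum edge at the lumen wall, so truncation (Gibbs)
ringing largely cancels between the velocity-compensated and
velocity-encoded acquisitions.

Assumptions (deliberate, matching the scope of a verification study):
ideal instantaneous RF excitation confined to the FOV slab; ideal spoiling
(`Mr = phi = 0` at the end of every TR); rectangular gradient lobes with no
slew or ramp; no field inhomogeneity, no diffusion, no noise, steady flow
only.

## Sequence

One TR of the spoiled gradient echo contains: RF at `t = 0`; a phase-encode
lobe (y axis, duration `TP`, amplitude `line * 2 pi/(gamma_rad Ly TP)`) and a
bipolar velocity-encoding pair (each lobe `TV` long, amplitude
`GV = pi/(gamma_rad venc TV^2)`, positive lobe first) both centred at `TC`;
a readout prephaser (`-GR`, `TS/2`) immediately followed by the plateau
(`+GR`, `TS`) centred on TE.  Defaults: `TS = Nx dts` with sampling pitch
`dts = 0.01 ms`, `TP = TS/2`, `TV = TP/2`.

Choices worth noting:

* **Readout amplitude.** `GR = 2 pi/(gamma_rad Lx dts)`, so one sampling
  pitch advances kx by exactly `2 pi / Lx` and the reconstructed FOV equals
  the prescribed FOV.  (The textbook form `2 pi/(gamma_rad Lx TS)` would make
  the per-sample k-step `2 pi/(Lx Nx)` and the reconstructed FOV `Nx Lx`.)
* **TV is one lobe.** With rectangular lobes the pair's first moment is
  `GV TV^2`, so a spin at constant `v` accrues exactly `pi v / venc`; the
  positive-lobe-first polarity encodes positive velocity as positive phase.
* **TC defaults to `TE - TS - TV`** — the velocity encoding sits directly
  against the readout, as in clinical PC sequences, and therefore tracks TE.
  This is the lever behind the displacement-artifact experiment: the velocity
  is encoded at `TC` while spatial encoding refers to `TE`, so the apparent
  velocity of accelerating spins grows with TE.  `TC` is an ordinary protocol
  field and can be pinned instead.
* The phase-encode lobe overlaps the bipolar pair (different axes superpose
  in `Bz`); only `TC` and `TE` are treated as binding times.

k-space is sampled line-sequentially, `Nx` samples at interval `dts` centred
on TE; the image is the centred 2-D inverse DFT with `1/(Nx Ny)`
normalization.  Velocity maps use phase differences,
`v = venc * wrap(arg I_enc - arg I_ref)/pi` (two-point per axis; the
four-point scheme is one reference plus one encoded acquisition per axis).
Voxels whose reference magnitude falls below 1 % of the maximum are masked.

## Eulerian backend

(Mz, Mr, phi) live on a rectangular node lattice.  The advection term is
discretized dimension-by-dimension with fifth-order WENO (Jiang-Shu
smoothness indicators, `eps = 1e-6`, divided differences), upwinded on the
sign of the nodal velocity component; axes whose velocity component vanishes
identically are skipped.  Inlet faces hold three Dirichlet ghost layers
(`Mz = M0, Mr = 0, phi = 0` — unsaturated spins convect in); outlet and wall
faces replicate the edge value.  Face roles are inferred from the mean normal
velocity and can be overridden.

Time integration is the 5th-order stage combination of the Dormand-Prince
pair at fixed step (six RHS evaluations per step, no error control), so
stage times are deterministic and bit-reproducible.  Each TR is split at
gradient-lobe edges and readout sample times; within such an interval the
gradient vector is constant, the RHS is autonomous and smooth, and the step
is bounded by the advective CFL limit `courant * min_axis(h/max|v_axis|)`
(`courant = 0.5` by default).  During readout the sub-intervals are one
sampling pitch long, so every sample time is hit exactly — the purpose the
global `Delta t <= dts` cap in `cfl_timestep` serves when stepping uniformly.
The phase field is evolved on the whole grid (also where `Mr = 0`) so it
stays smooth across the lumen boundary; per-TR spoiling keeps it unwrapped.

The signal is the trapezoid-rule volume integral of
`Mr (cos phi, sin phi)` — the exact integral of the cell-linear interpolant.
Advection is in advective (non-conservative) form, so the integral of Mr is
conserved only to discretization order, not exactly.

## Lagrangian backend

Massless particles are seeded uniformly at random (counter-based Philox
generator, one integer seed) over the spin-bearing domain, `density`
particles per image voxel in expectation, each carrying `(Mz, Mr, phi)` and
the fixed volume `voxel_volume / density`.  Positions follow
`dx/dt = v(x)` with trilinear interpolation; phase and magnetization are
integrated stage-synchronously with the same fixed-step Dormand-Prince
scheme and interval splitting as the fixed-grid backend.  No particles are
created or destroyed; particles leaving the grid hull coast at the clamped
boundary velocity and are counted as a quality metric.  Spins whose
interpolated velocity is exactly zero can never move; they take a closed-form
relaxation/phase path, which is what makes spin-filled domains affordable.
Seeding margins extend the populated region upstream by
`max speed x (scan duration, or one TR under per-TR reinitialization)` so the
slab never drains.

## Phantoms

* **Hagen-Poiseuille pipe** — `vz = vmax (1 - (r/r0)^2)`, exact analytic
  form attached.  Two geometries are supported: a 5 mm-radius cylinder whose
  no-slip wall sits inside the 16 mm domain (static material outside), and a
  5 cm-radius pipe whose smooth core contains the domain as a window.  In the
  window variant the signed mean of the normalized reconstruction error
  decreases monotonically with grid refinement into the 1e-5 range
  (coarse 1.6e-5, medium 7.8e-6, fine 4.2e-6 in the shipped runs); with the
  no-slip wall in-plane, the error instead converges to an irreducible
  band-limited truncation floor of about 0.2 % of vmax (see Limitations).
* **Stenotic cylinder** — lumen radius
  `r̂/r̂0 = 1 - (1 + cos(pi z / L))/4` for `|z| < L` (50 % reduction at the
  throat, continuous and C1 in z), `r̂0 = L/2 = 7.3 mm`.  The velocity field
  is built from the Stokes stream function
  `psi = v0 r̂0^2 (s^2 - s^4/2)`, `s = r/r̂(z)`, giving an exactly
  mass-conserving, axisymmetric, no-slip field that reduces to a parabolic
  profile with mean speed `v0` in the straight sections and quadruples the
  centreline velocity at the throat.  The default `v0 = 0.4 m/s` keeps
  throat velocities inside `venc = 4 m/s`.  This analytic stand-in replaces a
  turbulence-resolving CFD solution; it reproduces convective acceleration
  (hence displacement artifacts) but not turbulent fluctuation.
* **Disturbed flow** — seeded sinusoidal vector-potential modes, windowed to
  vanish near the wall, added through a centred-difference curl.  Because
  centred differences commute, the added field is exactly divergence-free
  under the matching divergence stencil.  The amplitude (RMS m/s) is a free
  parameter of the IVSD preset.

The voxel-averaged reference profile uses a fixed 4x4x4 Gauss-Legendre rule
per voxel — exact for the quadratic parabola.  Error statistics
(`(v_MRI - v̄)/vmax`) are taken by default over voxels lying entirely inside
the lumen; the partial-volume rim is excluded (an all-voxel mode exists).

## IVSD

With a Gaussian intravoxel velocity distribution of SD `s`, the
velocity-encoded voxel magnitude is attenuated by `exp(-pi^2 s^2 / 2 venc^2)`,
inverted as `IVSD = (venc/pi) sqrt(2 ln(|I0|/|I_BPG|))`, floored at zero when
the ratio inverts and masked below the noise floor.  The displacement-artifact
prediction traces seed points through the flow, samples the velocity at
`t = TC`, and deposits it at the in-plane position at `t = TE`, voxel-binned —
the theory overlay for the TE-sweep experiment.

## Problem sizes and defaults

Preset experiments ship with the verification parameters: pipe scan
(TR 5 ms, TE 4 ms, 36x36, FOV 18x18 mm, slice 10 mm, flip 4 deg,
venc 0.12 m/s, grids 32x32x5 / 64x64x10 / 128x128x20, particle densities
1-100 per voxel), stenosis TE sweep (TE 1-4 ms, 32x32, FOV 15x15x2 mm,
flip 5 deg, venc 4 m/s, per-TR reinitialization), and IVSD mapping
(TE 0.5 ms, 10x10 matrix of 2 mm voxels, venc 1.5 m/s, x/y encoding).
Shared tissue constants: T1 = 1200 ms, T2 = 250 ms, M0 = 100 (normalized).
The flip angle of the pipe preset is the printed 4 deg and is used verbatim,
although the Ernst angle for TR/T1 = 5/1200 is 5.2 deg.  The stenosis
experiments reinitialize positions and magnetization to their steady-state
values before each repetition; the particle-backend pipe verification runs
adopt the same policy — for this steady, fully saturated configuration it is
equivalent to continuous scanning (verified against the fixed-grid backend
to < 1e-6 of vmax) and markedly cheaper, since the seeding margin then only
needs to cover one TR of travel.  The test suite runs
the TE-sweep and property checks on reduced matrices (8x8-16x16) and
moderate particle densities to keep a full run on one CPU within minutes;
the physics exercised is unchanged.

## Known limitations

* The reconstruction converges, with grid/particle refinement, to the ideal
  band-limited image of the object — not to the voxel-averaged profile.
  Even for the smooth window object, the mean *magnitude* of the per-voxel
  error bottoms out near 1.5e-4 of vmax (sign-alternating ringing from the
  domain's vacuum edge, which cancels in the signed mean); with the no-slip
  wall in-plane, intravoxel curvature bias (`~ w^2/(6 r0^2)`) and edge
  ringing set a floor of ~2e-3 of vmax.  An independent truncated-Fourier
  oracle reproduces both floors, so these are properties of the measurement
  model, not solver error.
* Advective-form WENO conserves transverse magnetization only asymptotically.
* WENO5 attains its nominal order away from derivative critical points;
  order checks use monotone profiles.
* No turbulence: the disturbed-flow generator superposes smooth solenoidal
  modes, so IVSD experiments probe the encoding/inversion chain, not
  turbulence physics.
* Steady fields only; pulsatile or time-resolved flow is out of scope.
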