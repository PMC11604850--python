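# pcmrisim

Phase-contrast MRI (PC-MRI) maps flow velocities in vivo, but the
reconstructed velocity fields carry intrinsic errors — partial-volume and
intravoxel dephasing, displacement (misregistration) artifacts, aliasing —
that are hard to quantify because the true flow is unknown.  `pcmrisim`
simulates the full PC-MRI measurement chain on *prescribed* flow fields so
those errors can be studied quantitatively: it solves the advection-modified
Bloch equations

    dM_z/dt + v·∇M_z = (M_0 − M_z)/T_1
    dM_r/dt + v·∇M_r = −M_r/T_2
    dφ/dt  + v·∇φ   = −γ B_z(x, t)

through a spoiled-gradient-echo (SPGR) sequence with bipolar velocity
encoding, samples Cartesian k-space line by line, and reconstructs velocity
images with the standard phase-difference method, `v = venc·Δφ/π`.

Two interchangeable transport backends are provided:

* **Eulerian** — (M_z, M_r, φ) on a fixed Cartesian grid; WENO5 upwind
  advection, fixed-step Dormand–Prince time integration, inlet/outlet
  boundary conditions.  Free of particle-sampling noise.
* **Lagrangian** — magnetization-carrying particles advected through the
  field (trilinear velocity interpolation, same integrator), the
  conventional reference approach; accuracy depends on particle density.

Built-in phantoms: Hagen–Poiseuille pipe flow (exact analytic reference),
an analytic mass-conserving stenotic-cylinder field built from a Stokes
stream function (for displacement-artifact studies), and seeded
divergence-free flow disturbances on top of it (for intravoxel velocity SD
(IVSD) mapping).  Intended users: MR-physics and flow-imaging researchers
who need a desk-scale, fully reproducible verification bench.

## Worked example

Simulate the pipe-flow verification scan (cylinder radius 5 mm,
vmax = 0.1 m/s, TR 5 ms, TE 4 ms, 36×36 matrix, FOV 18×18 mm, slice 10 mm,
flip 4°, venc 0.12 m/s, Eulerian backend on the coarse 32×32×5 grid):

```python
from pcmrisim.runner import poiseuille_config, run_experiment

res = run_experiment(poiseuille_config(grid="coarse"))
print(res["metrics"].to_string(index=False))
```

prints

```
component  mean_abs_error  max_abs_error  n_voxels  vmax
        z        0.002464       0.007819       277   0.1
```

i.e. the reconstructed axial velocity deviates from the voxel-averaged
analytic parabola by 0.25 % of vmax on average (0.78 % at worst) over the
277 voxels lying fully inside the lumen — the per-voxel error
`(v_MRI − v̄_z)/vmax` of the verification study.  The velocity image itself
is in `res["velocity"].components["z"]` (m/s, NaN outside the noise floor).

The same scan from the shell, with artifacts (k-space HDF5, NIfTI velocity
maps, CSV metrics, archived config) written to a run directory:

```bash
pcmrisim preset run poiseuille --outdir runs/pipe
pcmrisim preset list                  # poiseuille, stenosis-te-sweep, ivsd
```

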