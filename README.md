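# hemoflow

Particle-based blood flow in tubes and microvascular bifurcations with
open (non-periodic) inflow/outflow boundary conditions.

The package couples three ingredients:

* a **DPD plasma fluid** (conservative + dissipative + random pair forces
  with a generalized dissipative weight `w(r) = (1 - r/r_c)^s`),
* a **coarse-grained red-blood-cell membrane**: closed triangulated meshes
  with worm-like-chain in-plane elasticity, bending resistance, global
  area/volume constraints and membrane viscosity (dissipative + matched
  random per-spring forces),
* an **open-boundary framework**: a periodic *generating region* runs a
  fully developed pilot flow and feeds the main domain by duplicating
  particles (and whole cells, with slaved motion) that cross the *copy
  border*; one-way coupling keeps the generating region autonomous; at
  each outlet an adaptive probabilistic membrane removes crossing
  particles with probability `P`, driven toward a target number density by
  `dP = h |rho - rho_t| / rho_t`; cells are dissolved into fluid inside
  per-outlet deletion regions.

Walls are frozen layers of equilibrated-fluid particles combined with
bounce-back reflection (no-slip). Everything runs in reduced DPD units
with unit particle mass.

## Layout

| module | contents |
|---|---|
| `hemoflow.core` | particle container, neighbor search, velocity-Verlet driver |
| `hemoflow.dpd` | DPD parameters and pair forces, temperature estimator, Poiseuille fit |
| `hemoflow.membrane` | cell meshes, all membrane force terms (analytic gradients) |
| `hemoflow.geometry` | signed-distance geometries (tube, bifurcation), walls, bounce-back |
| `hemoflow.obc` | open-boundary machinery: ghosts, duplication, outflow controller |
| `hemoflow.forces` | force composition + interaction masking (numba fast path in `hemoflow.kernels`) |
| `hemoflow.observables` | velocity/pressure profiles, recovery efficiency |
| `hemoflow.scenarios` | fixture generation (cell packing, pilot runs) and end-to-end scenario runners |
| `hemoflow.io` | VTK/XYZ snapshots, HDF5 checkpoints, CSV series |

## CLI

```sh
hemoflow run config.yaml --out results/
hemoflow validate-poiseuille --seed 1 --steps 6000
hemoflow sweep config.yaml --param phi_d --values 1,2,6 --out sweep.csv
```

A minimal config:

```yaml
scenario: tube_obc           # tube_pbc | tube_obc | bifurcation
seed: 1
d: 8.0                       # tube diameter (DPD units)
gen_len: 10.0                # generating-region length
L_main: 16.0
fluid: {a: 4.0, gamma: 30.0, r_c: 1.5, kBT: 0.0945, s: 0.5, n: 2.96, g: 0.1}
obc:   {h: 0.05, P0: 0.1, window: 100}
run:   {dt: 0.005, relax: 200, pilot: 600, production: 8000, warmup: 3000}
```

Bifurcation runs add a `bifurcation:` block (`d_parent`, `d_daughter1/2`,
`theta`, `L_daughter`, `straight_main`) plus `phi_d` (target daughter
flow-rate ratio) and use `membrane: {enabled: true, n_v: 500,
hematocrit: 0.15, ...}` for suspensions.

## Notes on scale

Default geometries are reduced (desk-scale) versions that preserve the
dimensionless ratios of the study (daughter/parent diameter 0.825,
cell-to-vessel size ratio ~0.4-0.5). Suspension transport runs use a
stronger body force than the single-phase validation so cells transit
within tractable step counts; trends (plasma skimming vs flow-rate ratio,
bifurcation-angle effect) are the reproducible objects at this scale, not
the paper-scale percentages.
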