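# aawall — wall stress in idealized abdominal aortic aneurysms

`aawall` is a finite-element analysis pipeline for cardiovascular
biomechanics: it builds parametric, idealized geometries of the human
abdominal aorta — with and without an aneurysmal sac — solves the static
nonlinear elasticity problem under luminal pressure, and quantifies how the
peak and average von Mises wall stress inside the sac respond to the sac's
geometric and mechanical parameters.  It is aimed at readers studying
rupture-risk surrogates beyond the clinical maximum-diameter criterion.

## Model

The wall is a nearly incompressible fiber-reinforced hyperelastic solid —
a neo-Hookean matrix plus two symmetric collagen-fiber families with
exponential stiffening (HGO-type, no dispersion):

    psi = mu/2 (Ibar1 - 3) + k1/(2 k2) * sum_{i=4,6} [exp(k2 (Ibar_i - 1)^2) - 1]
        + kappa/2 (J - 1)^2

with `Ibar4`, `Ibar6` the squared isochoric stretches along the ±phi fiber
helices.  The vessel (trunk, aorto-iliac bifurcation, aneurysmal sac with
seven shape controls) is meshed with structured first-order tetrahedra; a
total-Lagrangian Newton solver with follower pressure loading and an
average-nodal-pressure treatment of near incompressibility produces the
displacement and Cauchy-stress fields; post-processing reports the peak
(PWS) and element-size-weighted average (AWS) von Mises stress in the sac.
Two response variables, one pressure (120 mmHg = 0.016 MPa), exhaustive
parameter sweeps.  Independent semi-analytic thick-walled-cylinder
oracles gate the solver's correctness.  See `docs/methods.md` for the
full account, assumptions and known limitations.

## Worked example

```python
import aawall as aw

solid = aw.build_aaa()                       # baseline aneurysm geometry
mesh, sol = aw.run_case(solid, aw.BASELINE_AAA,
                        aw.BoundaryConditions(pressure=0.016, increments=5),
                        resolution=(44, 24, 2))
summary = aw.summarize(sol, mesh, aw.sac_region(mesh, solid))
print(f"{mesh.n_elements} tets: sac PWS {summary.PWS:.3f} MPa, "
      f"AWS {summary.AWS:.3f} MPa")
```

prints (exact run from this repository):

```
12672 tets: sac PWS 0.440 MPa, AWS 0.176 MPa
```

i.e. at 120 mmHg the baseline 45 mm sac carries a peak wall stress of
0.44 MPa — about half the ~1 MPa ultimate strength usually assumed for
aneurysmal tissue — and an average sac stress of 0.18 MPa, several times
the referent aorta's level.  Doubling the sac diameter or halving the sac
wall thickness pushes the peak toward the failure range, which is the
sensitivity structure the `analysis/` scripts chart:

* `analysis/01_baselines.py` — referent vs baseline AAA stress fields
* `analysis/02_mesh_independence.py` — 4%-criterion mesh study
* `analysis/03_geometry_sweeps.py` — isolated sweeps of the seven sac shape
  parameters
* `analysis/04_material_sweeps.py` — mu, k1, k2 sweeps
* `analysis/05_interactions.py` — diameter × {thickness, extent, k1} grids

Each writes tidy CSV tables under `results/`.  A thin CLI wraps the same
library calls (`aawall baselines`, `aawall sweep --param sac_thickness`,
`aawall interactions`, `aawall mesh-study`, `aawall report`).

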