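# Methods

## Problem and model

`aawall` computes the static stress state of an idealized human abdominal
aorta, with and without an aneurysmal sac, under physiological luminal
pressure, and quantifies how the peak (PWS) and size-weighted average (AWS)
von Mises wall stress within the sac respond to isolated changes of the
sac's geometric and mechanical parameters.

The wall is a nearly incompressible, fiber-reinforced hyperelastic solid:
an isotropic neo-Hookean matrix plus two symmetric families of collagen
fibers with exponential stiffening (an HGO-type strain energy without fiber
dispersion),

    psi = mu/2 (Ibar1 - 3)
        + k1/(2 k2) * sum_{i=4,6} [ exp(k2 (Ibar_i - 1)^2) - 1 ]
        + kappa/2 (J - 1)^2,

where `Ibar1, Ibar4, Ibar6` are modified invariants of the right
Cauchy–Green tensor and `Ibar4/Ibar6` are squared isochoric stretches along
the two fiber directions, which lie in the wall surface at a helix angle
±phi from the longitudinal vessel axis.  Units are mm–MPa–N throughout.

Material presets: referent normal aortic tissue (mu = 0.007 MPa,
k1 = 2.87 MPa, k2 = 17.26, phi = 36°) and baseline aneurysmal tissue
(mu = 0.013 MPa, k1 = 2.74 MPa, k2 = 119.6, phi = 45°; the defining source
lists 119.6 in its parameter table and 119 in its summary table — the
preset stores 119.6).  Loading is a uniform luminal pressure of 120 mmHg,
applied as the printed rounded value 0.016 MPa, as a follower load (normal
to the deformed lumen surface).  All end caps (aortic inlet, iliac
outlets) are fully fixed; first-order tetrahedra have no rotational
degrees of freedom, so "complete motion constraint" reduces to
displacement fixation.

### Fiber compression behavior

The exponential fiber energy is applied exactly as written — symmetric
about `Ibar_i = 1`, i.e. compressed fibers stiffen too.  A tension-only
switch exists (`fiber_tension_only`), but is off by default for a concrete
mechanical reason: a ±45° two-family fabric whose fibers carry no
compression possesses a near-mechanism in-plane "trellis" mode
(circumferential extension traded against axial shortening at constant
fiber stretch, resisted only by the very soft matrix).  Under sac
inflation the tension-only model collapses into this mode (displacements
of tens of mm, wildly inflated stress); the symmetric form is stable and
matches the as-printed energy.

### Local frames and fibers on a curved vessel

Each element carries an orthonormal (radial, circumferential, axial)
frame taken from the *wall mid-surface*: radial = surface normal,
axial = in-surface meridian, circumferential completes the triad.  On a
straight tube this is exactly the cylindrical triad; on the sac shoulders
and through the bifurcation flare the meridian tilts with the wall so the
fiber helices always lie in the wall surface.  (Frames built from the
centerline tangent instead were tried and rejected: on the shoulders they
push the fiber directions out of the surface, leaving the meridian
unreinforced, and the sac then collapses.)

## Geometry

The vessel is a generalized cylinder: cross-sections normal to z with
star-shaped inner/outer profiles `r(theta, z)` about per-section centers.
The referent aorta is a straight tube (outer diameter 20 mm, wall 2 mm)
spanning the 128 mm cross-section field CS0..CS8 (16 mm spacing, CS0 at
z = 0).  Below CS0 the section morphs into a two-lobed outline following
the common-iliac centerlines, which leave the aortic axis along circular
arcs of radius Rc = 50 mm up to the 20° take-off angle, with the 15°
out-of-plane angle as a common lateral drift of the bifurcation plane.
The junction is truncated where lobe separation reaches 60% of the inner
lobe radius and capped (the cap is split at the symmetry plane into the
two iliac outlet tags); the crotch is rounded by a 3 mm smoothing length
and the wall thickens by up to 50% toward the carina — the bifurcation is
fused, reinforced tissue, not a free-standing thin waisted shell, and an
unreinforced waist balloons through a numerical limit point below the
working pressure.

The aneurysmal sac superposes a bulge controlled by seven parameters
(axial extent, circumferential extent ∈ {90°, 180°, 270°, 360°}, maximum
transverse outer diameter, axial location of the sac midplane, sac wall
thickness, and signed arc/chord tortuosity in the XZ and YZ planes).
Axially, the two fully dilated planes sit one quarter-extent apart around
the midplane and carry the full sac profile; quintic C² shoulders blend
back to the referent sections, with the shoulder support calibrated so
the *measurable* bulged span (outer radius more than 1% above referent)
equals the requested extent.  A loft that interpolates the section stack
with natural cubic splines was implemented and rejected: its ringing
perturbs the maximum diameter — the study's defining parameter — by
several percent.  Circumferentially, partial extents place the bulged arc
symmetrically about the anterior direction (+x) and return to the
referent circle with a C¹ cosine blend over the remaining angle, touching
it at the posterior point.  Wall thickness follows the same axial blend
from the referent 2 mm to the sac value on the dilated planes.
Tortuosity bows the trunk centerline as a circular arc (arc/chord = |tau|,
sagitta from a bisection root-find), pinned at both ends of the field;
sections stay parallel to the XY plane.  The bulge support is clipped at
CS0.

## Discretization and solver

The generalized-cylinder parameterization admits a structured
(z, theta, r) grid; each hexahedral cell splits into six tetrahedra by the
translation-invariant Kuhn triangulation, conforming across the periodic
seam, with at least two elements through the wall.  Boundary triangles
inherit tags (lumen, outer wall, caps) from the construction.  The angular
resolution floor keeps the inscribed-polygon volume error below 0.8%.

The solver is total-Lagrangian displacement FEM with one quadrature point
per linear tetrahedron.  Pure-displacement linear tetrahedra lock under
near incompressibility, so the volumetric energy is treated with *average
nodal pressures* (mean dilatation over node patches): nodes carry the
volume-weighted average Jacobian of their element patch, and elements see
the mean of their four nodal pressures.  The exact tangent of the patch
coupling is assembled as a sparse rank-one product `H^T D H`.  A 2%
fraction of the bulk modulus is kept as an element-level penalty — this
damps element-level Jacobian oscillations that are invisible to the patch
average, while adding negligible locking.  Default bulk modulus
`kappa = 1000 * max(mu, 0.01)` MPa; the cylinder benchmark error shrinks
monotonically as kappa is raised (tested).

Stress and the consistent tangent come from complex-step differentiation
of the analytic second Piola–Kirchhoff stress (machine-precision
derivatives; the test suite cross-checks them against real-arithmetic
finite differences).  The follower-pressure load stiffness (nonsymmetric)
is included, so residual norms drop quadratically near the root — the
suite asserts the superlinear tail.

Pressure is ramped with a quadratic schedule (more increments at low
pressure, where the unloaded wall is bending-soft) and each Newton step is
trust-region-capped at 0.5 mm: the exponential fiber response makes an
uncapped first step overshoot into overflow.  Diverged increments retry
with bisection of the load step.  Failed sweep cases are tabulated, never
fatal.

Degenerate inputs are rejected with typed errors (no lumen, sub-unit
tortuosity index, off-grid circumferential extents, negative pressure,
fiber-exponent overflow is raised as a diagnostic rather than clamped).

## Verification

Two independent semi-analytic oracles solve incompressible, fixed-length
axisymmetric inflation of a thick-walled two-fiber tube: quadrature of
radial equilibrium with closed-form energy derivatives plus a bracketing
root-find, and a shooting method with finite-difference energy derivatives
and an adaptive ODE integrator.  They agree to 1e-6 and satisfy the global
equilibrium identity (hoop-stress integral = P × deformed inner radius).
The FE solver is held to the quadrature oracle on a matched tube: with
plane-strain end conditions (axial rollers — the oracle's fixed-length
assumption) the layered hoop-stress profile agrees to ~3% at the default
mesh; with fully fixed caps the mid-tube axial stretch is ~0.995 rather
than 1, worth ~6% in hoop stress, which is why the verification runs use
rollers while the vessel studies keep fixed caps.  A thin-walled tube
(R/t = 20) at low pressure matches the Laplace membrane value to ~2%.

## Study conditions and problem sizes

All experiments run at 0.016 MPa with five ramp increments.  The
parametric grids are exactly the study's value lists (no interpolation);
the baseline AAA is (axial 64 mm, 360°, diameter 45 mm, location 32 mm,
sac thickness 1.5 mm, tortuosity 1.00/1.00).  The bundled analyses and the
reproduction script use desk-scale structured meshes — (44, 24, 2) cells
(≈ 12,700 tetrahedra) for the two absolute baseline solves and (36, 20, 2)
(≈ 8,600) for the sweep sets, whose targets are ratios; the test suite
uses (32, 18, 2).  Mesh-level convergence of the response variables is
governed by the 4% criterion of `mesh_independence`, not by any fixed
element count.  Interaction sweeps cross the diameter grid with thickness
{1.0, 1.5, 2.0} mm, axial extent {64, 96} mm and k1 {1, 2.74, 15, 50} MPa.

## What the idealized generator does and does not emulate

The geometry module is the study's synthetic-input generator: it emulates
idealized, parametrically controlled aneurysm shapes — not patient
anatomy.  It has no intraluminal thrombus, no imaging noise, no
residual stress or axial prestretch, no wall heterogeneity beyond the
prescribed thickness profile, and the iliac arteries are truncated near
the carina (their terminations are fully fixed in any case).  Passing
tests therefore demonstrate the mechanics pipeline and parameter
sensitivities on clean idealized shapes; they do not validate
patient-specific stress prediction.

## Known limitations and documented discrepancies

* **Referent average stress.**  The reported referent-aorta values in the
  source study (AWS 0.013 MPa, PWS 0.091 MPa) sit below what static
  equilibrium permits for the stated tube and pressure: the through-wall
  hoop-stress integral must equal P × inner radius, forcing a mean von
  Mises level of at least ~0.06 MPa for *any* constitutive choice.  This
  package reproduces the equilibrium-consistent value (~0.11 MPa with
  fibers at 36° from the axis, which load the wall axially) and verifies
  it against the independent cylinder oracle instead.
* **Absolute sac stresses.**  The baseline sac here carries PWS ≈ 0.37–0.47
  and AWS ≈ 0.17–0.18 MPa at desk-scale meshes versus the reported
  0.76 / 0.11 MPa.  The sac surface loft of the original CAD chain is not
  fully specified; peak stress is dominated by shoulder/neck bending and
  is therefore sensitive to the loft's local curvature in a way no
  reconstruction can pin down.  Trends and the diameter sensitivity
  reproduce well; the thickness/k1/k2 sensitivity magnitudes, which
  amplify through the same bending concentrations, come out smaller than
  reported.
* **Circumferential extent.**  Partial extents produce a posterior crease
  whose sharpness (hence PWS) depends on the unspecified blend geometry;
  the 270° case concentrates stress more strongly here than reported.
* **Formulation.**  Exact element technology of the original solver
  ("hybrid" linear tetrahedra) is not replicated; correctness is defined
  by the semi-analytic oracle instead, per the verification gates above.
* The dual reading of "element size" in the AWS weighting (element volume
  vs deformed lumen-face area) spans ~15% on the baseline sac because the
  area mode samples only inner-wall elements; volume weighting is the
  default and both are available.
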