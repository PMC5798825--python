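"""Parametric construction of the aorta-iliac vessel and its aneurysmal variants.

This module is the pipeline's synthetic-input generator.  A vessel is
represented as a *generalized cylinder*: cross-sections normal to the z axis,
each a closed star-shaped profile given by inner/outer radius functions
``r(theta, z)`` about a per-section center ``(cx(z), cy(z))``.  The referent
normal aorta is a straight tube (outer diameter D, wall thickness t) that
morphs, below the bifurcation plane z = 0, into a two-lobed ("peanut")
outline following the diverging common-iliac centerlines; the junction is
truncated just proximal to lumen separation and capped (all termination
surfaces are fully fixed downstream, so the distal iliac segments carry no
load information).  The iliac centerlines leave the aortic axis along
circular arcs of radius Rc (the junction radius of curvature) until they
reach the take-off angle alpha; the out-of-plane angle beta tilts the
bifurcation plane.

Aneurysmal variants superpose on the trunk a smooth axisymmetric (or
partial-circumference) bulge described by seven parameters: axial extent,
circumferential extent, maximum transverse outer diameter, axial location of
the sac midplane, sac wall thickness, and signed arc/chord tortuosity of the
centerline in the XZ and YZ planes.  Cross-sectional planes CS0..CS8 span
the geometric-variation field L* = 128 mm at 16 mm spacing; the anterior
direction is +x.

Coordinates: z along the abdominal axis increasing superiorly, CS0 at z = 0,
bifurcation below CS0.  Units mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GeometryError",
    "ReferentGeometryParameters",
    "AAAParameters",
    "CrossSection",
    "VesselSolid",
    "tortuosity_to_sagitta",
    "circumferential_profile",
    "build_referent",
    "build_aaa",
    "build_cylinder",
    "BASELINE_AAA_GEOMETRY",
]

#: length of the geometric-variation field CS0..CS8 [mm]
L_STAR = 128.0
#: spacing of the CS planes [mm]
CS_SPACING = L_STAR / 8.0

# Axial bulge: plateau half-width as a fraction of the axial extent.  The
# fully dilated planes then sit one CS spacing apart at the baseline extent;
# the cosine shoulders make the sac a smooth barrel (doubly curved), the
# shape a loft of closed splines through the dilated sections produces.
_PLATEAU_FRACTION = 0.125
# Smoothing length for the crotch (carina) rounding of the two-lobe outline [mm]
_CROTCH_SMOOTH = 3.0
# Junction is truncated where lobe separation reaches this fraction of the
# inner lobe radius (mild waist; distal to it the iliacs separate and are
# not load-informative under fully fixed terminations).
_SEPARATION_FRACTION = 0.6
# Wall thickening factor toward the carina: the aortic bifurcation is a
# fused, reinforced tissue region, not a free-standing thin waisted shell.
_CARINA_THICKENING = 0.5


class GeometryError(ValueError):
    """Infeasible or degenerate geometric parameter combination."""


@dataclass(frozen=True)
class ReferentGeometryParameters:
    """Referent normal aorta-iliac dimensions [mm, degrees]."""

    L: float = 120.0            # abdominal length
    D: float = 20.0             # outer diameter
    t: float = 2.0              # wall thickness
    iliac_D_prox: float = 13.0  # proximal iliac outer diameter
    iliac_D_dist: float = 10.3  # distal iliac outer diameter
    Li: float = 42.0            # iliac length
    alpha: float = 20.0         # in-plane take-off angle
    beta: float = 15.0          # out-of-plane bifurcation angle
    Rc: float = 50.0            # junction centerline radius of curvature

    def __post_init__(self) -> None:
        for name in ("L", "D", "t", "iliac_D_prox", "iliac_D_dist", "Li", "Rc"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.t >= self.D / 2.0:
            raise GeometryError("wall thickness t >= D/2 leaves no lumen")
        if self.iliac_D_dist > self.iliac_D_prox:
            raise GeometryError("iliac diameter must not increase distally")
        if not 0.0 <= self.alpha < 90.0 or not 0.0 <= self.beta < 90.0:
            raise GeometryError("angles must lie in [0, 90) degrees")


@dataclass(frozen=True)
class AAAParameters:
    """Seven geometric controls of the aneurysmal sac (baseline defaults)."""

    axial_extent: float = 64.0      # mm
    circ_extent: float = 360.0      # degrees, one of {90, 180, 270, 360}
    max_diameter: float = 45.0      # transverse outer diameter [mm]
    location_z: float = 32.0        # CS0 -> sac midplane [mm]
    sac_thickness: float = 1.5      # wall thickness at dilated planes [mm]
    tort_xz: float = 1.0            # signed arc/chord index, |tau| >= 1
    tort_yz: float = 1.0

    def __post_init__(self) -> None:
        if self.circ_extent not in (90.0, 180.0, 270.0, 360.0):
            raise GeometryError("circ_extent must be one of 90, 180, 270, 360 degrees")
        if self.axial_extent <= 0 or self.max_diameter <= 0 or self.sac_thickness <= 0:
            raise GeometryError("axial extent, diameter and thickness must be positive")
        for tau in (self.tort_xz, self.tort_yz):
            if abs(tau) < 1.0:
                raise GeometryError("|tortuosity| must be >= 1 (1.00 = straight)")


#: Table-of-baseline sac parameters (underlined values).
BASELINE_AAA_GEOMETRY = AAAParameters()


def load_geometry_config(path):
    """(ReferentGeometryParameters, AAAParameters | None) from a YAML config.

    Top-level keys ``referent`` and ``aaa`` each hold a key-value mapping of
    the dataclass fields; either may be omitted for the defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    ref = ReferentGeometryParameters(**(data.get("referent") or {}))
    aaa = AAAParameters(**data["aaa"]) if data.get("aaa") is not None else None
    return ref, aaa


def tortuosity_to_sagitta(tau: float, chord: float) -> float:
    """Maximum centerline offset (sagitta, mm) of a circular-arc centerline.

    The tortuous centerline is modeled as a circular arc whose
    arc-length/chord ratio equals |tau|; the sagitta follows from the arc
    half-angle theta/2 solving ``theta / (2 sin(theta/2)) = |tau|``.  The sign
    of tau selects the bow direction.
    """
    a = abs(tau)
    if a < 1.0:
        raise GeometryError("|tau| must be >= 1")
    if a == 1.0:
        return 0.0
    f = lambda th: th / (2.0 * np.sin(th / 2.0)) - a
    theta = brentq(f, 1e-9, 2.0 * np.pi - 1e-9, xtol=1e-14)
    s = (chord / 2.0) * (1.0 - np.cos(theta / 2.0)) / np.sin(theta / 2.0)
    return float(np.sign(tau) * s)


def _arc_offset(z: np.ndarray, chord: float, sagitta: float) -> np.ndarray:
    """In-plane offset of a circular-arc centerline pinned at z=0 and z=chord."""
    if sagitta == 0.0:
        return np.zeros_like(np.asarray(z, dtype=float))
    s = abs(sagitta)
    R = s / 2.0 + chord**2 / (8.0 * s)
    off = np.sqrt(np.maximum(R**2 - (np.asarray(z, float) - chord / 2.0) ** 2, 0.0)) - (R - s)
    return np.sign(sagitta) * off


def circumferential_profile(
    circ_extent: float, bulge_outer_radius: float, base_outer_radius: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed outer profile r(theta) of a (possibly partial) sac cross-section.

    For 360 degrees the profile is a circle of the bulge radius.  Otherwise a
    bulged arc of angular width ``circ_extent`` centered on the anterior
    direction (theta = 0) carries the bulge radius, and a C1 cosine blend over
    the remaining angle returns the profile to the referent circle, which it
    touches at the posterior point.
    """
    if circ_extent not in (90.0, 180.0, 270.0, 360.0):
        raise GeometryError("circ_extent must be one of 90, 180, 270, 360 degrees")

    dR = bulge_outer_radius - base_outer_radius

    def r(theta: np.ndarray) -> np.ndarray:
        th = np.mod(np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
        if circ_extent == 360.0:
            return np.full_like(th, bulge_outer_radius)
        half = np.deg2rad(circ_extent) / 2.0
        u = (np.abs(th) - half) / (np.pi - half)  # 0..1 across the half-gap
        g = np.where(np.abs(th) <= half, 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(u, 0.0, 1.0))))
        return base_outer_radius + dR * g

    return r


def _smoothstep5(s):
    s = np.clip(s, 0.0, 1.0)
    return s**3 * (10.0 - 15.0 * s + 6.0 * s * s)


def _axial_loft_weight(loc: float, extent: float, rel_threshold: float | None = None):
    """Loft weight w(z): 1 between the dilated planes, C2 shoulders outside.

    The two fully dilated planes sit at loc -/+ extent/8 (one CS spacing
    apart at the baseline extent) and carry the full sac profile; quintic
    smoothstep shoulders blend back to the referent sections.  A clamped
    blend is used rather than an interpolating spline through the section
    stack: interpolation rings by several percent in radius, which would
    corrupt the defining maximum-transverse-diameter parameter (the sac
    carries exactly the prescribed diameter on the dilated planes).

    `rel_threshold` is the weight at which the bulge becomes geometrically
    measurable (e.g. 1% of the referent radius over the bulge amplitude);
    when given, the shoulder support is extended slightly so the measurable
    bulged span equals the requested axial extent.
    """
    p = _PLATEAU_FRACTION * extent            # plateau half-width (extent/8)
    h = extent / 2.0
    h_eff = h
    if rel_threshold is not None and 0.0 < rel_threshold < 0.5:
        s_star = brentq(lambda s: _smoothstep5(s) - rel_threshold, 0.0, 0.5)
        h_eff = (h - s_star * p) / (1.0 - s_star)

    def w(z):
        dz = np.abs(np.asarray(z, dtype=float) - loc)
        s = (h_eff - dz) / (h_eff - p)
        return np.where(dz <= p, 1.0, _smoothstep5(s))

    return w


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class CrossSection:
    """Sampled closed profile pair of one CS plane."""

    z: float
    center: tuple[float, float]
    theta: np.ndarray
    r_inner: np.ndarray
    r_outer: np.ndarray

    def polygon_outer(self) -> np.ndarray:
        cx, cy = self.center
        return np.stack(
            [cx + self.r_outer * np.cos(self.theta), cy + self.r_outer * np.sin(self.theta)], axis=1
        )


@dataclass
class VesselSolid:
    """Tagged parametric boundary representation of the vessel wall.

    The solid is fully described by the callables below; surfaces are sampled
    on demand (meshing, STL export).  Boundary tags: ``lumen``, ``outer_wall``
    and the end caps ``cap_inlet`` (aortic inlet, z = z_max),
    ``cap_outlet_left`` / ``cap_outlet_right`` (iliac outlets at z = z_min,
    split at the x = 0 symmetry plane).
    """

    ref: ReferentGeometryParameters
    aaa: AAAParameters | None
    z_min: float
    z_max: float
    sac_span: tuple[float, float]
    center: Callable[[np.ndarray], np.ndarray]          # (n,) z -> (n, 2) offsets
    r_outer: Callable[[np.ndarray, np.ndarray], np.ndarray]   # (theta, z) -> r
    r_inner: Callable[[np.ndarray, np.ndarray], np.ndarray]
    # junction description used for local frames (None above the bifurcation)
    lobe_center_x: Callable[[np.ndarray], np.ndarray]   # depth d -> half-separation
    lobe_center_y: Callable[[np.ndarray], np.ndarray]
    provenance: dict = field(default_factory=dict)

    # -- sampling helpers -------------------------------------------------
    def surface_point(self, theta, z, s):
        """Point on the wall: s=0 lumen, s=1 outer surface."""
        theta = np.asarray(theta, float)
        z = np.asarray(z, float)
        ri = self.r_inner(theta, z)
        ro = self.r_outer(theta, z)
        r = ri + (ro - ri) * s
        c = self.center(z)
        x = c[..., 0] + r * np.cos(theta)
        y = c[..., 1] + r * np.sin(theta)
        return np.stack([x, y, np.broadcast_to(z, x.shape)], axis=-1)

    def cross_sections(self, n_theta: int = 128) -> list[CrossSection]:
        """The nine CS0..CS8 planes as sampled profile pairs."""
        theta = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
        out = []
        for k in range(9):
            z = k * CS_SPACING
            c = self.center(np.array([z]))[0]
            out.append(
                CrossSection(
                    z=z,
                    center=(float(c[0]), float(c[1])),
                    theta=theta,
                    r_inner=self.r_inner(theta, np.full_like(theta, z)),
                    r_outer=self.r_outer(theta, np.full_like(theta, z)),
                )
            )
        return out

    # -- export -----------------------------------------------------------
    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=float)

    def to_stl(self, path, n_theta: int = 96, n_z: int = 160) -> None:
        """ASCII STL of the outer wall surface (visualization aid)."""
        th = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
        zs = np.linspace(self.z_min, self.z_max, n_z)
        T, Z = np.meshgrid(th, zs, indexing="ij")
        pts = self.surface_point(T, Z, 1.0)
        with open(path, "w") as fh:
            fh.write("solid vessel\n")
            for i in range(n_theta):
                i2 = (i + 1) % n_theta
                for j in range(n_z - 1):
                    quad = [pts[i, j], pts[i2, j], pts[i2, j + 1], pts[i, j + 1]]
                    for tri in ((0, 1, 2), (0, 2, 3)):
                        a, b, c = (quad[k] for k in tri)
                        n = np.cross(b - a, c - a)
                        nn = np.linalg.norm(n)
                        n = n / nn if nn > 0 else n
                        fh.write(f" facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
                        fh.write("  outer loop\n")
                        for v in (a, b, c):
                            fh.write(f"   vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
                        fh.write("  endloop\n endfacet\n")
            fh.write("endsolid vessel\n")


# ---------------------------------------------------------------------------
# junction (aorto-iliac bifurcation) construction
# ---------------------------------------------------------------------------

def _junction_functions(ref: ReferentGeometryParameters):
    """Lobe center / radius profiles of the bifurcation region vs depth d = -z."""
    a = np.deg2rad(ref.alpha)
    b = np.deg2rad(ref.beta)
    Rc = ref.Rc
    rho_trunk = ref.D / 2.0
    rho_il0 = ref.iliac_D_prox / 2.0
    taper = (ref.iliac_D_prox - ref.iliac_D_dist) / 2.0 / ref.Li
    d_arc = Rc * np.sin(a)  # depth over which the centerline arc turns by alpha

    def cx(d):
        d = np.asarray(d, dtype=float)
        on_arc = Rc - np.sqrt(np.maximum(Rc**2 - np.minimum(d, d_arc) ** 2, 0.0))
        post = np.maximum(d - d_arc, 0.0) * np.tan(a)
        return on_arc + post

    def cy(d):
        # common out-of-plane drift toward the tilted bifurcation plane,
        # eased near the apex so the centerline leaves tangent to the axis
        d = np.asarray(d, dtype=float)
        s0 = 5.0
        return -np.tan(b) * (np.sqrt(d**2 + s0**2) - s0)

    def rho_out(d):
        d = np.asarray(d, dtype=float)
        w = _smoothstep(d / max(d_arc, 1e-9)) if d_arc > 0 else np.ones_like(d)
        rho_il = rho_il0 - taper * d
        return rho_trunk * (1.0 - w) + rho_il * w

    # truncation depth: lobe separation reaches _SEPARATION_FRACTION of the
    # (unthickened) inner lobe radius
    def gap(d):
        return cx(d) - _SEPARATION_FRACTION * (rho_out(d) - ref.t)

    d_hi = d_arc + ref.Li
    if a <= 1e-12:
        d_end = d_arc if d_arc > 0 else 10.0  # parallel iliacs never separate
    else:
        if gap(d_hi) < 0:
            raise GeometryError(
                "iliac lumens never separate within the iliac length; "
                "take-off angle / fillet radius combination infeasible"
            )
        d_end = float(brentq(gap, 1e-9, d_hi, xtol=1e-10))

    def rho_in(d):
        d = np.asarray(d, dtype=float)
        thick = ref.t * (1.0 + _CARINA_THICKENING * np.clip(d / d_end, 0.0, 1.0) ** 2)
        return rho_out(d) - thick

    if np.min(rho_in(d_end)) <= 0.2:
        raise GeometryError("wall thickness leaves no lumen in the junction region")
    return cx, cy, rho_out, rho_in, d_end


def _two_lobe_radius(theta, c, rho, smooth):
    """Star-shaped outline radius of the union of two discs at (+/-c, 0).

    Smooth maximum of the two per-disc ray supports; `smooth` rounds the
    reentrant crotch (carina) outward by ~smooth/2.
    """
    ct = np.cos(theta)
    disc = np.sqrt(np.maximum(rho**2 - c**2 + (c * ct) ** 2, 0.0))
    r1 = c * ct + disc
    r2 = -c * ct + disc
    return 0.5 * (r1 + r2 + np.sqrt((r1 - r2) ** 2 + smooth**2))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _make_solid(ref: ReferentGeometryParameters, aaa: AAAParameters | None) -> VesselSolid:
    cx_j, cy_j, rho_out_j, rho_in_j, d_end = _junction_functions(ref)
    R_base = ref.D / 2.0
    t_ref = ref.t
    z_max = L_STAR

    if aaa is not None:
        loc, ext = aaa.location_z, aaa.axial_extent
        z_lo = max(0.0, loc - ext / 2.0)
        z_hi = min(z_max, loc + ext / 2.0)
        sag_x = tortuosity_to_sagitta(aaa.tort_xz, z_max)
        sag_y = tortuosity_to_sagitta(aaa.tort_yz, z_max)
        prof_g = circumferential_profile(aaa.circ_extent, aaa.max_diameter / 2.0, R_base)
        amp = aaa.max_diameter / 2.0 - R_base
        thr = 0.01 * R_base / amp if amp > 0.011 * R_base else None
        w_loft = _axial_loft_weight(loc, ext, thr)
    else:
        z_lo, z_hi = 0.0, min(BASELINE_AAA_GEOMETRY.axial_extent, z_max)
        sag_x = sag_y = 0.0
        prof_g = None

    # centerline offset: circular arcs over the trunk, tangent-extended below z=0
    def center(z):
        z = np.asarray(z, dtype=float)
        offx = _arc_offset(np.clip(z, 0.0, z_max), z_max, sag_x)
        offy = _arc_offset(np.clip(z, 0.0, z_max), z_max, sag_y)
        if sag_x != 0.0 or sag_y != 0.0:
            h = 1e-6
            slope_x = (_arc_offset(np.array([h]), z_max, sag_x)[0]) / h
            slope_y = (_arc_offset(np.array([h]), z_max, sag_y)[0]) / h
            below = np.minimum(z, 0.0)
            offx = offx + slope_x * below
            offy = offy + slope_y * below
        cyj = cy_j(np.maximum(-z, 0.0))
        return np.stack([offx, offy + cyj], axis=-1)

    def _trunk_radii(theta, z):
        """(r_inner, r_outer) for z >= 0 (trunk + optional sac)."""
        if aaa is None:
            ro = np.broadcast_to(R_base, np.broadcast(theta, z).shape).copy()
            ri = ro - t_ref
            return ri, ro
        # fade the bulge out over the first few mm above the bifurcation
        # plane so a support clipped at CS0 still meets the junction flush
        b = w_loft(z) * _smoothstep5(np.asarray(z, dtype=float) / 4.0)
        g = prof_g(theta) - R_base  # circumferential shape increment
        ro = R_base + g * b
        tt = t_ref - (t_ref - aaa.sac_thickness) * b
        return ro - tt, ro

    def r_outer(theta, z):
        theta = np.asarray(theta, float)
        z = np.asarray(z, float)
        theta, z = np.broadcast_arrays(theta, z)
        out = np.empty_like(z, dtype=float)
        up = z >= 0.0
        if np.any(up):
            _, out_up = _trunk_radii(theta[up], z[up])
            out[up] = out_up
        if np.any(~up):
            d = -z[~up]
            sm = _CROTCH_SMOOTH * np.clip(d / 5.0, 0.0, 1.0)
            out[~up] = _two_lobe_radius(theta[~up], cx_j(d), rho_out_j(d), sm)
        return out

    def r_inner(theta, z):
        theta = np.asarray(theta, float)
        z = np.asarray(z, float)
        theta, z = np.broadcast_arrays(theta, z)
        out = np.empty_like(z, dtype=float)
        up = z >= 0.0
        if np.any(up):
            in_up, _ = _trunk_radii(theta[up], z[up])
            out[up] = in_up
        if np.any(~up):
            d = -z[~up]
            sm = _CROTCH_SMOOTH * np.clip(d / 5.0, 0.0, 1.0)
            out[~up] = _two_lobe_radius(theta[~up], cx_j(d), rho_in_j(d), sm)
        return out

    prov = {"referent": asdict(ref), "aaa": asdict(aaa) if aaa is not None else None,
            "z_min": -d_end, "z_max": z_max, "sac_span": [z_lo, z_hi]}
    return VesselSolid(
        ref=ref, aaa=aaa, z_min=-d_end, z_max=z_max, sac_span=(z_lo, z_hi),
        center=center, r_outer=r_outer, r_inner=r_inner,
        lobe_center_x=cx_j, lobe_center_y=cy_j, provenance=prov,
    )


def build_referent(params: ReferentGeometryParameters | None = None) -> VesselSolid:
    """Referent normal aorta-iliac solid (no aneurysm)."""
    return _make_solid(params or ReferentGeometryParameters(), None)


def build_aaa(
    ref: ReferentGeometryParameters | None = None,
    aaa: AAAParameters | None = None,
) -> VesselSolid:
    """Aneurysmal variant of the referent solid."""
    ref = ref or ReferentGeometryParameters()
    aaa = aaa if aaa is not None else BASELINE_AAA_GEOMETRY
    if aaa.max_diameter < ref.D:
        raise GeometryError("sac diameter below the referent diameter is infeasible")
    if aaa.sac_thickness > ref.t:
        raise GeometryError("sac thickness above the referent thickness is out of range")
    return _make_solid(ref, aaa)


@dataclass
class _TubeSolid(VesselSolid):
    pass


def build_cylinder(inner_radius: float, outer_radius: float, length: float) -> VesselSolid:
    """Straight thick-walled tube (verification geometry), capped at both ends."""
    if not 0 < inner_radius < outer_radius:
        raise GeometryError("need 0 < Ri < Ro")
    t = outer_radius - inner_radius

    def center(z):
        z = np.asarray(z, dtype=float)
        return np.zeros(z.shape + (2,))

    r_out = lambda theta, z: np.broadcast_to(outer_radius, np.broadcast(theta, z).shape).copy()
    r_in = lambda theta, z: np.broadcast_to(inner_radius, np.broadcast(theta, z).shape).copy()
    zero = lambda d: np.zeros_like(np.asarray(d, dtype=float))
    ref = ReferentGeometryParameters(D=2 * outer_radius, t=t, L=length)
    return _TubeSolid(
        ref=ref, aaa=None, z_min=0.0, z_max=length, sac_span=(0.0, length),
        center=center, r_outer=r_out, r_inner=r_in,
        lobe_center_x=zero, lobe_center_y=zero,
        provenance={"cylinder": {"Ri": inner_radius, "Ro": outer_radius, "L": length}},
    )
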