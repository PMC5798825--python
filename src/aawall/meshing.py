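"""Volume meshing of vessel solids into tagged first-order tetrahedra.

The generalized-cylinder parameterization of :mod:`aawall.geometry` admits a
structured grid in (z, theta, radial) space; each hexahedral cell is split
into six tetrahedra by the Kuhn (Freudenthal) triangulation, which is
translation-invariant and therefore conforming across cells and across the
periodic seam.  Boundary triangles inherit tags from the solid (lumen,
outer_wall, aortic inlet cap, two iliac outlet caps).

Each element additionally carries an orthonormal local vessel frame
(radial, circumferential, axial) derived from the construction centerlines,
and the reference fiber direction pair rotated into that frame.  Within the
bifurcation region the axial director blends the trunk and iliac centerline
tangents by inverse-distance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constitutive import fiber_directions
from .geometry import VesselSolid

__all__ = ["Mesh", "MeshingError", "generate_mesh", "assign_local_frames", "mesh_independence"]


class MeshingError(RuntimeError):
    pass


# Kuhn triangulation of the unit cube: six tets along the main diagonal.
# Offsets in (i, j, k) = (z, theta, r) index space.
def _kuhn_tets():
    import itertools

    corners = {}
    for dz in (0, 1):
        for dt in (0, 1):
            for dr in (0, 1):
                corners[(dz, dt, dr)] = (dz, dt, dr)
    tets = []
    for perm in itertools.permutations(range(3)):
        v = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] += 1
            v.append(tuple(cur))
        # odd permutations give negative orientation: swap last two vertices
        parity = _perm_sign(perm)
        if parity < 0:
            v[2], v[3] = v[3], v[2]
        tets.append(v)
    return tets


def _perm_sign(p):
    s = 1
    p = list(p)
    for i in range(len(p)):
        while p[i] != i:
            j = p[i]
            p[i], p[j] = p[j], p[i]
            s = -s
    return s


_KUHN = _kuhn_tets()


@dataclass
class Mesh:
    """First-order tetrahedral mesh with boundary tags and per-element frames."""

    nodes: np.ndarray                     # (N, 3) reference coordinates [mm]
    tets: np.ndarray                      # (E, 4) connectivity
    boundary: dict[str, np.ndarray]       # tag -> (F, 3) outward-oriented triangles
    node_grid: np.ndarray                 # (N, 3) structured (iz, itheta, ir) indices
    grid_shape: tuple[int, int, int]      # (nz, ntheta, nr) cell counts
    volumes: np.ndarray = field(default=None)       # (E,)
    grads: np.ndarray = field(default=None)         # (E, 4, 3) shape-function gradients
    centroids: np.ndarray = field(default=None)     # (E, 3)
    frames: np.ndarray = field(default=None)        # (E, 3, 3) rows: radial, circ, axial
    fiber_a04: np.ndarray = field(default=None)     # (E, 3) global-frame fiber directions
    fiber_a06: np.ndarray = field(default=None)
    quality: np.ndarray = field(default=None)       # (E,) edge aspect ratio

    def __post_init__(self):
        if self.volumes is None:
            self._compute_geometry()

    def _compute_geometry(self):
        X = self.nodes[self.tets]                    # (E, 4, 3)
        Dm = X[:, 1:, :] - X[:, :1, :]               # (E, 3, 3) rows: edges
        det = np.linalg.det(Dm)
        if np.any(det <= 0):
            bad = int(np.sum(det <= 0))
            raise MeshingError(f"{bad} inverted/degenerate elements in generated mesh")
        self.volumes = det / 6.0
        # x = X0 + Dm^T xi  =>  grad N_a = column a-1 of Dm^{-1} for a = 1..3
        Dminv = np.linalg.inv(Dm)                    # (E, 3, 3)
        grads = np.empty((len(self.tets), 4, 3))
        grads[:, 1:, :] = np.swapaxes(Dminv, 1, 2)
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
        self.grads = grads
        self.centroids = X.mean(axis=1)
        e = X[:, [0, 0, 0, 1, 1, 2], :] - X[:, [1, 2, 3, 2, 3, 3], :]
        el = np.linalg.norm(e, axis=2)
        self.quality = el.max(axis=1) / el.min(axis=1)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.tets)


def _resolution(solid: VesselSolid, target_edge: float):
    zs = np.linspace(solid.z_min, solid.z_max, 64)
    th = np.linspace(-np.pi, np.pi, 32, endpoint=False)
    T, Z = np.meshgrid(th, zs, indexing="ij")
    ro = solid.r_outer(T, Z)
    ri = solid.r_inner(T, Z)
    r_mean = 0.5 * float((ro + ri).mean())
    t_mean = float((ro - ri).mean())
    length = solid.z_max - solid.z_min
    nz = max(8, int(np.ceil(length / target_edge)))
    # angular floor: inscribed-polygon area error (2 pi / n)^2 / 6 kept below 0.8%
    n_floor = int(np.ceil(2.0 * np.pi / np.sqrt(6.0 * 0.008)))
    ntheta = max(n_floor, int(np.ceil(2.0 * np.pi * r_mean / target_edge)))
    nr = max(2, int(round(t_mean / target_edge)))
    return nz, ntheta, nr


def generate_mesh(solid: VesselSolid, target_edge: float,
                  resolution: tuple[int, int, int] | None = None) -> Mesh:
    """Conforming tet mesh of the vessel wall with >= 2 elements through thickness.

    `target_edge` [mm] sets the nominal element edge; `resolution` overrides
    the derived (nz, ntheta, nr) cell counts directly.
    """
    nz, ntheta, nr = resolution if resolution is not None else _resolution(solid, target_edge)
    nr = max(nr, 2)

    zs = np.linspace(solid.z_min, solid.z_max, nz + 1)
    thetas = np.linspace(-np.pi, np.pi, ntheta, endpoint=False)
    svals = np.linspace(0.0, 1.0, nr + 1)

    T = np.broadcast_to(thetas[None, :, None], (nz + 1, ntheta, nr + 1))
    Z = np.broadcast_to(zs[:, None, None], (nz + 1, ntheta, nr + 1))
    S = np.broadcast_to(svals[None, None, :], (nz + 1, ntheta, nr + 1))
    pts = solid.surface_point(T, Z, S)               # (nz+1, ntheta, nr+1, 3)
    nodes = pts.reshape(-1, 3)

    def nid(iz, it, ir):
        return (iz * ntheta + (it % ntheta)) * (nr + 1) + ir

    IZ, IT, IR = np.meshgrid(np.arange(nz), np.arange(ntheta), np.arange(nr), indexing="ij")
    IZ, IT, IR = IZ.ravel(), IT.ravel(), IR.ravel()
    tets = np.empty((len(IZ) * 6, 4), dtype=np.int64)
    for m, tet in enumerate(_KUHN):
        for v, (dz, dt, dr) in enumerate(tet):
            tets[m::6, v] = nid(IZ + dz, IT + dt, IR + dr)

    grid = np.empty((len(nodes), 3), dtype=np.int64)
    iz_idx = np.arange(nz + 1)
    grid[:, 0] = np.repeat(iz_idx, ntheta * (nr + 1))
    grid[:, 1] = np.tile(np.repeat(np.arange(ntheta), nr + 1), nz + 1)
    grid[:, 2] = np.tile(np.arange(nr + 1), (nz + 1) * ntheta)

    # fix orientation if needed (mapping may flip chirality)
    X = nodes[tets]
    det = np.linalg.det(X[:, 1:, :] - X[:, :1, :])
    flip = det < 0
    if np.any(flip):
        tmp = tets[flip, 2].copy()
        tets[flip, 2] = tets[flip, 3]
        tets[flip, 3] = tmp

    boundary = _extract_boundary(nodes, tets, grid, nz, nr)
    mesh = Mesh(nodes=nodes, tets=tets, boundary=boundary, node_grid=grid,
                grid_shape=(nz, ntheta, nr))
    assign_local_frames(mesh, solid)
    return mesh


def _extract_boundary(nodes, tets, grid, nz, nr):
    # all four faces of each tet, opposite-vertex bookkeeping for orientation
    faces = np.concatenate([
        tets[:, [1, 2, 3]], tets[:, [0, 3, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 1]],
    ])
    opp = np.concatenate([tets[:, 0], tets[:, 1], tets[:, 2], tets[:, 3]])
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    dup = np.all(ks[1:] == ks[:-1], axis=1)
    is_dup = np.zeros(len(ks), bool)
    is_dup[1:] |= dup
    is_dup[:-1] |= dup
    bidx = order[~is_dup]
    bfaces, bopp = faces[bidx], opp[bidx]

    # orient outward: normal away from the opposite vertex
    a, b, c = nodes[bfaces[:, 0]], nodes[bfaces[:, 1]], nodes[bfaces[:, 2]]
    n = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", n, nodes[bopp] - a) > 0
    bfaces[inward] = bfaces[inward][:, [0, 2, 1]]

    iz = grid[bfaces, 0]
    ir = grid[bfaces, 2]
    tags = {}
    on_bottom = np.all(iz == 0, axis=1)
    on_top = np.all(iz == nz, axis=1)
    on_lumen = np.all(ir == 0, axis=1) & ~on_bottom & ~on_top
    on_outer = np.all(ir == nr, axis=1) & ~on_bottom & ~on_top
    cen_x = nodes[bfaces].mean(axis=1)[:, 0]
    tags["cap_inlet"] = bfaces[on_top]
    tags["cap_outlet_left"] = bfaces[on_bottom & (cen_x < 0)]
    tags["cap_outlet_right"] = bfaces[on_bottom & (cen_x >= 0)]
    tags["lumen"] = bfaces[on_lumen]
    tags["outer_wall"] = bfaces[on_outer]
    n_tagged = sum(len(v) for v in tags.values())
    if n_tagged != len(bfaces):
        raise MeshingError(
            f"boundary tagging incomplete: {len(bfaces)} boundary faces, {n_tagged} tagged"
        )
    return tags


def assign_local_frames(mesh: Mesh, solid: VesselSolid) -> Mesh:
    """Per-element (radial, circumferential, axial) frames and fiber anchors.

    The frame follows the *wall mid-surface*: the radial director is the
    surface normal, the axial director is the in-surface meridian (the
    surface tangent along the vessel's longitudinal parameter), and the
    circumferential director completes the right-handed triad.  The helical
    fiber families therefore always lie in the wall surface — on the sac
    shoulders and through the bifurcation flare the meridian tilts with the
    wall, which is what a helix "at angle phi from the longitudinal vessel
    axis" means on a curved vessel.  For a straight tube this reduces to the
    cylindrical (e_r, e_theta, e_z) triad exactly.
    """
    cen = mesh.centroids
    z = cen[:, 2]
    c = solid.center(z)
    theta = np.arctan2(cen[:, 1] - c[:, 1], cen[:, 0] - c[:, 0])
    h_z, h_t = 1e-4, 1e-4

    def mid_surface(th, zz):
        ri = solid.r_inner(th, zz)
        ro = solid.r_outer(th, zz)
        R = 0.5 * (ri + ro)
        cc = solid.center(zz)
        return np.stack([cc[..., 0] + R * np.cos(th),
                         cc[..., 1] + R * np.sin(th), zz], axis=-1)

    T_z = (mid_surface(theta, z + h_z) - mid_surface(theta, z - h_z)) / (2 * h_z)
    T_t = (mid_surface(theta + h_t, z) - mid_surface(theta - h_t, z)) / (2 * h_t)
    circ = T_t / np.linalg.norm(T_t, axis=1, keepdims=True)
    axial = T_z - circ * np.einsum("ij,ij->i", T_z, circ)[:, None]
    nrm = np.linalg.norm(axial, axis=1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise MeshingError("degenerate meridian direction on the wall surface")
    axial /= nrm
    rad = np.cross(circ, axial)
    rad /= np.linalg.norm(rad, axis=1, keepdims=True)

    mesh.frames = np.stack([rad, circ, axial], axis=1)
    return mesh


def set_fibers(mesh: Mesh, phi: float) -> Mesh:
    """Rotate the +/-phi fiber pair into every element's local frame."""
    a04_loc, a06_loc = fiber_directions(phi)
    R = mesh.frames  # rows radial, circ, axial
    mesh.fiber_a04 = np.einsum("j,eji->ei", a04_loc, R)
    mesh.fiber_a06 = np.einsum("j,eji->ei", a06_loc, R)
    return mesh


def mesh_independence(run, levels: Sequence[float], threshold: float = 4.0):
    """Refine until PWS and AWS each change by less than `threshold` percent.

    `run` is a callable mapping a target edge length to a
    :class:`aawall.postprocess.StressSummary`; `levels` is a decreasing list
    of edge lengths.  Returns ``(edge, report)`` where `edge` is the coarsest
    level whose next refinement changes both responses by < threshold, and
    `report` is a list of per-level dicts with pairwise percent changes.
    """
    if len(levels) < 2:
        raise ValueError("need at least two refinement levels")
    report = []
    prev = None
    converged_edge = None
    for edge in levels:
        summ = run(edge)
        entry = {"target_edge": edge, "PWS": summ.PWS, "AWS": summ.AWS,
                 "n_elements": summ.n_elements}
        if prev is not None:
            dp = abs(summ.PWS - prev["PWS"]) / abs(prev["PWS"]) * 100.0
            da = abs(summ.AWS - prev["AWS"]) / abs(prev["AWS"]) * 100.0
            entry["pct_change_PWS"] = dp
            entry["pct_change_AWS"] = da
            if converged_edge is None and dp < threshold and da < threshold:
                converged_edge = prev["target_edge"]
        report.append(entry)
        prev = entry
    if converged_edge is None:
        entry = report[-1]
        entry["converged"] = False
    return converged_edge, report
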