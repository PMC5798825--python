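"""Static total-Lagrangian finite-element solution of the pressurized vessel.

Displacement-based formulation on first-order tetrahedra with one quadrature
point per element (consistent with the linear interpolation).  Pure-
displacement linear tetrahedra lock volumetrically under the wall model's
near incompressibility, so the default formulation treats the volumetric
energy with *average nodal pressures* (a mean-dilatation treatment over
node patches): each node carries the volume-weighted average Jacobian of
its element patch, the volumetric energy is ``sum_n kappa/2 (Jbar_n - 1)^2
V_n``, and elements see the mean of their four nodal pressures.  This
removes both the locking and the element-level checkerboard pressure while
keeping the tangent exact (the patch coupling assembles as a sparse
rank-one product).  A pure-penalty (element-level) fallback is retained.

The luminal pressure is a follower load: it acts normal to the *deformed*
lumen surface, and its (nonsymmetric) load stiffness is included in the
Newton tangent, which is otherwise the exact complex-step linearization of
the internal forces — residual norms therefore drop quadratically near the
root.  The pressure is ramped in equal increments from zero; a diverged
increment is retried with automatic bisection of the load step (bounded
depth).  All end-cap node displacements are fully fixed (first-order
tetrahedra carry no rotational degrees of freedom, so "complete motion
constraint" reduces to displacement fixation).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as co
from .constitutive import MaterialParameters
from .meshing import Mesh, generate_mesh, set_fibers

__all__ = [
    "BoundaryConditions",
    "SolverSettings",
    "Solution",
    "SolverError",
    "assemble_residual",
    "total_potential_energy",
    "newton_solve",
    "reaction_balance",
    "run_case",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoundaryConditions:
    """Static luminal pressure with constrained end caps.

    cap_mode 'fixed' clamps every displacement component of all end-cap nodes
    (the vessel studies' condition).  'axial_roller' constrains only the
    axial component plus a minimal in-plane pinning of rigid modes — the
    plane-strain condition matched by the thick-walled-cylinder oracle.
    """

    pressure: float = 0.016          # MPa (120 mmHg as printed)
    increments: int = 10
    fixed_tags: tuple[str, ...] = ("cap_inlet", "cap_outlet_left", "cap_outlet_right")
    cap_mode: str = "fixed"

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")
        if self.increments < 1:
            raise ValueError("need at least one increment")
        if self.cap_mode not in ("fixed", "axial_roller"):
            raise ValueError(f"unknown cap_mode {self.cap_mode!r}")


@dataclass(frozen=True)
class SolverSettings:
    tol: float = 1e-8                # relative residual tolerance
    max_iter: int = 25
    line_search: bool = True
    incompressibility: str = "nodal"     # "nodal" (average nodal pressure) or "penalty"
    # fraction of kappa kept as an element-level penalty in nodal mode; damps
    # the patch formulation's element-level Jacobian oscillation modes while
    # contributing negligible locking or element-pressure bias
    stab_fraction: float = 0.02
    max_bisections: int = 4
    # trust-region cap on the Newton step [mm]: the unloaded wall is
    # bending-soft while the fiber response stiffens exponentially, so an
    # uncapped first step can overshoot far outside the model's range
    max_step: float = 0.5
    # exponent of the ramp schedule p_k = P (k/n)^ramp_power: > 1 concentrates
    # increments at low pressure where the shell is most compliant
    ramp_power: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.tol < 1.0:
            raise ValueError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.incompressibility not in ("nodal", "penalty"):
            raise ValueError(f"unknown incompressibility treatment {self.incompressibility!r}")


@dataclass
class Solution:
    u: np.ndarray                    # (N, 3) nodal displacements [mm]
    stress: np.ndarray               # (E, 3, 3) Cauchy stress at centroids [MPa]
    history: list                    # per-increment dicts with residual norms
    converged: bool
    provenance: dict = field(default_factory=dict)

    def deformed(self, mesh: Mesh) -> np.ndarray:
        return mesh.nodes + self.u


def _fixed_mask(mesh: Mesh, bc: BoundaryConditions) -> np.ndarray:
    """Per-node, per-component constraint mask (N, 3)."""
    cap = np.zeros(mesh.n_nodes, dtype=bool)
    for tag in bc.fixed_tags:
        tris = mesh.boundary.get(tag)
        if tris is not None and len(tris):
            cap[np.unique(tris)] = True
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    if bc.cap_mode == "fixed":
        fixed[cap] = True
        return fixed
    # axial roller: uz = 0 on caps; pin in-plane rigid translation/rotation at
    # two cap nodes (choices lie on the symmetry axis of the axisymmetric
    # solution, so they do not disturb it)
    fixed[cap, 2] = True
    capidx = np.nonzero(cap)[0]
    pts = mesh.nodes[capidx]
    zlo = pts[:, 2].min()
    onz = capidx[np.abs(pts[:, 2] - zlo) < 1e-9]
    p = mesh.nodes[onz]
    pin1 = onz[np.argmax(p[:, 0])]          # near (+R, 0): fix x and y
    pin2 = onz[np.argmin(p[:, 0])]          # near (-R, 0): fix y
    fixed[pin1, 0] = fixed[pin1, 1] = True
    fixed[pin2, 1] = True
    return fixed


def _deformation_gradients(mesh: Mesh, u: np.ndarray) -> np.ndarray:
    du = np.einsum("eai,eaj->eij", u[mesh.tets], mesh.grads)
    return np.eye(3)[None] + du


def _pressure_forces(mesh, tris, pressure, u, want_tangent):
    """Follower-load nodal forces and (optionally) load-stiffness blocks.

    `tris` are outward-oriented lumen triangles; the pressure pushes the wall
    along the inward-to-solid direction (opposite the outward normal).
    """
    x = (mesh.nodes + u)[tris]                  # (T, 3, 3)
    e1 = x[:, 1] - x[:, 0]
    e2 = x[:, 2] - x[:, 0]
    cr = np.cross(e1, e2)                       # outward normal * 2A
    f = np.zeros_like(u)
    fr = np.repeat((-pressure / 6.0) * cr[:, None, :], 3, axis=1)
    np.add.at(f, tris, fr)
    if not want_tangent:
        return f, None

    def skew(v):
        S = np.zeros(v.shape[:-1] + (3, 3))
        S[..., 0, 1], S[..., 0, 2] = -v[..., 2], v[..., 1]
        S[..., 1, 0], S[..., 1, 2] = v[..., 2], -v[..., 0]
        S[..., 2, 0], S[..., 2, 1] = -v[..., 1], v[..., 0]
        return S
    # dc/dx1 = skew(e2) - skew(e1); dc/dx2 = -skew(e2); dc/dx3 = skew(e1)
    dc = np.stack([skew(e2) - skew(e1), -skew(e2), skew(e1)], axis=1)  # (T, b, i, k)
    Kt = np.repeat(((-pressure / 6.0) * dc)[:, None, ...], 3, axis=1)   # (T, a, b, i, k)
    Kt = np.transpose(Kt, (0, 1, 3, 2, 4))                              # (T, a, i, b, k)
    return f, Kt


class _System:
    """Precomputed scatter maps for fast repeated assembly on one mesh."""

    def __init__(self, mesh: Mesh, bc: BoundaryConditions, settings: SolverSettings):
        self.mesh = mesh
        self.bc = bc
        self.settings = settings
        self.nodal = settings.incompressibility == "nodal"
        self.fixed_dofs = _fixed_mask(mesh, bc)          # (N, 3) bool
        self.free = ~self.fixed_dofs.ravel()
        self.dofmap = np.full(3 * mesh.n_nodes, -1, dtype=np.int64)
        self.dofmap[self.free] = np.arange(self.free.sum())
        self.ndof = int(self.free.sum())
        self.lumen = mesh.boundary["lumen"]

        dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        self.elem_dofs = dofs
        rows = np.repeat(dofs, 12, axis=1).ravel()
        cols = np.tile(dofs, (1, 12)).ravel()
        self._keep_int = (self.dofmap[rows] >= 0) & (self.dofmap[cols] >= 0)
        self.rows_int = self.dofmap[rows[self._keep_int]]
        self.cols_int = self.dofmap[cols[self._keep_int]]

        tdofs = (3 * self.lumen[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 9)
        trows = np.repeat(tdofs, 9, axis=1).ravel()
        tcols = np.tile(tdofs, (1, 9)).ravel()
        self._keep_ext = (self.dofmap[trows] >= 0) & (self.dofmap[tcols] >= 0)
        self.rows_ext = self.dofmap[trows[self._keep_ext]]
        self.cols_ext = self.dofmap[tcols[self._keep_ext]]

        # nodal-pressure bookkeeping: patch volumes V_n = sum_e V0_e / 4
        V4 = np.repeat(mesh.volumes / 4.0, 4)
        self.patch_vol = np.bincount(mesh.tets.ravel(), weights=V4, minlength=mesh.n_nodes)
        # H matrix sparsity: row = patch node, col = free dof of the element
        self._H_rows = np.repeat(mesh.tets.ravel(), 12)
        self._H_cols_full = np.tile(dofs, (1, 4)).reshape(-1)

    # -- volumetric (average nodal pressure) ------------------------------
    def _nodal_volumetric(self, kappa, F, want_tangent):
        mesh = self.mesh
        J = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        # g[e, a, i] = dJ_e / du_{a,i} / J = F^{-T}_{iK} gradN_{aK}; scale by J
        g = np.einsum("e,eKi,eaK->eai", J, Finv, mesh.grads)
        Jbar = np.bincount(mesh.tets.ravel(),
                           weights=np.repeat(mesh.volumes * J / 4.0, 4),
                           minlength=mesh.n_nodes) / self.patch_vol
        p_node = kappa * (Jbar - 1.0)
        pbar = p_node[mesh.tets].mean(axis=1)                 # (E,)
        fe = (pbar * mesh.volumes)[:, None, None] * g
        f = np.zeros((mesh.n_nodes, 3))
        np.add.at(f, mesh.tets, fe)
        energy = 0.5 * kappa * np.sum((Jbar - 1.0) ** 2 * self.patch_vol)
        if not want_tangent:
            return f, energy, None, pbar
        # element-local geometric part: d(J F^-T)/dF contracted with gradients
        w = (pbar * mesh.volumes / J)
        Ke = w[:, None, None, None, None] * (
            np.einsum("eai,ebk->eaibk", g, g) - np.einsum("ebi,eak->eaibk", g, g))
        # cross-patch rank-one coupling: K += H^T diag(kappa / V_n) H
        gv = (mesh.volumes / 4.0)[:, None] * g.reshape(len(g), 12)
        Hvals = np.tile(gv, (1, 4)).reshape(-1)
        keep = self.dofmap[self._H_cols_full] >= 0
        H = sp.coo_matrix(
            (Hvals[keep], (self._H_rows[keep], self.dofmap[self._H_cols_full[keep]])),
            shape=(self.mesh.n_nodes, self.ndof)).tocsr()
        D = sp.diags(kappa / self.patch_vol)
        K_cross = (H.T @ (D @ H)).tocsc()
        return f, energy, (Ke, K_cross), pbar

    # -- full residual/tangent --------------------------------------------
    def residual(self, mat, u, pressure, want_tangent=False):
        mesh = self.mesh
        F = _deformation_gradients(mesh, u)
        beta = self.settings.stab_fraction if self.nodal else 1.0
        P, A = co.pk1_stress_and_tangent(mat, F, mesh.fiber_a04, mesh.fiber_a06,
                                         want_tangent=want_tangent,
                                         volumetric=True, kappa_scale=beta)
        fe = np.einsum("e,eij,eaj->eai", mesh.volumes, P, mesh.grads)
        f_int = np.zeros_like(u)
        np.add.at(f_int, mesh.tets, fe)
        Ke = None
        if want_tangent:
            Ke = np.einsum("e,eaJ,eiJkL,ebL->eaibk", mesh.volumes, mesh.grads, A, mesh.grads)
        K_cross = None
        pbar = None
        if self.nodal:
            fv, _, Kv, pbar = self._nodal_volumetric(
                (1.0 - beta) * mat.kappa_vol, F, want_tangent)
            f_int = f_int + fv
            if want_tangent:
                Ke = Ke + Kv[0]
                K_cross = Kv[1]
        f_ext, Kt = _pressure_forces(mesh, self.lumen, pressure, u, want_tangent)
        r = (f_int - f_ext).ravel()
        K = None
        if want_tangent:
            vals = Ke.reshape(len(mesh.tets), -1).ravel()[self._keep_int]
            allv = [vals]
            allr = [self.rows_int]
            allc = [self.cols_int]
            if Kt is not None and len(self.lumen):
                allv.append((-Kt).reshape(len(self.lumen), -1).ravel()[self._keep_ext])
                allr.append(self.rows_ext)
                allc.append(self.cols_ext)
            K = sp.coo_matrix((np.concatenate(allv),
                               (np.concatenate(allr), np.concatenate(allc))),
                              shape=(self.ndof, self.ndof)).tocsc()
            if K_cross is not None:
                K = K + K_cross
        return r, K, f_ext, F, pbar

    def cauchy(self, mat, F, pbar):
        """Element Cauchy stress; nodal mode adds the smooth patch pressure."""
        mesh = self.mesh
        state = co.DeformationState(F=F, a04=mesh.fiber_a04, a06=mesh.fiber_a06)
        if not self.nodal:
            return co.cauchy_stress(mat, state)
        beta = self.settings.stab_fraction
        C = np.einsum("...ki,...kj->...ij", F, F)
        S = co.pk2_stress(mat, C, mesh.fiber_a04, mesh.fiber_a06,
                          volumetric=True, kappa_scale=beta)
        J = np.linalg.det(F)
        sig = np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]
        sig = 0.5 * (sig + np.swapaxes(sig, -1, -2))
        return sig + pbar[:, None, None] * np.eye(3)


def assemble_residual(mesh: Mesh, mat: MaterialParameters, bc: BoundaryConditions,
                      displacement: np.ndarray,
                      settings: SolverSettings | None = None):
    """Residual (free DOFs) and follower-load force field at a given state."""
    settings = settings or SolverSettings()
    sys = _System(mesh, bc, settings)
    r, _, f_ext, _, _ = sys.residual(mat, displacement, bc.pressure, want_tangent=False)
    return r[sys.free], f_ext


def total_potential_energy(mesh: Mesh, mat: MaterialParameters, bc: BoundaryConditions,
                           u: np.ndarray, settings: SolverSettings | None = None) -> float:
    """Total potential: strain energy minus pressure times swept lumen volume.

    Valid for energy-gradient checks: with the end caps fixed, the lumen
    surface rim is immobile and the pressure potential is ``-P * V`` with V
    the volume functional of the deformed lumen surface.
    """
    settings = settings or SolverSettings()
    sys = _System(mesh, bc, settings)
    F = _deformation_gradients(mesh, u)
    if settings.incompressibility == "nodal":
        beta = settings.stab_fraction
        C = np.einsum("...ki,...kj->...ij", F, F)
        detC, _, I1b, I4b, I6b = co._modified_invariants(C, mesh.fiber_a04, mesh.fiber_a06)
        J = np.sqrt(detC)
        psi = 0.5 * mat.mu * (I1b - 3.0)
        for Iib in (I4b, I6b):
            p, _ = co._fiber_psi_and_coef(mat, Iib)
            psi = psi + p
        psi = psi + 0.5 * beta * mat.kappa_vol * (J - 1.0) ** 2
        W = float(np.sum(psi * mesh.volumes))
        _, evol, _, _ = sys._nodal_volumetric((1.0 - beta) * mat.kappa_vol, F,
                                              want_tangent=False)
        W += float(evol)
    else:
        state = co.DeformationState(F=F, a04=mesh.fiber_a04, a06=mesh.fiber_a06)
        W = float(np.sum(co.strain_energy(mat, state) * mesh.volumes))
    x = (mesh.nodes + u)[mesh.boundary["lumen"]]
    vol = float(np.einsum("ti,ti->", x[:, 0], np.cross(x[:, 1], x[:, 2])) / 6.0)
    return W + bc.pressure * vol


def _solve_increment(sys: _System, mat, u, pressure, settings, history, verbose=False):
    mesh = sys.mesh
    rec = {"pressure": pressure, "residuals": []}
    r, _, f_ext, _, _ = sys.residual(mat, u, pressure, want_tangent=False)
    ref = max(np.linalg.norm(f_ext.ravel()[sys.free]), 1e-10)
    rn = np.linalg.norm(r[sys.free])
    rec["residuals"].append(rn)
    for it in range(settings.max_iter):
        if rn <= settings.tol * ref:
            rec["converged"] = True
            history.append(rec)
            if verbose:
                print(f"    p={pressure:.5f}: converged in {it} iterations", flush=True)
            return u
        _, K, _, _, _ = sys.residual(mat, u, pressure, want_tangent=True)
        lu = spla.splu(K)
        du_f = lu.solve(-r[sys.free])
        du = np.zeros(3 * mesh.n_nodes)
        du[sys.free] = du_f
        du = du.reshape(-1, 3)
        du_max = np.abs(du).max()
        capped = du_max > settings.max_step
        if capped:
            du *= settings.max_step / du_max

        step = 1.0
        while True:
            try:
                u_try = u + step * du
                r_try, _, _, _, _ = sys.residual(mat, u_try, pressure, want_tangent=False)
                rn_try = np.linalg.norm(r_try[sys.free])
                # a capped (non-Newton) step need not reduce the residual;
                # it only has to stay finite and in range
                if np.isfinite(rn_try) and (capped or rn_try < rn
                                            or not settings.line_search):
                    break
            except (ValueError, co.ConstitutiveOverflow, FloatingPointError):
                pass
            step *= 0.5
            if step < 1.0 / 32.0:
                rec["converged"] = False
                history.append(rec)
                raise SolverError(f"line search failed at pressure {pressure:.5f} MPa")
        u, r, rn = u_try, r_try, rn_try
        rec["residuals"].append(rn)
    rec["converged"] = rn <= settings.tol * ref
    history.append(rec)
    if not rec["converged"]:
        raise SolverError(
            f"Newton did not converge at pressure {pressure:.5f} MPa "
            f"(residual {rn:.3e}, reference {ref:.3e})"
        )
    return u


def newton_solve(mesh: Mesh, mat: MaterialParameters, bc: BoundaryConditions,
                 settings: SolverSettings | None = None,
                 u0: np.ndarray | None = None, verbose: bool = False) -> Solution:
    """Incremental follower-pressure ramp to the stationary solution.

    `u0` optionally warm-starts the ramp: the full pressure is attempted in a
    single increment from that state (with bisection fallback), which is much
    cheaper when a neighboring case's solution is available.
    """
    settings = settings or SolverSettings()
    if mesh.fiber_a04 is None:
        set_fibers(mesh, mat.phi)
    sys = _System(mesh, bc, settings)
    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else np.array(u0, copy=True)
    history: list = []
    t0 = time.perf_counter()

    if bc.pressure == 0.0:
        targets = []
    elif u0 is not None:
        targets = [bc.pressure]
    else:
        frac = (np.arange(1, bc.increments + 1) / bc.increments) ** settings.ramp_power
        targets = list(bc.pressure * frac)
    p_cur = 0.0
    pending = list(reversed(targets))
    bisections = 0
    while pending:
        p_next = pending.pop()
        try:
            u = _solve_increment(sys, mat, u, p_next, settings, history, verbose)
            p_cur = p_next
        except SolverError:
            bisections += 1
            if bisections > settings.max_bisections * max(2, len(targets)):
                raise SolverError(
                    f"pressure ramp failed near {p_next:.5f} MPa after repeated bisection; "
                    f"history: {[h['pressure'] for h in history]}"
                )
            pending.append(p_next)
            pending.append(0.5 * (p_cur + p_next))

    F = _deformation_gradients(mesh, u)
    pbar = None
    if sys.nodal:
        _, _, _, pbar = sys._nodal_volumetric(mat.kappa_vol, F, want_tangent=False)
    stress = sys.cauchy(mat, F, pbar)
    prov = {
        "pressure": bc.pressure, "increments": bc.increments,
        "settings": asdict(settings), "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements, "wall_time_s": time.perf_counter() - t0,
    }
    return Solution(u=u, stress=stress, history=history, converged=True, provenance=prov)


def reaction_balance(mesh: Mesh, mat: MaterialParameters, bc: BoundaryConditions,
                     sol: Solution, settings: SolverSettings | None = None) -> dict:
    """Global equilibrium check: reactions at fixed caps vs pressure resultant."""
    settings = settings or SolverSettings()
    sys = _System(mesh, bc, settings)
    r, _, f_ext, _, _ = sys.residual(mat, sol.u, bc.pressure, want_tangent=False)
    fixed = sys.fixed_dofs.ravel()
    reactions = np.where(fixed, r, 0.0).reshape(-1, 3).sum(axis=0)
    x = (mesh.nodes + sol.u)[sys.lumen]
    cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    load = (-bc.pressure / 2.0) * cr.sum(axis=0)
    return {"reaction": reactions, "pressure_resultant": load}


def run_case(solid, mat: MaterialParameters, bc: BoundaryConditions | None = None,
             settings: SolverSettings | None = None, target_edge: float = 2.6,
             resolution: tuple[int, int, int] | None = None):
    """Full pipeline: solid -> mesh -> frames/fibers -> solve.

    Returns ``(mesh, solution)``; the solution's provenance records every
    input parameter and the mesh level.
    """
    bc = bc or BoundaryConditions()
    mesh = generate_mesh(solid, target_edge, resolution=resolution)
    set_fibers(mesh, mat.phi)
    sol = newton_solve(mesh, mat, bc, settings)
    sol.provenance.update({
        "material": asdict(mat), "bc": asdict(bc),
        "target_edge": target_edge, "geometry": solid.provenance,
    })
    return mesh, sol
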