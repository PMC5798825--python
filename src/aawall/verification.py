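"""Semi-analytic oracles: thick-walled cylinder inflation and the Laplace law.

These solutions are independent of the finite-element path: they use their
own closed-form reduced strain-energy derivatives for an incompressible,
fixed-length, axisymmetric inflation of a two-fiber-family tube, integrating
the radial equilibrium equation ``d(sigma_rr)/dr = (sigma_tt - sigma_rr)/r``
through the wall.  Two implementations are provided: quadrature plus a
bracketing root-find on the deformed inner radius, and an independent
shooting method built on finite-difference energy derivatives and an ODE
integrator.  Their mutual agreement and their agreement with the FE solver
are the pipeline's primary correctness gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp, cumulative_trapezoid
from scipy.optimize import brentq

from .constitutive import MaterialParameters

__all__ = ["CylinderSpec", "CylinderSolution", "laplace_hoop", "inflate_cylinder",
           "inflate_cylinder_shooting"]


@dataclass(frozen=True)
class CylinderSpec:
    inner_radius: float          # mm
    outer_radius: float          # mm
    length: float                # mm (bookkeeping; the solution is per unit length)
    material: MaterialParameters
    pressure: float              # MPa

    def __post_init__(self):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < Ri < Ro")
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")


@dataclass
class CylinderSolution:
    r: np.ndarray                # deformed radii through the wall [mm]
    R: np.ndarray                # reference radii [mm]
    sigma_rr: np.ndarray         # radial Cauchy stress [MPa]
    sigma_tt: np.ndarray         # circumferential (hoop) Cauchy stress [MPa]
    sigma_zz: np.ndarray         # axial Cauchy stress [MPa]
    inner_radius_deformed: float


def laplace_hoop(P: float, r: float, t: float) -> float:
    """Thin-walled membrane hoop stress P*r/t [MPa]."""
    if not t < r:
        raise ValueError("membrane estimate requires t < r")
    return P * r / t


def _reduced_derivatives(mat: MaterialParameters):
    """Closed-form d/dlam of W*(lam_t, lam_z=1) for the incompressible tube."""
    phi = np.deg2rad(mat.phi)
    s2, c2 = np.sin(phi) ** 2, np.cos(phi) ** 2

    def fiber_coef(I4):
        E = I4 - 1.0
        if mat.fiber_tension_only:
            E = np.where(E > 0, E, 0.0)
        return 2.0 * mat.k1 * E * np.exp(mat.k2 * E * E)

    def dW_dlt(lt):
        I4 = lt**2 * s2 + c2
        # two identical families; each contributes d(I4)/dlt = 2 lt sin^2
        return mat.mu * (lt - lt**-3) + 2.0 * fiber_coef(I4) * lt * s2

    def dW_dlz_at(lt, lz=1.0):
        I4 = lt**2 * s2 + lz**2 * c2
        lr = 1.0 / (lt * lz)
        return mat.mu * (lz - lz**-3 * lt**-2) + 2.0 * fiber_coef(I4) * lz * c2

    return dW_dlt, dW_dlz_at


def _kinematics(R, ri, Ri):
    r = np.sqrt(ri**2 + R**2 - Ri**2)
    return r, r / R


def _first_root(f, lo, hi, n_scan: int = 400):
    """First sign change of f on (lo, hi], refined by brentq."""
    grid = np.linspace(lo, hi, n_scan)
    prev_x, prev_f = grid[0], f(grid[0] + 1e-12 * (hi - lo))
    for x in grid[1:]:
        fx = f(x)
        if prev_f == 0.0:
            return float(prev_x)
        if prev_f * fx < 0:
            return float(brentq(f, prev_x, x, xtol=1e-12, rtol=1e-14))
        prev_x, prev_f = x, fx
    raise RuntimeError("inflation root-find found no equilibrium radius "
                       "(pressure beyond the limit point?)")


def inflate_cylinder(spec: CylinderSpec, n: int = 400) -> CylinderSolution:
    """Incompressible fixed-length inflation by quadrature of radial equilibrium.

    Satisfies sigma_rr(r_i) = -P and sigma_rr(r_o) = 0 to the root-find
    tolerance; returns through-wall Cauchy stress profiles on n stations.
    """
    Ri, Ro, P = spec.inner_radius, spec.outer_radius, spec.pressure
    dW_dlt, dW_dlz = _reduced_derivatives(spec.material)

    def pressure_for(ri):
        def integrand(R):
            r, lt = _kinematics(R, ri, Ri)
            # sigma_tt - sigma_rr = lam_t dW*/dlam_t; change of variable dr = (R/r) dR
            return lt * dW_dlt(lt) / r * (R / r)
        val, _ = quad(integrand, Ri, Ro, limit=200)
        return val

    if P == 0.0:
        ri = Ri
    else:
        # the pressure-radius response can be non-monotone (limit-point
        # ballooning for weakly stiffening walls): bracket the first,
        # stable, ascending-branch root by scanning outward
        f = lambda ri: pressure_for(ri) - P
        ri = _first_root(f, Ri, 3.0 * Ri)

    R = np.linspace(Ri, Ro, n)
    r, lt = _kinematics(R, ri, Ri)
    integrand = lt * dW_dlt(lt) / r
    srr = -P + np.concatenate([[0.0], cumulative_trapezoid(integrand, r)]) if n > 1 else np.array([-P])
    stt = srr + lt * dW_dlt(lt)
    szz = srr + dW_dlz(lt)  # lam_z = 1
    return CylinderSolution(r=r, R=R, sigma_rr=srr, sigma_tt=stt, sigma_zz=szz,
                            inner_radius_deformed=float(ri))


def inflate_cylinder_shooting(spec: CylinderSpec, n: int = 400,
                              h: float = 1e-6) -> CylinderSolution:
    """Independent oracle: shooting on the radial-equilibrium ODE.

    Uses finite-difference derivatives of the reduced strain energy (no
    closed-form derivative reuse) and an adaptive ODE integrator; the
    deformed inner radius is found by a secant iteration on the outer
    traction condition sigma_rr(r_o) = 0.
    """
    Ri, Ro, P = spec.inner_radius, spec.outer_radius, spec.pressure
    mat = spec.material
    phi = np.deg2rad(mat.phi)
    s2, c2 = np.sin(phi) ** 2, np.cos(phi) ** 2

    def W(lt, lz=1.0):
        lr = 1.0 / (lt * lz)
        I4 = lt**2 * s2 + lz**2 * c2
        E = max(I4 - 1.0, 0.0) if mat.fiber_tension_only else I4 - 1.0
        if mat.k2 > 1e-8:
            fib = mat.k1 / mat.k2 * (np.exp(mat.k2 * E * E) - 1.0)
        else:
            fib = mat.k1 * E * E * (1.0 + 0.5 * mat.k2 * E * E)
        return 0.5 * mat.mu * (lr**2 + lt**2 + lz**2 - 3.0) + fib

    def stress_diff(lt):
        return lt * (W(lt + h) - W(lt - h)) / (2.0 * h)

    def outer_srr(ri):
        ro = np.sqrt(ri**2 + Ro**2 - Ri**2)

        def rhs(r, y):
            lt = r / np.sqrt(r**2 - ri**2 + Ri**2)
            return [stress_diff(lt) / r]

        sol = solve_ivp(rhs, (ri, ro), [-P], rtol=1e-10, atol=1e-14, dense_output=True)
        return sol, float(sol.y[0, -1])

    if P == 0.0:
        ri = Ri
        sol, _ = outer_srr(ri)
    else:
        f = lambda ri: outer_srr(ri)[1]
        ri = _first_root(f, Ri * (1 + 1e-12), 3.0 * Ri)
        sol, _ = outer_srr(ri)

    R = np.linspace(Ri, Ro, n)
    r = np.sqrt(ri**2 + R**2 - Ri**2)
    lt = r / R
    srr = sol.sol(r)[0]
    stt = srr + np.array([stress_diff(x) for x in lt])
    szz = srr + np.array([(W(x, 1.0 + h) - W(x, 1.0 - h)) / (2.0 * h) for x in lt])
    return CylinderSolution(r=r, R=R, sigma_rr=srr, sigma_tt=stt, sigma_zz=szz,
                            inner_radius_deformed=float(ri))
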