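"""Two-fiber-family hyperelastic model of the arterial wall.

The wall is modeled as a nearly incompressible fiber-reinforced solid: an
isotropic neo-Hookean ground matrix plus two symmetrically oriented families
of collagen fibers with an exponential stiffening response (an HGO-type
strain-energy function, without fiber dispersion).  The strain energy is
split into an isochoric part, written in terms of the modified (isochoric)
invariants ``Ibar1``, ``Ibar4``, ``Ibar6`` of the right Cauchy-Green tensor,
and a volumetric penalty ``U(J) = (kappa/2)(J-1)^2`` enforcing near
incompressibility::

    psi = mu/2 (Ibar1 - 3)
        + k1/(2 k2) * sum_{i=4,6} [exp(k2 (Ibar_i - 1)^2) - 1]
        + kappa/2 (J - 1)^2

``Ibar4`` and ``Ibar6`` are the squared isochoric stretches along the two
fiber directions, which lie at a helix angle ``+phi`` / ``-phi`` from the
longitudinal vessel axis in the local (radial, circumferential, axial)
frame.  By default a fiber family contributes only when extended
(``Ibar_i > 1``), the standard tension-only treatment.

Units: mm-MPa-N.  All functions broadcast over leading array dimensions so
that a whole mesh of deformation states is evaluated in one call.  Stress
functions are "complex-step safe": evaluating them on complex-perturbed
kinematic inputs yields machine-precision derivatives, which is how the
consistent tangents are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "MaterialParameters",
    "DeformationState",
    "ConstitutiveOverflow",
    "fiber_directions",
    "isochoric_invariants",
    "strain_energy",
    "pk2_stress",
    "cauchy_stress",
    "material_tangent",
    "pk1_stress_and_tangent",
    "REFERENT_NORMAL",
    "BASELINE_AAA",
    "load_material",
]

_I3 = np.eye(3)

# Guard for the fiber exponential: exp arguments above this are reported as a
# diagnostic error rather than silently clamped.
_EXP_GUARD = 500.0
# Below this k2 the energy uses the series limit k1/2 * E^2 (1 + k2 E^2 / 2).
_K2_SERIES = 1e-8


class ConstitutiveOverflow(FloatingPointError):
    """Raised when the fiber exponential would overflow (diagnostic, not a clamp)."""


@dataclass(frozen=True)
class MaterialParameters:
    """Parameters of the two-fiber-family wall model.

    mu : shear-like stiffness of the ground matrix [MPa]
    k1 : fiber stiffness [MPa]
    k2 : dimensionless fiber exponent
    phi : fiber helix angle from the longitudinal axis [degrees]
    kappa_vol : volumetric penalty modulus [MPa]; default 1000*max(mu, 0.01)
    fiber_tension_only : drop a fiber family's term when its Ibar_i < 1.
        Default False: the exponential fiber energy is applied as written,
        symmetric about Ibar_i = 1.  The tension-only variant leaves a
        +/-45-degree fiber fabric with a near-mechanism in-plane shear mode
        (circumferential extension traded against axial shortening at
        constant fiber stretch), which is unstable for sac inflation.
    """

    mu: float
    k1: float
    k2: float
    phi: float
    kappa_vol: float | None = None
    fiber_tension_only: bool = False

    def __post_init__(self) -> None:
        if self.kappa_vol is None:
            object.__setattr__(self, "kappa_vol", 1000.0 * max(self.mu, 0.01))
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        if not 0.0 <= self.phi <= 90.0:
            raise ValueError(f"phi must lie in [0, 90] degrees, got {self.phi}")
        if self.kappa_vol < 100.0 * self.mu:
            raise ValueError("kappa_vol must be at least 100*mu for near incompressibility")


#: Referent normal abdominal aortic tissue.
REFERENT_NORMAL = MaterialParameters(mu=0.007, k1=2.87, k2=17.26, phi=36.0)
#: Baseline aneurysmal tissue (fitted human AAA median-type values).
BASELINE_AAA = MaterialParameters(mu=0.013, k1=2.74, k2=119.6, phi=45.0)

_PRESETS = {"referent_normal": REFERENT_NORMAL, "baseline_aaa": BASELINE_AAA}


def load_material(source) -> MaterialParameters:
    """Material parameters from a preset name or a key-value (YAML) config.

    Recognized keys: mu, k1, k2, phi, kappa_vol, fiber_tension_only.
    """
    import yaml

    if isinstance(source, str) and source in _PRESETS:
        return _PRESETS[source]
    with open(source) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"material config {source!r} is not a key-value mapping")
    allowed = {"mu", "k1", "k2", "phi", "kappa_vol", "fiber_tension_only"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown material keys: {sorted(unknown)}")
    return MaterialParameters(**data)


@dataclass
class DeformationState:
    """A (batch of) deformation gradient(s) with reference fiber directions.

    F : (..., 3, 3) deformation gradient
    a04, a06 : (..., 3) unit reference fiber directions
    """

    F: np.ndarray
    a04: np.ndarray
    a06: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F)
        self.a04 = np.asarray(self.a04, dtype=float)
        self.a06 = np.asarray(self.a06, dtype=float)
        for a in (self.a04, self.a06):
            n = np.linalg.norm(a, axis=-1)
            if not np.allclose(n, 1.0, atol=1e-8):
                raise ValueError("fiber directions must be unit vectors")

    @property
    def J(self) -> np.ndarray:
        return np.linalg.det(self.F)


def fiber_directions(phi: float) -> Tuple[np.ndarray, np.ndarray]:
    """Unit fiber direction pair in the local (radial, circumferential, axial) frame.

    The families lie in the circumferential-axial plane at +/-phi degrees from
    the axial direction: ``a04 = (0, sin phi, cos phi)``,
    ``a06 = (0, -sin phi, cos phi)``.
    """
    if not 0.0 <= phi <= 90.0:
        raise ValueError(f"phi must lie in [0, 90] degrees, got {phi}")
    p = np.deg2rad(phi)
    a04 = np.array([0.0, np.sin(p), np.cos(p)])
    a06 = np.array([0.0, -np.sin(p), np.cos(p)])
    return a04, a06


def _det33(C: np.ndarray) -> np.ndarray:
    # explicit cofactor expansion: complex-safe and fast for batched 3x3
    return (
        C[..., 0, 0] * (C[..., 1, 1] * C[..., 2, 2] - C[..., 1, 2] * C[..., 2, 1])
        - C[..., 0, 1] * (C[..., 1, 0] * C[..., 2, 2] - C[..., 1, 2] * C[..., 2, 0])
        + C[..., 0, 2] * (C[..., 1, 0] * C[..., 2, 1] - C[..., 1, 1] * C[..., 2, 0])
    )


def _inv33(C: np.ndarray, det: np.ndarray) -> np.ndarray:
    adj = np.empty_like(C)
    adj[..., 0, 0] = C[..., 1, 1] * C[..., 2, 2] - C[..., 1, 2] * C[..., 2, 1]
    adj[..., 0, 1] = C[..., 0, 2] * C[..., 2, 1] - C[..., 0, 1] * C[..., 2, 2]
    adj[..., 0, 2] = C[..., 0, 1] * C[..., 1, 2] - C[..., 0, 2] * C[..., 1, 1]
    adj[..., 1, 0] = C[..., 1, 2] * C[..., 2, 0] - C[..., 1, 0] * C[..., 2, 2]
    adj[..., 1, 1] = C[..., 0, 0] * C[..., 2, 2] - C[..., 0, 2] * C[..., 2, 0]
    adj[..., 1, 2] = C[..., 0, 2] * C[..., 1, 0] - C[..., 0, 0] * C[..., 1, 2]
    adj[..., 2, 0] = C[..., 1, 0] * C[..., 2, 1] - C[..., 1, 1] * C[..., 2, 0]
    adj[..., 2, 1] = C[..., 0, 1] * C[..., 2, 0] - C[..., 0, 0] * C[..., 2, 1]
    adj[..., 2, 2] = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    return adj / det[..., None, None]


def _modified_invariants(C, a04, a06):
    detC = _det33(C)
    if np.any(np.real(detC) <= 0):
        raise ValueError("non-positive det(C): invalid deformation state")
    Jm23 = detC ** (-1.0 / 3.0)
    Cbar = Jm23[..., None, None] * C
    I1b = Cbar[..., 0, 0] + Cbar[..., 1, 1] + Cbar[..., 2, 2]
    I4b = np.einsum("...i,...ij,...j->...", a04, Cbar, a04)
    I6b = np.einsum("...i,...ij,...j->...", a06, Cbar, a06)
    return detC, Cbar, I1b, I4b, I6b


def isochoric_invariants(state: DeformationState) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Modified invariants (Ibar1, Ibar4, Ibar6) of the right Cauchy-Green tensor."""
    F = state.F
    J = np.linalg.det(F)
    if np.any(np.real(J) <= 0):
        raise ValueError("non-positive J: invalid deformation state")
    C = np.einsum("...ki,...kj->...ij", F, F)
    _, _, I1b, I4b, I6b = _modified_invariants(C, state.a04, state.a06)
    return I1b, I4b, I6b


def _fiber_psi_and_coef(params: MaterialParameters, Iib: np.ndarray):
    """Per-family energy and stress coefficient 2*dpsi/dIbar_i, tension-masked."""
    E = Iib - 1.0
    if params.fiber_tension_only:
        # >= : at the reference state the tension branch supplies the
        # (one-sided) tangent an inflation step actually sees
        active = (np.real(E) >= 0.0).astype(float)
    else:
        active = np.ones_like(np.real(E))
    arg = params.k2 * E * E
    if np.any(np.real(arg) > _EXP_GUARD):
        worst = float(np.max(np.real(arg)))
        raise ConstitutiveOverflow(
            f"fiber exponential argument k2*(Ibar-1)^2 = {worst:.3g} exceeds guard "
            f"{_EXP_GUARD:g}; deformation state out of the model's numeric range"
        )
    ex = np.exp(arg)
    if params.k2 > _K2_SERIES:
        psi = params.k1 / (2.0 * params.k2) * (ex - 1.0)
    else:
        psi = 0.5 * params.k1 * E * E * (1.0 + 0.5 * arg)
    coef = 2.0 * params.k1 * E * ex
    return psi * active, coef * active


def strain_energy(params: MaterialParameters, state: DeformationState) -> np.ndarray:
    """Strain-energy density [MPa] = isochoric matrix + fibers + volumetric penalty."""
    F = state.F
    C = np.einsum("...ki,...kj->...ij", F, F)
    detC, _, I1b, I4b, I6b = _modified_invariants(C, state.a04, state.a06)
    J = np.sqrt(detC)
    psi = 0.5 * params.mu * (I1b - 3.0)
    for Iib in (I4b, I6b):
        p, _ = _fiber_psi_and_coef(params, Iib)
        psi = psi + p
    psi = psi + 0.5 * params.kappa_vol * (J - 1.0) ** 2
    return psi


def pk2_stress(params: MaterialParameters, C: np.ndarray, a04: np.ndarray, a06: np.ndarray,
               volumetric: bool = True, kappa_scale: float = 1.0) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dpsi/dC for (batched) C = F^T F.

    Complex-safe: C may carry complex perturbations for derivative extraction.
    With ``volumetric=False`` only the isochoric part is returned (the solver's
    nodal-pressure formulation supplies the volumetric response separately).
    """
    detC, Cbar, I1b, I4b, I6b = _modified_invariants(C, a04, a06)
    J = np.sqrt(detC)
    Cinv = _inv33(C, detC)
    Jm23 = detC ** (-1.0 / 3.0)

    # fictitious stress Sbar = 2 dpsibar/dCbar
    Sbar = params.mu * np.broadcast_to(_I3, C.shape).astype(C.dtype).copy()
    for Iib, a in ((I4b, a04), (I6b, a06)):
        _, coef = _fiber_psi_and_coef(params, Iib)
        Sbar = Sbar + coef[..., None, None] * np.einsum("...i,...j->...ij", a, a)

    SbarC = np.einsum("...ij,...ij->...", Sbar, C)
    S = Jm23[..., None, None] * (Sbar - (SbarC / 3.0)[..., None, None] * Cinv)
    if volumetric:
        S = S + (kappa_scale * params.kappa_vol * J * (J - 1.0))[..., None, None] * Cinv
    return S


def cauchy_stress(params: MaterialParameters, state: DeformationState) -> np.ndarray:
    """Cauchy stress sigma = (1/J) F S F^T [MPa], symmetric by construction."""
    F = state.F
    J = np.linalg.det(F)
    if np.any(np.real(J) <= 0):
        raise ValueError("non-positive J: invalid deformation state")
    C = np.einsum("...ki,...kj->...ij", F, F)
    S = pk2_stress(params, C, state.a04, state.a06)
    sig = np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


_CS_EPS = 1e-30  # complex-step size; derivative error is O(eps^2) = exact in floats


def material_tangent(params: MaterialParameters, state: DeformationState) -> np.ndarray:
    """Spatial elasticity tensor c_ijkl = (1/J) F_iI F_jJ F_kK F_lL * 2 dS_IJ/dC_KL.

    Computed by complex-step differentiation of the analytic second
    Piola-Kirchhoff stress; possesses both minor symmetries.
    """
    F = np.asarray(state.F, dtype=float)
    a04, a06 = state.a04, state.a06
    C = np.einsum("...ki,...kj->...ij", F, F)
    J = np.linalg.det(F)
    CSE = np.empty(C.shape + (3, 3))
    for K in range(3):
        for L in range(K, 3):
            dC = np.zeros((3, 3), dtype=complex)
            dC[K, L] += 0.5j * _CS_EPS
            dC[L, K] += 0.5j * _CS_EPS
            S = pk2_stress(params, C.astype(complex) + dC, a04, a06)
            d = 2.0 * S.imag / _CS_EPS  # 2 dS/dC along symmetrized direction
            CSE[..., K, L] = d
            CSE[..., L, K] = d
    c = np.einsum("...iI,...jJ,...kK,...lL,...IJKL->...ijkl", F, F, F, F, CSE)
    return c / J[..., None, None, None, None]


def pk1_stress_and_tangent(
    params: MaterialParameters, F: np.ndarray, a04: np.ndarray, a06: np.ndarray,
    want_tangent: bool = True, volumetric: bool = True, kappa_scale: float = 1.0,
):
    """First Piola-Kirchhoff stress P = F S and (optionally) A = dP/dF.

    The tangent is extracted by complex-step differentiation along the nine
    components of F, giving a Newton linearization consistent with the
    residual to machine precision.  Shapes: P (..., 3, 3); A (..., 3, 3, 3, 3)
    with A[..., i, J, k, L] = dP_iJ / dF_kL.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive J at a quadrature point (inverted element)")
    C = np.einsum("...ki,...kj->...ij", F, F)
    S = pk2_stress(params, C, a04, a06, volumetric=volumetric, kappa_scale=kappa_scale)
    P = np.einsum("...iI,...IJ->...iJ", F, S)
    if not want_tangent:
        return P, None
    A = np.empty(F.shape + (3, 3))
    for k in range(3):
        for L in range(3):
            Fc = F.astype(complex)
            Fc[..., k, L] += 1j * _CS_EPS
            Cc = np.einsum("...ki,...kj->...ij", Fc, Fc)
            Sc = pk2_stress(params, Cc, a04, a06, volumetric=volumetric,
                            kappa_scale=kappa_scale)
            Pc = np.einsum("...iI,...IJ->...iJ", Fc, Sc)
            A[..., k, L] = Pc.imag / _CS_EPS
    return P, A
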