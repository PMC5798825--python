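"""Von Mises stress fields and the two response variables PWS and AWS.

PWS is the maximum of the unsmoothed element-centroid von Mises stress over
the region of interest (no nodal extrapolation or gradient smoothing); AWS
is the element-size-weighted average.  The default weight is the element
reference volume; an optional mode weights lumen-adjacent elements by their
deformed lumen-face area instead (the two readings of "element size" for a
solid mesh bound the interpretation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import Mesh
from .geometry import VesselSolid

__all__ = ["StressSummary", "von_mises", "sac_region", "summarize"]


@dataclass
class StressSummary:
    PWS: float                      # peak von Mises stress in region [MPa]
    AWS: float                      # size-weighted average von Mises [MPa]
    region: str
    n_elements: int
    von_mises: np.ndarray           # per-element values over the region [MPa]
    weighting: str = "volume"

    def __post_init__(self):
        if self.AWS > self.PWS * (1 + 1e-12):
            raise ValueError("AWS cannot exceed PWS")


def von_mises(stress: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Scalar equivalent stress sqrt(3/2 s:s) of the deviator s [MPa].

    Accepts a single symmetric 3x3 tensor or a batch (..., 3, 3).
    """
    sig = np.asarray(stress, dtype=float)
    asym = np.abs(sig - np.swapaxes(sig, -1, -2)).max()
    scale = max(np.abs(sig).max(), 1e-300)
    if asym > 10 * rtol * scale:
        raise ValueError(f"stress tensor not symmetric (asymmetry {asym:.3e})")
    tr = np.trace(sig, axis1=-2, axis2=-1)
    s = sig - (tr / 3.0)[..., None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", s, s))


def sac_region(mesh: Mesh, solid: VesselSolid,
               span: tuple[float, float] | None = None) -> np.ndarray:
    """Element indices whose reference centroid z lies in the sac axial window.

    For the referent geometry the baseline sac span serves as the analogous
    location; pass `span` to override the solid's recorded span.
    """
    z_lo, z_hi = span if span is not None else solid.sac_span
    z = mesh.centroids[:, 2]
    idx = np.nonzero((z >= z_lo) & (z <= z_hi))[0]
    if len(idx) == 0:
        raise ValueError(f"empty sac region for span [{z_lo}, {z_hi}]")
    return idx


def summarize(solution, mesh: Mesh, region: np.ndarray,
              weighting: str = "volume", region_name: str = "sac") -> StressSummary:
    """PWS / AWS over a region of element indices.

    weighting='volume' uses reference element volumes; 'lumen_area' restricts
    the average to lumen-adjacent elements weighted by their deformed
    lumen-face areas.
    """
    vm_all = von_mises(solution.stress)
    vm = vm_all[region]
    pws = float(vm.max())
    if weighting == "volume":
        w = mesh.volumes[region]
        aws = float(np.average(vm, weights=w))
    elif weighting == "lumen_area":
        tris = mesh.boundary["lumen"]
        x = (mesh.nodes + solution.u)[tris]
        areas = 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
        # map each lumen triangle to its owning element by matching node triples
        tri_key = {tuple(sorted(t)): a for t, a in zip(tris.tolist(), areas)}
        w = np.zeros(len(region))
        in_region = set(region.tolist())
        elem_area = np.zeros(mesh.n_elements)
        faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        for fi in faces:
            keys = np.sort(mesh.tets[:, fi], axis=1)
            for e, k in enumerate(map(tuple, keys.tolist())):
                if k in tri_key:
                    elem_area[e] += tri_key[k]
        w = elem_area[region]
        if w.sum() == 0:
            raise ValueError("no lumen-adjacent elements in region")
        aws = float(np.average(vm[w > 0], weights=w[w > 0]))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return StressSummary(PWS=pws, AWS=aws, region=region_name,
                         n_elements=len(region), von_mises=vm, weighting=weighting)
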